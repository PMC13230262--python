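"""Spatio-temporal feature extraction: ConvGRU cells in a residual U-Net.

A ConvGRU replaces the fully connected gate transformations of a GRU with
convolutions, preserving the spatial layout of feature maps:

    z_t = sigmoid(x_t * W_xz + h_{t-1} * W_hz + b_z)        (update gate)
    r_t = sigmoid(x_t * W_xr + h_{t-1} * W_hr + b_r)        (reset gate)
    h^_t = tanh(x_t * W_xh + (r_t . h_{t-1}) * W_hh + b_h)  (candidate)
    h_t = z_t . h_{t-1} + (1 - z_t) . h^_t

where ``*`` is convolution and ``.`` elementwise product. The candidate in
``standard`` mode gates ``h_{t-1}`` by the reset gate (the form the original
ConvGRU works define); a ``verbatim`` mode omits ``r_t`` from the candidate
(i.e. uses ``h_{t-1}`` ungated), since the gate otherwise goes unused in
some presentations of the equations. Both modes are tested; neither is
asserted as uniquely correct.

The feature extractor is a 5-level residual U-Net. Recurrence placement
variants:

* ``NR`` — no recurrence (frame-independent features);
* ``RB`` — a single ConvGRU at the bottleneck (encoder level 5);
* ``RC`` — ConvGRU at encoder levels 2 and 5 and decoder levels 3 and 5;
* ``RA`` — ConvGRU at every encoder and decoder level.

In recurrent blocks the ConvGRU replaces the second convolution of the
residual block, so the identity connection lets the network ignore temporal
information entirely when it is unhelpful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, avg_pool2, concat_channels, conv2d, upsample2
from .scoring import FeatureMap

__all__ = [
    "ConvGRUCell",
    "convgru_step",
    "RecurrentUNetConfig",
    "SequenceState",
    "RecurrentUNet",
    "extract_features",
    "residual_block",
    "ResidualBlock",
    "VARIANT_PLACEMENTS",
]

VARIANT_PLACEMENTS: dict[str, dict[str, set[int]]] = {
    "NR": {"enc": set(), "dec": set()},
    "RB": {"enc": {5}, "dec": set()},
    "RC": {"enc": {2, 5}, "dec": {3, 5}},
    "RA": {"enc": {1, 2, 3, 4, 5}, "dec": {1, 2, 3, 4, 5}},
}


def _conv_params(rng, c_out, c_in, k, scale=None):
    scale = scale if scale is not None else np.sqrt(2.0 / (c_in * k * k))
    return Tensor(rng.normal(0.0, scale, size=(c_out, c_in, k, k)), requires_grad=True)


class ConvGRUCell:
    """Convolutional gated recurrent unit preserving spatial shape."""

    def __init__(
        self,
        c_in: int,
        c_hidden: int,
        kernel_size: int = 3,
        mode: str = "standard",
        rng: np.random.Generator | None = None,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd (same-padding)")
        if mode not in ("standard", "verbatim"):
            raise ValueError(f"unknown ConvGRU mode {mode!r}")
        rng = rng or np.random.default_rng(0)
        self.c_in = c_in
        self.c_hidden = c_hidden
        self.kernel_size = kernel_size
        self.mode = mode
        k = kernel_size
        s = np.sqrt(1.0 / (c_in * k * k))
        sh = np.sqrt(1.0 / (c_hidden * k * k))
        self.W_xz = _conv_params(rng, c_hidden, c_in, k, s)
        self.W_hz = _conv_params(rng, c_hidden, c_hidden, k, sh)
        self.W_xr = _conv_params(rng, c_hidden, c_in, k, s)
        self.W_hr = _conv_params(rng, c_hidden, c_hidden, k, sh)
        self.W_xh = _conv_params(rng, c_hidden, c_in, k, s)
        self.W_hh = _conv_params(rng, c_hidden, c_hidden, k, sh)
        self.b_z = Tensor(np.zeros(c_hidden), requires_grad=True)
        self.b_r = Tensor(np.zeros(c_hidden), requires_grad=True)
        self.b_h = Tensor(np.zeros(c_hidden), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [
            self.W_xz, self.W_hz, self.W_xr, self.W_hr, self.W_xh, self.W_hh,
            self.b_z, self.b_r, self.b_h,
        ]

    def init_state(self, h: int, w: int) -> Tensor:
        """Zero hidden state at sequence start."""
        return Tensor(np.zeros((self.c_hidden, h, w)))


def convgru_step(cell: ConvGRUCell, x_t, h_prev):
    """One ConvGRU step; accepts numpy arrays or Tensors, returns a Tensor."""
    x = x_t if isinstance(x_t, Tensor) else Tensor(np.asarray(x_t, dtype=float))
    h = h_prev if isinstance(h_prev, Tensor) else Tensor(np.asarray(h_prev, dtype=float))
    if x.data.ndim != 3 or h.data.ndim != 3:
        raise ValueError("ConvGRU expects (C, H, W) input and state")
    if x.data.shape[0] != cell.c_in or h.data.shape[0] != cell.c_hidden:
        raise ValueError(
            f"channel mismatch: x has {x.data.shape[0]} (expect {cell.c_in}), "
            f"h has {h.data.shape[0]} (expect {cell.c_hidden})"
        )
    if x.data.shape[1:] != h.data.shape[1:]:
        raise ValueError("input and hidden state spatial shapes differ")
    z = (conv2d(x, cell.W_xz) + conv2d(h, cell.W_hz) + _bias(cell.b_z)).sigmoid()
    r = (conv2d(x, cell.W_xr) + conv2d(h, cell.W_hr) + _bias(cell.b_r)).sigmoid()
    if cell.mode == "standard":
        h_for_cand = r * h
    else:  # verbatim: candidate uses h_{t-1} ungated
        h_for_cand = h
    h_hat = (conv2d(x, cell.W_xh) + conv2d(h_for_cand, cell.W_hh) + _bias(cell.b_h)).tanh()
    return z * h + (1.0 - z) * h_hat


def _bias(b: Tensor) -> Tensor:
    return b.reshape(-1, 1, 1)


class ResidualBlock:
    """``y = x + conv2(relu(conv1(x)))``; identity when F's weights are zero."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1_w = _conv_params(rng, channels, channels, kernel_size)
        self.conv1_b = Tensor(np.zeros(channels), requires_grad=True)
        self.conv2_w = _conv_params(rng, channels, channels, kernel_size)
        self.conv2_b = Tensor(np.zeros(channels), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.conv1_w, self.conv1_b, self.conv2_w, self.conv2_b]

    def forward(self, x: Tensor) -> Tensor:
        f = conv2d(x, self.conv1_w, self.conv1_b).relu()
        f = conv2d(f, self.conv2_w, self.conv2_b)
        return x + f


def residual_block(x, block: ResidualBlock):
    """Functional form of the residual computation (accepts numpy or Tensor)."""
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
    return block.forward(xt)


class RecurrentResidualBlock:
    """Residual block whose second convolution is replaced by a ConvGRU."""

    def __init__(self, channels: int, kernel_size: int = 3, mode: str = "standard",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1_w = _conv_params(rng, channels, channels, kernel_size)
        self.conv1_b = Tensor(np.zeros(channels), requires_grad=True)
        self.gru = ConvGRUCell(channels, channels, kernel_size, mode=mode, rng=rng)

    def parameters(self) -> list[Tensor]:
        return [self.conv1_w, self.conv1_b, *self.gru.parameters()]

    def forward(self, x: Tensor, h_prev: Tensor) -> tuple[Tensor, Tensor]:
        f = conv2d(x, self.conv1_w, self.conv1_b).relu()
        h = convgru_step(self.gru, f, h_prev)
        return x + h, h


@dataclass(frozen=True)
class RecurrentUNetConfig:
    """5-level recurrent residual U-Net configuration.

    ``channels`` are the per-level widths (level 1 = input resolution,
    level 5 = bottleneck at 1/16 resolution); ``feature_dim`` is the output
    feature dimension per pixel (64 is the full-scale setting; the default
    is small enough for CPU training).
    """

    variant: str = "NR"  # {NR | RA | RB | RC}
    channels: tuple[int, ...] = (4, 6, 8, 10, 12)
    in_channels: int = 1
    feature_dim: int = 16
    kernel_size: int = 3
    gru_mode: str = "standard"  # {standard | verbatim}
    levels: int = 5

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_PLACEMENTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.levels != 5:
            raise ValueError("the architecture is a 5-level U-Net")
        if len(self.channels) != 5:
            raise ValueError("channels must list 5 per-level widths")


class SequenceState:
    """Hidden maps of all recurrent layers; zeroed between sequences."""

    def __init__(self) -> None:
        self.hidden: dict[str, Tensor] = {}

    def reset(self) -> None:
        self.hidden.clear()

    def get(self, key: str, cell: ConvGRUCell, h: int, w: int) -> Tensor:
        if key not in self.hidden:
            self.hidden[key] = cell.init_state(h, w)
        return self.hidden[key]

    def set(self, key: str, value: Tensor) -> None:
        self.hidden[key] = value

    def detach(self) -> None:
        """Cut the autodiff graph (truncated backprop between batches)."""
        for k in list(self.hidden):
            self.hidden[k] = self.hidden[k].detach()


class RecurrentUNet:
    """Recurrent residual U-Net producing per-pixel features per frame."""

    def __init__(self, config: RecurrentUNetConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        ch = config.channels
        k = config.kernel_size
        place = VARIANT_PLACEMENTS[config.variant]
        self._modules: dict[str, object] = {}

        def make_block(key: str, channels: int, recurrent: bool):
            if recurrent:
                self._modules[key] = RecurrentResidualBlock(
                    channels, k, mode=config.gru_mode, rng=rng
                )
            else:
                self._modules[key] = ResidualBlock(channels, k, rng=rng)

        # encoder: entry conv changes width, block refines at that width
        prev = config.in_channels
        for lv in range(1, 6):
            self._modules[f"enc{lv}.entry_w"] = _conv_params(rng, ch[lv - 1], prev, k)
            self._modules[f"enc{lv}.entry_b"] = Tensor(np.zeros(ch[lv - 1]), requires_grad=True)
            make_block(f"enc{lv}.block", ch[lv - 1], lv in place["enc"])
            prev = ch[lv - 1]
        # decoder: stage d at resolution 1/2^(5-d); stages 2..5 concat skips
        dec_ch = [ch[4], ch[3], ch[2], ch[1], ch[0]]
        for d in range(1, 6):
            cin = ch[4] if d == 1 else dec_ch[d - 2] + dec_ch[d - 1]
            self._modules[f"dec{d}.entry_w"] = _conv_params(rng, dec_ch[d - 1], cin, k)
            self._modules[f"dec{d}.entry_b"] = Tensor(np.zeros(dec_ch[d - 1]), requires_grad=True)
            make_block(f"dec{d}.block", dec_ch[d - 1], d in place["dec"])
        self._modules["head_w"] = _conv_params(rng, config.feature_dim, ch[0], k)
        self._modules["head_b"] = Tensor(np.zeros(config.feature_dim), requires_grad=True)

    # --- parameter plumbing ----------------------------------------------

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for m in self._modules.values():
            if isinstance(m, Tensor):
                out.append(m)
            else:
                out.extend(m.parameters())
        return out

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_params(self, prefix: str = "unet") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for key, m in self._modules.items():
            if isinstance(m, Tensor):
                out[f"{prefix}.{key}"] = m.data
            else:
                for i, p in enumerate(m.parameters()):
                    out[f"{prefix}.{key}.p{i}"] = p.data
        return out

    def load_named(self, named: dict[str, np.ndarray], prefix: str = "unet") -> None:
        def assign(p: Tensor, name: str) -> None:
            v = np.asarray(named[name], dtype=float)
            if v.shape != p.data.shape:
                raise ValueError(
                    f"parameter {name!r} has shape {v.shape}, expected {p.data.shape}"
                )
            p.data[...] = v

        for key, m in self._modules.items():
            if isinstance(m, Tensor):
                assign(m, f"{prefix}.{key}")
            else:
                for i, p in enumerate(m.parameters()):
                    assign(p, f"{prefix}.{key}.p{i}")

    # --- forward ----------------------------------------------------------

    def _run_block(self, key: str, x: Tensor, state: SequenceState) -> Tensor:
        block = self._modules[key]
        if isinstance(block, RecurrentResidualBlock):
            h_prev = state.get(key, block.gru, x.data.shape[1], x.data.shape[2])
            y, h = block.forward(x, h_prev)
            state.set(key, h)
            return y
        return block.forward(x)

    def forward_frame(self, frame: np.ndarray | Tensor, state: SequenceState) -> Tensor:
        """Features for one frame, threading recurrent state; (C,H,W) in/out."""
        x = frame if isinstance(frame, Tensor) else Tensor(np.asarray(frame, dtype=float))
        if x.data.ndim == 2:
            x = x.reshape(1, *x.data.shape)
        _, H, W = x.data.shape
        if H % 16 or W % 16:
            raise ValueError(
                f"spatial size ({H}x{W}) must be a multiple of 16 for the 5-level U-Net"
            )
        skips: list[Tensor] = []
        for lv in range(1, 6):
            x = conv2d(
                x, self._modules[f"enc{lv}.entry_w"], self._modules[f"enc{lv}.entry_b"]
            ).relu()
            x = self._run_block(f"enc{lv}.block", x, state)
            if lv < 5:
                skips.append(x)
                x = avg_pool2(x)
        for d in range(1, 6):
            if d > 1:
                x = upsample2(x)
                x = concat_channels(x, skips[5 - d])
            x = conv2d(
                x, self._modules[f"dec{d}.entry_w"], self._modules[f"dec{d}.entry_b"]
            ).relu()
            x = self._run_block(f"dec{d}.block", x, state)
        return conv2d(x, self._modules["head_w"], self._modules["head_b"])


def extract_features(
    net: RecurrentUNet,
    frames: list[np.ndarray],
    state: SequenceState | None = None,
) -> list[FeatureMap]:
    """Per-frame feature maps for one camera's time-ordered frame sequence.

    With variant ``NR`` the output at time t depends only on frame t; with
    recurrent variants it depends only on frames <= t (causality by
    construction). The state is reset at sequence start.
    """
    if state is None:
        state = SequenceState()
    state.reset()
    out = []
    for frame in frames:
        feat = net.forward_frame(frame, state)
        out.append(FeatureMap(values=np.ascontiguousarray(feat.data.transpose(1, 2, 0))))
        state.detach()  # inference path: no need to retain the graph
    return out
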