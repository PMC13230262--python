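"""Metric suite: tip error, object-angle error, trajectory smoothness
(RMSD/RMSAD), visibility binning and grouped summaries.

Tip error is the Euclidean distance (mm) between predicted and true tip
positions in world coordinates; the object angle error is the angle between
the predicted and true tip-to-rear axis directions. RMSD and RMSAD measure
the frame-to-frame deviation of tip position and axis angle — a smoothness
proxy, expected close to (not equal to) the ground-truth values because the
instrument genuinely moves between frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import RigidPose, angle_between, normalize_direction
from .instrument import InstrumentModel, tip_rear_world
from .fusion_estimate import PointEstimate

__all__ = [
    "MetricRecord",
    "tip_error",
    "angle_error",
    "rmsd",
    "rmsad",
    "bin_by_visibility",
    "summarize",
    "records_to_frame",
    "markdown_report",
]


@dataclass(frozen=True)
class MetricRecord:
    frame: int
    tip_error: float  # mm
    angle_error: float  # degrees
    visibility: float  # fraction in [0, 1]
    occluded: bool
    method: str

    def __post_init__(self) -> None:
        if self.tip_error < 0:
            raise ValueError("tip_error must be non-negative")
        if not 0.0 <= self.angle_error <= 180.0:
            raise ValueError("angle_error must lie in [0, 180] degrees")


def tip_error(pred: PointEstimate, gt_pose: RigidPose, model: InstrumentModel) -> float:
    """Euclidean distance between predicted and true tip positions (mm)."""
    gt_tip = gt_pose.transform(model.tip)
    return float(np.linalg.norm(pred.tip - gt_tip))


def angle_error(pred: PointEstimate, gt_pose: RigidPose, model: InstrumentModel) -> float:
    """Angle (degrees) between predicted and true tip-to-rear directions."""
    _, _, gt_dir = tip_rear_world(gt_pose, model)
    return angle_between(pred.direction, gt_dir)


def rmsd(tips: np.ndarray) -> float:
    """Root-mean-square frame-to-frame tip displacement (mm)."""
    tips = np.asarray(tips, dtype=float).reshape(-1, 3)
    if tips.shape[0] < 2:
        raise ValueError("rmsd requires at least 2 frames")
    steps = np.diff(tips, axis=0)
    return float(np.sqrt(np.mean(np.sum(steps**2, axis=1))))


def rmsad(directions: np.ndarray) -> float:
    """Root-mean-square frame-to-frame angular deviation (degrees)."""
    d = np.asarray(directions, dtype=float).reshape(-1, 3)
    if d.shape[0] < 2:
        raise ValueError("rmsad requires at least 2 frames")
    angles = [angle_between(d[i], d[i - 1]) for i in range(1, d.shape[0])]
    return float(np.sqrt(np.mean(np.square(angles))))


def records_to_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": [r.frame for r in records],
            "tip_error": [r.tip_error for r in records],
            "angle_error": [r.angle_error for r in records],
            "visibility": [r.visibility for r in records],
            "occluded": [r.occluded for r in records],
            "method": [r.method for r in records],
        }
    )


def bin_by_visibility(records: list[MetricRecord], bin_width: float = 0.01) -> pd.DataFrame:
    """Mean errors per half-open visibility bin ``[k*w, (k+1)*w)``.

    The final bin is closed at 1.0 so the bins partition [0, 1] without
    double counting. Empty bins are reported with count 0.
    """
    if not 0.0 < bin_width <= 1.0:
        raise ValueError("bin_width must lie in (0, 1]")
    n_bins = int(np.ceil(1.0 / bin_width))
    df = records_to_frame(records)
    idx = np.minimum((df["visibility"] / bin_width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = df[idx == b]
        rows.append(
            {
                "bin_lo": b * bin_width,
                "bin_hi": min((b + 1) * bin_width, 1.0),
                "mean_tip_error": sel["tip_error"].mean() if len(sel) else np.nan,
                "mean_angle_error": sel["angle_error"].mean() if len(sel) else np.nan,
                "count": len(sel),
            }
        )
    return pd.DataFrame(rows)


def summarize(records: list[MetricRecord], group_keys: list[str] | None = None) -> pd.DataFrame:
    """Grouped mean±SD, median, IQR and RMSD/RMSAD per group.

    SD is the sample standard deviation (n-1 denominator); a single-record
    group reports SD 0 with ``sd_defined = False``.
    """
    df = records_to_frame(records)
    group_keys = group_keys or ["method"]
    rows = []
    for keys, g in df.groupby(group_keys, sort=True):
        if len(g) == 0:
            continue
        if not isinstance(keys, tuple):
            keys = (keys,)
        g = g.sort_values("frame")
        row = dict(zip(group_keys, keys))
        for metric in ("tip_error", "angle_error"):
            vals = g[metric].to_numpy()
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{metric}_median"] = float(np.median(vals))
            q75, q25 = np.percentile(vals, [75, 25])
            row[f"{metric}_iqr"] = float(q75 - q25)
        row["sd_defined"] = len(g) > 1
        row["count"] = len(g)
        rows.append(row)
    return pd.DataFrame(rows)


def markdown_report(summary: pd.DataFrame, title: str = "Results") -> str:
    """Small markdown table in the Mean±SD / median style of the experiment
    tables; one row per group."""
    lines = [f"## {title}", ""]
    keys = [c for c in summary.columns if not any(
        c.startswith(p) for p in ("tip_error", "angle_error", "sd_defined", "count")
    )]
    header = keys + ["Tip error (mm) Mean±SD", "Angle error (deg) Mean±SD", "n"]
    lines.append("| " + " | ".join(header) + " |")
    lines.append("|" + "---|" * len(header))
    for _, row in summary.iterrows():
        cells = [str(row[k]) for k in keys]
        cells.append(f"{row['tip_error_mean']:.2f}±{row['tip_error_sd']:.2f}")
        cells.append(f"{row['angle_error_mean']:.2f}±{row['angle_error_sd']:.2f}")
        cells.append(str(int(row["count"])))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
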