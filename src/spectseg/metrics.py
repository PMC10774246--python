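"""Evaluation quantities: DSC, volume-error summaries, paired t-test,
misclassification projections.

Volume agreement is summarised on *relative* volumes r_i = Vhat_i / V_i:
MAE = mean(|r_i - 1|) * 100 (percent), MRV = mean(r_i), and S the sample
standard deviation of the r_i — matching how per-phantom tables are usually
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import CaseSpec
from .segment import BinaryMask

__all__ = [
    "EvalRecord",
    "dsc",
    "summarize",
    "paired_t",
    "misclass_projection",
    "records_to_frame",
]


@dataclass(frozen=True)
class EvalRecord:
    """Per-case, per-method segmentation outcome."""

    case: CaseSpec
    method: str  # "otsu" | "chan_vese"
    estimated_volume_ml: float
    true_volume_ml: float
    dsc: float
    otsu_threshold: int | None = None
    k: float | None = None

    @property
    def relative_volume(self) -> float:
        return self.estimated_volume_ml / self.true_volume_ml


def dsc(mask: BinaryMask, truth) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|).

    Defined as 1 when both masks are empty and 0 when exactly one is empty.
    ``truth`` may be a BinaryMask or a boolean array on the same grid.
    """
    a = mask.u if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    b = truth.u if isinstance(truth, BinaryMask) else np.asarray(truth, bool)
    if a.shape != b.shape:
        raise ValueError("masks live on different grids")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate evaluation records (one row per case x method)."""
    rows = []
    for r in records:
        rows.append(
            {
                "volume_ml": r.case.volume_ml,
                "background_rel": r.case.background_rel,
                "hotspot_rel": r.case.hotspot_rel,
                "seed": r.case.seed,
                "method": r.method,
                "estimated_volume_ml": r.estimated_volume_ml,
                "true_volume_ml": r.true_volume_ml,
                "relative_volume": r.relative_volume,
                "dsc": r.dsc,
                "otsu_threshold": r.otsu_threshold,
                "k": r.k,
            }
        )
    return pd.DataFrame(rows)


def summarize(records, pooled_label: str = "20-50") -> pd.DataFrame:
    """Per-volume-group and pooled MAE (%), MRV and sample SD of relative volumes.

    Records of different methods must not be mixed; group by method first.
    """
    records = list(records)
    if len({r.method for r in records}) > 1:
        raise ValueError("summarize expects records of a single method")
    rel = {}
    for r in records:
        rel.setdefault(r.case.volume_ml, []).append(r.relative_volume)
    groups = [(str(int(v) if float(v).is_integer() else v), vals) for v, vals in sorted(rel.items())]
    groups.append((pooled_label, [x for _, vals in groups for x in vals]))
    rows = []
    for label, vals in groups:
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 records; SD undefined")
        arr = np.asarray(vals, dtype=np.float64)
        rows.append(
            {
                "volume_group": label,
                "n": len(arr),
                "mae_pct": float(np.abs(arr - 1.0).mean() * 100.0),
                "mrv": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def paired_t(dsc_a, dsc_b) -> tuple[float, float]:
    """Classical paired t-test on per-case differences (two-sided).

    Returns (t statistic, p value). All-equal pairs give (0, 1); zero
    variance of the differences with a non-zero mean gives p = 0 with a
    warning.
    """
    a = np.asarray(dsc_a, dtype=np.float64)
    b = np.asarray(dsc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn("zero variance of differences with non-zero mean; p = 0")
        return float(np.inf * np.sign(d.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def misclass_projection(mask: BinaryMask, truth, axis: int = 1):
    """Missed-voxel and false-positive count maps summed along an axis.

    Sums truth AND NOT mask (missed object voxels) and mask AND NOT truth
    (background misclassified as object) along the given anatomical axis
    (default 1 = anterior-posterior, y). Map totals equal the 3D confusion
    counts.
    """
    a = mask.u if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    b = truth.u if isinstance(truth, BinaryMask) else np.asarray(truth, bool)
    if a.shape != b.shape:
        raise ValueError("masks live on different grids")
    if not 0 <= axis < a.ndim:
        raise ValueError(f"axis {axis} invalid for {a.ndim}D masks")
    missed = (b & ~a).sum(axis=axis)
    false_pos = (a & ~b).sum(axis=axis)
    return missed, false_pos
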