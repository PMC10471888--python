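"""Absolute mtDNA copy-number quantification from qPCR plates.

Each plate carries a standard curve of six 10-fold serial dilutions of a
single-copy plasmid; threshold cycle (Ct) is linear in log10 template
copies, and the fitted line converts a sample's mean Ct into copies per
reaction.  Copies per cell divide out the number of sorted cells and the
fraction of the lysate loaded into the reaction.  Plate-to-plate variation
is removed by rescaling against an on-plate control sample::

    normalised = (absolute / on-plate control) * mean control

Replicate QC: a sample is excluded when its triplicate Ct SD exceeds 0.3
or its mean Ct exceeds 30; a single within-triplicate outlier replicate
may be dropped first (see :func:`apply_ct_exclusions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "CurveQCBounds",
    "fit_standard_curve",
    "quantify",
    "normalize_plate",
    "apply_ct_exclusions",
]

# perfect PCR doubles template each cycle: slope = -1/log10(2) = -3.3219
PERFECT_EFFICIENCY_SLOPE = -1.0 / math.log10(2.0)


@dataclass(frozen=True)
class CurveQCBounds:
    """Acceptable standard-curve ranges (assay-validated defaults)."""

    slope_min: float = -3.449
    slope_max: float = -3.264
    min_r_squared: float = 0.9992


@dataclass(frozen=True)
class StandardCurve:
    slope: float          # Ct per log10 copies; negative for real curves
    intercept: float      # Ct at 1 copy
    r_squared: float
    qc_pass: bool = True
    qc_reason: str = ""


def fit_standard_curve(copies, cts,
                       qc: CurveQCBounds | None = None) -> StandardCurve:
    """Least-squares line of Ct on log10(copies per reaction).

    Requires at least 3 dilution points with positive known copies.  The
    curve is flagged (``qc_pass=False``) when slope or r² falls outside the
    configured bounds; a flat curve (slope >= 0) always fails QC.
    """
    qc = qc or CurveQCBounds()
    copies = np.asarray(copies, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if copies.size < 3 or cts.size != copies.size:
        raise ValueError("need >= 3 (copies, Ct) dilution points")
    if np.any(copies <= 0):
        raise ValueError("known copies must be positive")
    res = stats.linregress(np.log10(copies), cts)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue ** 2)
    reasons = []
    if slope >= 0:
        reasons.append(f"non-negative slope {slope:.3f}")
    elif not (qc.slope_min <= slope <= qc.slope_max):
        reasons.append(f"slope {slope:.3f} outside "
                       f"[{qc.slope_min}, {qc.slope_max}]")
    if r2 < qc.min_r_squared:
        reasons.append(f"r^2 {r2:.5f} < {qc.min_r_squared}")
    return StandardCurve(slope=slope, intercept=intercept, r_squared=r2,
                         qc_pass=not reasons, qc_reason="; ".join(reasons))


def quantify(mean_ct: float, curve: StandardCurve, n_cells: int,
             volume_factor: float = 1.0 / 25.0) -> float:
    """Copies per cell from a sample's mean Ct.

    copies_in_reaction = 10 ** ((mean_ct - intercept) / slope);
    copies_per_cell   = copies_in_reaction / (n_cells * volume_factor).

    ``volume_factor`` is the fraction of the cell lysate loaded into the
    reaction; the default 1/25 corresponds to 5 ul of a 1:5 dilution of a
    25 ul lysate.  It is an assay constant and should be set to match the
    actual volume bookkeeping.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if volume_factor <= 0:
        raise ValueError("volume_factor must be positive")
    if curve.slope == 0:
        raise ValueError("degenerate standard curve (slope 0)")
    copies_in_reaction = 10.0 ** ((mean_ct - curve.intercept) / curve.slope)
    return copies_in_reaction / (n_cells * volume_factor)


def ct_from_copies(copies_in_reaction: float, curve: StandardCurve) -> float:
    """Inverse of the curve: expected Ct for a given template amount."""
    if copies_in_reaction <= 0:
        raise ValueError("copies must be positive")
    return curve.intercept + curve.slope * math.log10(copies_in_reaction)


def normalize_plate(absolute: float, on_plate_control: float,
                    mean_control: float) -> float:
    """Rescale an absolute copy number by the plate's control sample."""
    if on_plate_control <= 0 or mean_control <= 0:
        raise ValueError("control copy numbers must be positive")
    return (absolute / on_plate_control) * mean_control


def _drop_outlier(cts: np.ndarray, sd_max: float):
    """Try dropping one replicate: allowed when the remaining pair is tight
    (SD <= sd_max) and the dropped value deviates from the pair mean by more
    than 3x the pair's spread.  Returns (kept cts, dropped index or None)."""
    best = None
    for i in range(cts.size):
        rest = np.delete(cts, i)
        spread = float(np.ptp(rest))
        sd_rest = float(np.std(rest, ddof=1))
        dev = abs(cts[i] - rest.mean())
        if sd_rest <= sd_max and dev > 3.0 * spread and dev > sd_max:
            if best is None or dev > best[0]:
                best = (dev, i)
    if best is None:
        return cts, None
    return np.delete(cts, best[1]), int(best[1])


def apply_ct_exclusions(samples: pd.DataFrame, sd_max: float = 0.3,
                        ct_max: float = 30.0,
                        drop_outliers: bool = True) -> pd.DataFrame:
    """Flag replicate-level QC failures on a qPCR sample table.

    ``samples`` needs a ``sample`` column and replicate Ct columns named
    ct1, ct2, ct3 (NaN = missing).  Per sample: optionally drop one
    within-triplicate outlier (a replicate whose removal leaves a tight
    pair it deviates from by more than 3x that pair's spread), then exclude
    iff the SD of the remaining Cts exceeds ``sd_max`` or their mean
    exceeds ``ct_max``; fewer than 2 usable replicates is itself an
    exclusion.  Adds mean_ct, ct_sd, n_replicates_used, dropped_replicate,
    excluded and exclusion_reason columns.  Idempotent and
    order-independent across samples.
    """
    ct_cols = [c for c in samples.columns if c.startswith("ct")
               and c[2:].isdigit()]
    if not ct_cols:
        raise ValueError("no replicate Ct columns (ct1, ct2, ...) found")
    out = samples.copy()
    means, sds, nused, dropped, excl, reasons = [], [], [], [], [], []
    for _, row in samples.iterrows():
        cts = row[ct_cols].to_numpy(dtype=float)
        cts = cts[np.isfinite(cts)]
        drop_idx = None
        if drop_outliers and cts.size >= 3:
            kept, drop_idx = _drop_outlier(cts, sd_max)
            if drop_idx is not None:
                cts = kept
        if cts.size < 2:
            means.append(float(cts.mean()) if cts.size else np.nan)
            sds.append(np.nan)
            nused.append(int(cts.size))
            dropped.append(drop_idx)
            excl.append(True)
            reasons.append("fewer than 2 usable replicates")
            continue
        m = float(cts.mean())
        sd = float(np.std(cts, ddof=1))
        reason = []
        if sd > sd_max:
            reason.append(f"Ct SD {sd:.3f} > {sd_max}")
        if m > ct_max:
            reason.append(f"mean Ct {m:.2f} > {ct_max}")
        means.append(m); sds.append(sd); nused.append(int(cts.size))
        dropped.append(drop_idx)
        excl.append(bool(reason))
        reasons.append("; ".join(reason))
    out["mean_ct"] = means
    out["ct_sd"] = sds
    out["n_replicates_used"] = nused
    out["dropped_replicate"] = dropped
    out["excluded"] = excl
    out["exclusion_reason"] = reasons
    return out
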