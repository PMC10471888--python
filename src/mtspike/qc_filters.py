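"""Per-batch read-depth QC and negative-control plate exclusion.

Three filters produce the analysis-ready cell set:

* a lower read-depth threshold per sequencing batch (fixed, or an
  "auto" stand-in that anchors the threshold at a configurable floor);
* an upper-depth rule against wells that received more than one cell —
  by default depth > k * Q3 with k = 1.5 (the literal reading of
  "1.5 times the upper boundary of the interquartile range"), with the
  classic Tukey fence Q3 + k * (Q3 - Q1) available as a variant;
* whole-plate exclusion when the plate's negative-control well shows a
  cell-like read depth (suspected contamination).

Quartiles use linear interpolation between order statistics throughout
(numpy/R type-7), declared in the config because conventions differ near
ties.  Thresholds are resolved once per batch from the input distribution
and recorded in the report, so re-applying the resolved report removes
nothing further.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "QCReport",
    "lower_depth_threshold",
    "upper_depth_exclusion",
    "flag_contaminated_plates",
    "apply_qc",
    "depth_summary",
]


@dataclass(frozen=True)
class QCConfig:
    lower_depth_threshold: int | str = "auto"
    auto_floor: int = 200
    upper_rule_multiplier: float = 1.5
    upper_rule_variant: str = "q3_times_k"      # or "tukey_fence"
    quartile_method: str = "linear"
    negative_control_max_depth: int = 10

    def __post_init__(self) -> None:
        if self.upper_rule_multiplier <= 0:
            raise ValueError("upper_rule_multiplier must be positive")
        if self.upper_rule_variant not in ("q3_times_k", "tukey_fence"):
            raise ValueError(f"unknown upper rule {self.upper_rule_variant!r}")
        if self.negative_control_max_depth < 0:
            raise ValueError("negative_control_max_depth must be >= 0")
        fixed = self.lower_depth_threshold
        if isinstance(fixed, str):
            if fixed != "auto":
                raise ValueError("lower_depth_threshold must be an int or 'auto'")
        elif fixed < 1:
            raise ValueError("lower_depth_threshold must be positive")


@dataclass
class QCReport:
    """Bookkeeping of one QC pass; per-plate counts sum exactly."""

    config: QCConfig
    lower_thresholds: dict = field(default_factory=dict)   # batch -> value
    upper_thresholds: dict = field(default_factory=dict)   # batch -> value
    excluded_plates: dict = field(default_factory=dict)    # plate -> reason
    per_plate: dict = field(default_factory=dict)
    retained_cells: list = field(default_factory=list)
    retained_depth_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {
            "config": asdict(self.config),
            "lower_thresholds": self.lower_thresholds,
            "upper_thresholds": self.upper_thresholds,
            "excluded_plates": self.excluded_plates,
            "per_plate": self.per_plate,
            "n_retained": len(self.retained_cells),
            "retained_depth_summary": self.retained_depth_summary,
        }


def lower_depth_threshold(depths, config: QCConfig) -> float:
    """Resolve the per-batch lower depth threshold; cells below it are excluded.

    A fixed integer is returned as-is.  Under ``"auto"`` the threshold is
    the smallest observed depth at or above the configured floor — a
    reproducible stand-in for the original per-batch visual inspection,
    with the floor defaulting to 200.
    """
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty batch: no depths to threshold")
    if config.lower_depth_threshold != "auto":
        return float(config.lower_depth_threshold)
    above = depths[depths >= config.auto_floor]
    if above.size == 0:
        return float(config.auto_floor)
    return float(above.min())


def upper_depth_exclusion(depths, config: QCConfig) -> np.ndarray:
    """Boolean mask of wells excluded by the upper (doublet) depth rule.

    q3_times_k excludes depth > k * Q3; tukey_fence excludes
    depth > Q3 + k * (Q3 - Q1).  With fewer than 4 depths no quartile is
    trusted: nothing is excluded and a warning is issued.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size < 4:
        warnings.warn("fewer than 4 depths; skipping upper-depth rule")
        return np.zeros(depths.shape, dtype=bool)
    return depths > _upper_threshold(depths, config)


def _upper_threshold(depths, config: QCConfig) -> float:
    q1, q3 = np.quantile(depths, [0.25, 0.75], method=config.quartile_method)
    if config.upper_rule_variant == "q3_times_k":
        return config.upper_rule_multiplier * q3
    return q3 + config.upper_rule_multiplier * (q3 - q1)


def flag_contaminated_plates(control_depths: dict, config: QCConfig) -> list:
    """Plates whose negative-control depth exceeds the configured maximum."""
    return sorted(p for p, d in control_depths.items()
                  if d > config.negative_control_max_depth)


def depth_summary(depths) -> dict:
    """Median / IQR / range of retained depths, the form the assay reports."""
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        return {"n": 0}
    q1, med, q3 = np.quantile(depths, [0.25, 0.5, 0.75], method="linear")
    return {"n": int(depths.size), "median": float(med),
            "iqr": [float(q1), float(q3)],
            "range": [float(depths.min()), float(depths.max())]}


def apply_qc(counts: pd.DataFrame, config: QCConfig | None = None,
             batch_col: str | None = None,
             fixed_thresholds: QCReport | None = None):
    """Run contamination, lower-depth and upper-depth filters.

    ``counts`` needs columns plate_id, well_id, depth and a boolean
    is_negative_control; every plate must contain exactly one control
    well.  Filters run per batch (``batch_col``, defaulting to one batch
    for the whole table) on cell wells only.  Passing a previous report as
    ``fixed_thresholds`` re-applies its resolved thresholds instead of
    re-estimating them — the idempotent re-run mode.

    Returns ``(retained, report)``: the retained cell-well rows and a
    :class:`QCReport`.
    """
    config = config or QCConfig()
    required = {"plate_id", "well_id", "depth", "is_negative_control"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")

    ctrl = counts[counts["is_negative_control"]]
    per_plate_ctrl = ctrl.groupby("plate_id").size()
    all_plates = counts["plate_id"].unique()
    missing = [p for p in all_plates if p not in per_plate_ctrl.index]
    if missing:
        raise ValueError(f"plates missing a negative control: {missing}")
    if (per_plate_ctrl > 1).any():
        raise ValueError("plates with more than one negative control: "
                         f"{list(per_plate_ctrl[per_plate_ctrl > 1].index)}")

    report = QCReport(config=config)
    control_depths = dict(zip(ctrl["plate_id"], ctrl["depth"]))
    if fixed_thresholds is not None:
        bad_plates = list(fixed_thresholds.excluded_plates)
    else:
        bad_plates = flag_contaminated_plates(control_depths, config)
    report.excluded_plates = {
        p: f"negative-control depth {control_depths.get(p)} > "
           f"{config.negative_control_max_depth}" for p in bad_plates}

    cells = counts[~counts["is_negative_control"]].copy()
    on_bad_plate = cells["plate_id"].isin(bad_plates)

    if batch_col is None:
        batches = pd.Series("all", index=cells.index)
    else:
        batches = cells[batch_col].astype(str)

    low_mask = np.zeros(len(cells), dtype=bool)
    high_mask = np.zeros(len(cells), dtype=bool)
    for batch in batches.unique():
        in_batch = (batches == batch).to_numpy()
        usable = in_batch & ~on_bad_plate.to_numpy()
        depths = cells.loc[usable, "depth"].to_numpy()
        if depths.size == 0:
            continue
        if fixed_thresholds is not None:
            lo = fixed_thresholds.lower_thresholds[batch]
            hi = fixed_thresholds.upper_thresholds.get(batch, np.inf)
        else:
            lo = lower_depth_threshold(depths, config)
            if depths.size < 4:
                warnings.warn(f"batch {batch}: fewer than 4 depths; "
                              "skipping upper-depth rule")
                hi = np.inf
            else:
                hi = _upper_threshold(depths, config)
        report.lower_thresholds[batch] = float(lo)
        report.upper_thresholds[batch] = float(hi)
        d_all = cells["depth"].to_numpy(dtype=float)
        low_mask |= in_batch & (d_all < lo)
        high_mask |= in_batch & (d_all > hi)

    excluded = on_bad_plate.to_numpy() | low_mask | high_mask
    retained = cells[~excluded]
    for plate, grp in cells.groupby("plate_id"):
        sel = cells.index.isin(grp.index)
        report.per_plate[plate] = {
            "n_in": int(sel.sum()),
            "plate_excluded": plate in bad_plates,
            "n_low_depth": int((low_mask & sel & ~on_bad_plate.to_numpy()).sum()),
            "n_high_depth_excluded":
                int((high_mask & sel & ~low_mask & ~on_bad_plate.to_numpy()).sum()),
            "n_retained": int((~excluded & sel).sum()),
        }
    report.retained_cells = list(
        retained["plate_id"].str.cat(retained["well_id"], sep=":"))
    report.retained_depth_summary = depth_summary(retained["depth"])
    return retained, report
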