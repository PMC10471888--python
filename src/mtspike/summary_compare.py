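"""Posterior summaries and pairwise comparisons of near-zero proportions.

For each cell subset the posterior of the spike weight pi is summarised by
its peak estimate(s): the point mass at pi = 0 (reported as a mode when the
posterior probability of "no spike" is large enough) and the local maxima
of a boundary-corrected kernel density estimate of the continuous draws —
multiple modes are reported when the posterior is bi/multimodal.

Two subsets are called different when zero lies outside the 95%
equal-tailed credible interval of the posterior difference between their
proportions, formed by pairing draws across the two independent chains
iteration by iteration (pairing is arbitrary for independent posteriors;
a permutation option exists for sensitivity).  No multiple-testing
correction is applied across pairs; the report counts comparisons so users
can adjust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spike_mixture import PosteriorDraws

__all__ = [
    "PeakEstimate",
    "PairComparison",
    "peak_estimates",
    "credible_interval",
    "compare_pair",
    "gradient_report",
]


@dataclass
class PeakEstimate:
    modes: list                 # sorted pi values, 0.0 first if point mass
    heights: list               # density height (point mass reported as mass)
    bandwidth: float
    zero_mass: float            # posterior P(pi = 0)

    @property
    def primary_mode(self) -> float:
        """Mode with the greatest height/mass; ties go to the smaller pi."""
        order = np.lexsort((self.modes, [-h for h in self.heights]))
        return self.modes[order[0]]


@dataclass
class PairComparison:
    label_a: str
    label_b: str
    mean_diff: float
    ci_low: float
    ci_high: float
    significant: bool
    level: float
    pairing: str
    n_pairs: int


def _reflected_kde(x: np.ndarray, grid: np.ndarray, bandwidth: float):
    """Gaussian KDE on [0,1] with reflection at both boundaries."""
    pts = np.concatenate([x, -x, 2.0 - x])
    diff = (grid[:, None] - pts[None, :]) / bandwidth
    dens = np.exp(-0.5 * diff * diff).sum(axis=1)
    dens /= x.size * bandwidth * np.sqrt(2 * np.pi)
    return dens


def _silverman(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.quantile(x, [0.75, 0.25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        scale = max(sd, 1e-3)
    return 0.9 * scale * x.size ** (-0.2)


def peak_estimates(draws, *, bandwidth: float | None = None,
                   prominence_frac: float = 0.10,
                   zero_mass_threshold: float = 0.25,
                   grid_n: int = 512, min_draws: int = 1000) -> PeakEstimate:
    """Posterior mode(s) of pi from retained draws.

    ``draws`` is a :class:`PosteriorDraws` or a flat array of pi draws
    (zeros encode the "no spike" state).  The point mass at 0 becomes a
    mode when its posterior mass exceeds ``zero_mass_threshold``.
    Continuous modes are local maxima of a reflected-Gaussian KDE whose
    prominence exceeds ``prominence_frac`` of the global density maximum;
    bandwidth defaults to Silverman's plug-in rule.
    """
    pi = draws.pi_flat if isinstance(draws, PosteriorDraws) else \
        np.asarray(draws, dtype=float).reshape(-1)
    if pi.size < min_draws:
        raise ValueError(f"need at least {min_draws} draws, got {pi.size}")
    zero_mass = float(np.mean(pi == 0.0))
    cont = pi[pi > 0.0]
    modes: list[float] = []
    heights: list[float] = []
    bw = float("nan")
    if cont.size >= 50 and np.ptp(cont) > 0:
        bw = bandwidth if bandwidth is not None else _silverman(cont)
        grid = np.linspace(0.0, 1.0, grid_n)
        dens = _reflected_kde(cont, grid, bw)
        dens *= cont.size / pi.size  # scale by continuous mass
        peaks, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
        # interior plateau/boundary maxima that find_peaks misses
        if dens.argmax() not in peaks and dens.argmax() in (0, grid_n - 1):
            peaks = np.append(peaks, dens.argmax())
        modes = [float(grid[i]) for i in peaks]
        heights = [float(dens[i]) for i in peaks]
    elif cont.size:
        modes = [float(np.median(cont))]
        heights = [float("inf")]  # degenerate cluster
        bw = 0.0
    if zero_mass > zero_mass_threshold:
        modes.insert(0, 0.0)
        heights.insert(0, zero_mass * 50.0)  # mass on a ~1/50 visual scale
    order = np.argsort(modes)
    return PeakEstimate(modes=[modes[i] for i in order],
                        heights=[heights[i] for i in order],
                        bandwidth=bw, zero_mass=zero_mass)


def credible_interval(draws, level: float = 0.95):
    """Equal-tailed credible interval from posterior draws."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0,1)")
    x = draws.pi_flat if isinstance(draws, PosteriorDraws) else \
        np.asarray(draws, dtype=float).reshape(-1)
    if x.size < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def compare_pair(draws_a, draws_b, level: float = 0.95,
                 pairing: str = "iteration", seed: int | None = None,
                 label_a: str = "A", label_b: str = "B") -> PairComparison:
    """Posterior difference of proportions between two independent fits.

    Draw sequences are truncated to the shorter length and paired either in
    stored iteration order (default) or after a seeded permutation of the
    second sequence.  The pair is significant iff zero lies outside the
    equal-tailed ``level`` interval of the differences.
    """
    a = draws_a.pi_flat if isinstance(draws_a, PosteriorDraws) else \
        np.asarray(draws_a, dtype=float).reshape(-1)
    b = draws_b.pi_flat if isinstance(draws_b, PosteriorDraws) else \
        np.asarray(draws_b, dtype=float).reshape(-1)
    if a.size < 1000 or b.size < 1000:
        raise ValueError("each group needs at least 1000 draws")
    m = min(a.size, b.size)
    a, b = a[:m], b[:m]
    if pairing == "permutation":
        rng = np.random.default_rng(seed)
        b = b[rng.permutation(m)]
    elif pairing != "iteration":
        raise ValueError("pairing must be 'iteration' or 'permutation'")
    diff = a - b
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diff, [alpha, 1.0 - alpha], method="linear")
    return PairComparison(
        label_a=label_a, label_b=label_b, mean_diff=float(diff.mean()),
        ci_low=float(lo), ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi), level=level,
        pairing=pairing, n_pairs=m)


def gradient_report(fits: dict, order, groups=None, level: float = 0.95,
                    **peak_kwargs):
    """Ordered peak-estimate table plus within-group pairwise comparisons.

    ``fits`` maps (subject, cell_type) -> PosteriorDraws; ``order`` is the
    declared maturity order of cell types (e.g. naive -> CM -> EM ->
    TEMRA); ``groups`` is a list of cell-type lists within which all pairs
    are compared (default: one group containing the whole order).  Returns
    ``(summary, comparisons)`` DataFrames.
    """
    order = list(order)
    known = {ct for (_, ct) in fits}
    unknown = known - set(order)
    if unknown:
        raise ValueError(f"cell types not in declared order: {sorted(unknown)}")
    groups = [list(g) for g in (groups or [order])]
    rank = {ct: i for i, ct in enumerate(order)}

    summary_rows = []
    for (subject, ct), draws in sorted(
            fits.items(), key=lambda kv: (kv[0][0], rank[kv[0][1]])):
        pk = peak_estimates(draws, **peak_kwargs)
        lo, hi = credible_interval(draws, level)
        summary_rows.append({
            "subject": subject, "cell_type": ct,
            "primary_peak": pk.primary_mode,
            "modes": ";".join(f"{m:.4f}" for m in pk.modes),
            "zero_mass": pk.zero_mass, "mean_pi": draws.mean_pi
            if isinstance(draws, PosteriorDraws) else float(np.mean(draws)),
            "ci_low": lo, "ci_high": hi,
        })

    comp_rows = []
    subjects = sorted({s for (s, _) in fits})
    for subject in subjects:
        for group in groups:
            present = [ct for ct in group if (subject, ct) in fits]
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    a, b = present[i], present[j]
                    pc = compare_pair(fits[(subject, a)], fits[(subject, b)],
                                      level=level, label_a=a, label_b=b)
                    comp_rows.append({
                        "subject": subject, "cell_type_a": a, "cell_type_b": b,
                        "mean_diff": pc.mean_diff, "ci_low": pc.ci_low,
                        "ci_high": pc.ci_high, "significant": pc.significant,
                    })
    comparisons = pd.DataFrame(
        comp_rows, columns=["subject", "cell_type_a", "cell_type_b",
                            "mean_diff", "ci_low", "ci_high", "significant"])
    return pd.DataFrame(summary_rows), comparisons
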