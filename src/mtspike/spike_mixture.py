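"""Bayesian spike-and-slab mixture for single-cell mutation-load data.

Per-cell variant allele fractions Y in (0,1) are modelled as a two-component
mixture: a "spike" of cells with near-zero mutation load, described by a
normal distribution truncated to (0,1), and a "slab" of cells spread across
the whole range, described by a uniform on (0,1)::

    Y ~ pi * N01(mu, sigma^2) + (1 - pi) * U(0, 1)
    pi ~ pi0 * delta_0 + (1 - pi0) * U(0, 1)

The spike weight pi itself carries a point mass at zero: with prior
probability pi0 there is no spike at all.  Priors are mu ~ U(0, 0.2),
sigma ~ Exp(5) and pi0 ~ U(0, 1).  Because pi0 enters the posterior only
through its mean, it is integrated out analytically: the prior probability
of "no spike" is E[pi0] = 1/2.

Two independent routes to the posterior are provided:

* :func:`fit_mcmc` — a Gibbs/Metropolis sampler with explicit per-cell
  allocations and a trans-model move between {no spike} and {spike present}
  whose acceptance ratio uses the allocation-summed (marginal) likelihood,
  so it is valid from any state.
* :func:`grid_posterior` — a deterministic dense-quadrature oracle over
  (pi, mu, sigma), exact up to grid resolution, used to validate the
  sampler and usable directly for small cell subsets.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import log_ndtr, logsumexp

__all__ = [
    "MixtureModelSpec",
    "PosteriorDraws",
    "GridPosterior",
    "spike_density",
    "log_spike_density",
    "log_likelihood",
    "nudge_boundary",
    "fit_mcmc",
    "grid_posterior",
    "split_rhat",
]


@dataclass(frozen=True)
class MixtureModelSpec:
    """Priors of the mixture model.

    mu_max : upper bound of the uniform prior on the spike mean (default 0.2).
    sigma_rate : rate of the exponential prior on the spike SD (default 5).
    The spike-absence probability pi0 is uniform on [0,1] and integrated out;
    the slab is uniform on (0,1).  Both are fixed by the model.
    """

    mu_max: float = 0.2
    sigma_rate: float = 5.0

    def __post_init__(self) -> None:
        if not (self.mu_max > 0 and self.sigma_rate > 0):
            raise ValueError("mu_max and sigma_rate must be positive")

    @property
    def prior_p_no_spike(self) -> float:
        """Marginal prior P(pi = 0) = E[pi0] = 1/2 under pi0 ~ U(0,1)."""
        return 0.5


@dataclass
class PosteriorDraws:
    """Retained MCMC draws for one cell subset, all chains concatenated.

    Arrays have shape (n_chains, n_draws_per_chain).  ``s`` is the
    spike-presence indicator; ``pi`` is exactly 0 wherever ``s`` is 0.
    """

    s: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def pi_flat(self) -> np.ndarray:
        return self.pi.reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.pi.size

    @property
    def p_no_spike(self) -> float:
        """Posterior P(s = 0 | Y) estimated as the fraction of s=0 draws."""
        return float(np.mean(self.s == 0))

    @property
    def mean_pi(self) -> float:
        return float(np.mean(self.pi))

    def pi_cdf(self, t) -> np.ndarray:
        """Empirical posterior CDF of pi (point mass at 0 included)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        flat = np.sort(self.pi_flat)
        return np.searchsorted(flat, t, side="right") / flat.size


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def log_spike_density(y, mu, sigma):
    """Log density of N(mu, sigma^2) truncated to (0,1), elementwise in y.

    log f(y) = log phi((y-mu)/sigma) - log sigma
               - log[Phi((1-mu)/sigma) - Phi((0-mu)/sigma)]

    Returns -inf outside (0,1).  The normaliser is computed via
    ``log_ndtr`` for stability far in the tails.
    """
    y = np.asarray(y, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = (0.0 - mu) / sigma
    b = (1.0 - mu) / sigma
    # log(Phi(b) - Phi(a)) = log_ndtr(b) + log1p(-exp(log_ndtr(a)-log_ndtr(b)))
    la, lb = log_ndtr(a), log_ndtr(b)
    log_z = lb + np.log1p(-np.exp(la - lb))
    z = (y - mu) / sigma
    out = -0.5 * z * z - 0.5 * math.log(2 * math.pi) - math.log(sigma) - log_z
    return np.where((y > 0) & (y < 1), out, -np.inf)


def spike_density(y, mu, sigma):
    """Density of the truncated-normal spike on (0,1); 0 outside."""
    with np.errstate(invalid="ignore"):
        out = np.exp(log_spike_density(y, mu, sigma))
    return out


def log_likelihood(y, pi, mu, sigma):
    """Allocation-summed log likelihood sum_i log[pi f(y_i) + (1-pi)].

    The slab contributes density 1 on (0,1), so at pi=0 the log likelihood
    is exactly 0 for any data inside the unit interval.
    """
    y = np.asarray(y, dtype=float)
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0,1]")
    if np.any(~np.isfinite(y)) or np.any((y <= 0) | (y >= 1)):
        raise ValueError("all observations must lie strictly in (0,1)")
    if pi == 0.0:
        return 0.0
    log_f = log_spike_density(y, mu, sigma)
    if pi == 1.0:
        return float(np.sum(log_f))
    return float(np.sum(np.logaddexp(math.log(pi) + log_f,
                                     math.log1p(-pi))))


def nudge_boundary(vaf, depth):
    """Map exact-boundary VAFs into (0,1) by half a read: 0 -> 1/(2d), 1 -> 1 - 1/(2d).

    Both mixture components have support (0,1); a cell whose finite read
    counts happen to be all-reference or all-variant would otherwise have
    zero density under the model.  Returns (nudged values, n_nudged).
    """
    vaf = np.asarray(vaf, dtype=float).copy()
    depth = np.broadcast_to(np.asarray(depth, dtype=float), vaf.shape)
    if np.any(depth < 1):
        raise ValueError("depth must be >= 1 to nudge boundary values")
    eps = 1.0 / (2.0 * depth)
    lo = vaf <= 0.0
    hi = vaf >= 1.0
    vaf[lo] = eps[lo]
    vaf[hi] = 1.0 - eps[hi]
    return vaf, int(np.sum(lo) + np.sum(hi))


# ---------------------------------------------------------------------------
# MCMC sampler
# ---------------------------------------------------------------------------

def _run_chain(y, spec, n_iter, burn_in, thin, rng, mu_step, log_sigma_step):
    n = y.size
    mu_max = spec.mu_max
    rate = spec.sigma_rate

    # initial state: spike present, moderate parameters
    s = 1
    pi = 0.5
    mu = 0.5 * mu_max
    sigma = 1.0 / rate
    log_f = log_spike_density(y, mu, sigma) if n else np.empty(0)
    z = np.zeros(n, dtype=bool)

    n_keep = (n_iter - burn_in) // thin
    out_s = np.empty(n_keep, dtype=np.int8)
    out_pi = np.empty(n_keep)
    out_mu = np.empty(n_keep)
    out_sigma = np.empty(n_keep)
    acc_mu = acc_sigma = acc_trans = 0
    try_mu = try_sigma = try_trans = 0
    k = 0

    def loglik_marg(pi_, log_f_):
        if n == 0 or pi_ == 0.0:
            return 0.0
        return float(np.sum(np.logaddexp(math.log(pi_) + log_f_,
                                         math.log1p(-pi_) if pi_ < 1 else -np.inf)))

    for it in range(n_iter):
        # -- allocations and spike weight (only meaningful when a spike exists)
        if s == 1 and n > 0:
            with np.errstate(over="ignore"):
                odds = pi * np.exp(log_f)
            p_spike = odds / (odds + (1.0 - pi))
            z = rng.random(n) < p_spike
            n_sp = int(z.sum())
            pi = rng.beta(n_sp + 1, n - n_sp + 1)
        elif s == 1:
            pi = rng.beta(1, 1)
        else:
            z[:] = False
            pi = 0.0

        y_sp = y[z]
        if y_sp.size == 0:
            # conditional for (mu, sigma) is the prior: draw exactly
            mu = rng.uniform(0.0, mu_max)
            sigma = rng.standard_exponential() / rate
            if n:
                log_f = log_spike_density(y, mu, sigma)
        else:
            cur = float(np.sum(log_spike_density(y_sp, mu, sigma)))
            # mu: random-walk proposal reflected into [0, mu_max]
            try_mu += 1
            prop = mu + mu_step * rng.standard_normal()
            prop = abs(prop)
            if prop > mu_max:
                prop = 2 * mu_max - prop
            prop = min(max(prop, 0.0), mu_max)
            new = float(np.sum(log_spike_density(y_sp, prop, sigma)))
            if math.log(rng.random()) < new - cur:
                mu = prop
                cur = new
                acc_mu += 1
            # sigma: log-scale random walk, Exp(rate) prior, Jacobian = sigma
            try_sigma += 1
            prop_s = sigma * math.exp(log_sigma_step * rng.standard_normal())
            new = float(np.sum(log_spike_density(y_sp, mu, prop_s)))
            log_a = (new - cur
                     - rate * (prop_s - sigma)
                     + math.log(prop_s) - math.log(sigma))
            if math.log(rng.random()) < log_a:
                sigma = prop_s
                acc_sigma += 1
            log_f = log_spike_density(y, mu, sigma)

        # -- trans-model move using the marginal (allocation-summed) likelihood;
        #    pi* is proposed from its U(0,1) prior so priors cancel and the
        #    acceptance ratio is the marginal likelihood ratio.  Attempted
        #    with probability 1/2: a certain flip would make the chain
        #    periodic when the data carry no information (prior sampling).
        if rng.random() < 0.5:
            try_trans += 1
            if s == 0:
                pi_prop = rng.uniform(0.0, 1.0)
                log_a = loglik_marg(pi_prop, log_f)  # loglik at pi=0 is 0
                if math.log(rng.random()) < log_a:
                    s, pi = 1, pi_prop
                    acc_trans += 1
            else:
                log_a = -loglik_marg(pi, log_f)
                if math.log(rng.random()) < log_a:
                    s, pi = 0, 0.0
                    z[:] = False
                    acc_trans += 1

        if it >= burn_in and (it - burn_in) % thin == 0:
            out_s[k] = s
            out_pi[k] = pi
            out_mu[k] = mu
            out_sigma[k] = sigma
            k += 1

    acc = {
        "mu": acc_mu / max(try_mu, 1),
        "sigma": acc_sigma / max(try_sigma, 1),
        "trans": acc_trans / max(try_trans, 1),
    }
    return out_s[:k], out_pi[:k], out_mu[:k], out_sigma[:k], acc


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential-scale-reduction diagnostic.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half,
    and the classic between/within variance ratio is returned.  Values near
    1 indicate the chains agree; > ~1.05 warrants suspicion.
    """
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def fit_mcmc(
    y,
    spec: MixtureModelSpec | None = None,
    *,
    n_iter: int = 30_000,
    burn_in: int = 10_000,
    thin: int = 4,
    n_chains: int = 4,
    seed: int = 0,
    mu_step: float = 0.02,
    log_sigma_step: float = 0.4,
    rhat_warn: float = 1.05,
) -> PosteriorDraws:
    """Sample the joint posterior of (s, pi, mu, sigma) given VAFs ``y``.

    ``y`` may be empty, in which case the sampler targets the prior
    (P(s=0) = 1/2, pi | spike uniform).  Values must lie strictly inside
    (0,1); use :func:`nudge_boundary` upstream for exact 0/1 VAFs, and divide
    by 100 first if loads are given in percent.

    Each iteration performs (i) per-cell allocation updates z | pi, mu,
    sigma, (ii) a conjugate Beta(n_spike+1, n_slab+1) update of pi, (iii)
    Metropolis updates of mu (reflected at [0, mu_max]) and sigma (log
    scale) — drawn exactly from the prior when no cell is allocated to the
    spike — and (iv) a trans-model move between s=0 and s=1 accepted with
    the marginal-likelihood ratio.

    Chain seeds are spawned deterministically from ``seed``.  A split-chain
    R-hat on pi above ``rhat_warn`` triggers a warning (never silent
    failure) and is stored in ``meta``.
    """
    spec = spec or MixtureModelSpec()
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.size and (np.any(~np.isfinite(y)) or np.any((y < 0) | (y > 1))):
        raise ValueError("VAFs must be finite and in [0,1]")
    if y.size and np.any((y <= 0) | (y >= 1)):
        raise ValueError(
            "VAFs exactly 0 or 1 have zero density under the model; "
            "apply nudge_boundary() with the cell's read depth first"
        )
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")

    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    ss, pis, mus, sigmas = [], [], [], []
    accs = []
    for cs in child_seeds:
        rng = np.random.default_rng(cs)
        out = _run_chain(y, spec, n_iter, burn_in, thin, rng,
                         mu_step, log_sigma_step)
        ss.append(out[0]); pis.append(out[1]); mus.append(out[2])
        sigmas.append(out[3]); accs.append(out[4])

    draws = PosteriorDraws(
        s=np.stack(ss), pi=np.stack(pis), mu=np.stack(mus),
        sigma=np.stack(sigmas),
        meta={
            "seed": seed, "n_iter": n_iter, "burn_in": burn_in,
            "thin": thin, "n_chains": n_chains,
            "acceptance": accs, "model": dataclasses.asdict(spec),
        },
    )
    rhat = split_rhat(draws.pi) if n_chains > 1 else float("nan")
    draws.meta["rhat_pi"] = rhat
    if np.isfinite(rhat) and rhat > rhat_warn:
        warnings.warn(
            f"split-chain R-hat on pi is {rhat:.3f} (> {rhat_warn}); "
            "chains may not have converged", RuntimeWarning)
    return draws


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------

@dataclass
class GridPosterior:
    """Deterministic quadrature posterior for one cell subset.

    ``pi_grid``/``pi_weights`` describe the continuous (spike-present) part
    of pi's marginal; ``p_no_spike`` is the point mass at pi = 0.
    """

    p_no_spike: float
    pi_grid: np.ndarray
    pi_weights: np.ndarray       # normalised over the continuous part
    mu_grid: np.ndarray
    mu_weights: np.ndarray
    sigma_grid: np.ndarray
    sigma_weights: np.ndarray

    @property
    def mean_pi(self) -> float:
        return float((1.0 - self.p_no_spike) * np.sum(self.pi_grid * self.pi_weights))

    def pi_cdf(self, t) -> np.ndarray:
        """P(pi <= t): point mass at 0 plus the continuous quadrature mass."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        cont = np.cumsum(self.pi_weights)
        idx = np.searchsorted(self.pi_grid, t, side="right")
        cont_at = np.where(idx > 0, cont[np.minimum(idx, cont.size) - 1], 0.0)
        return self.p_no_spike + (1.0 - self.p_no_spike) * cont_at


def _log_lik_grid(y, pi_grid, mu_grid, sigma_grid):
    """log L(pi, mu, sigma) on the full grid, shape (Gpi, Gmu, Gsig)."""
    n = y.size
    gm, gs = mu_grid.size, sigma_grid.size
    log_f = np.empty((n, gm, gs))
    for j, mu in enumerate(mu_grid):
        for k_, sg in enumerate(sigma_grid):
            log_f[:, j, k_] = log_spike_density(y, mu, sg)
    out = np.empty((pi_grid.size, gm, gs))
    for i, pi in enumerate(pi_grid):
        out[i] = np.logaddexp(math.log(pi) + log_f,
                              math.log1p(-pi)).sum(axis=0)
    return out


def grid_posterior(
    y,
    spec: MixtureModelSpec | None = None,
    *,
    n_pi: int = 160,
    n_mu: int = 60,
    n_sigma: int = 60,
    check_refinement: bool = False,
    refine_tol: float = 1e-3,
) -> GridPosterior:
    """Dense-quadrature posterior over (pi, mu, sigma) with the pi=0 point mass.

    The prior over each coordinate is handled by placing grid nodes at
    mid-quantiles of that prior (uniform for pi and mu, Exp(rate) for
    sigma) with equal weights, so every grid average is a prior
    expectation.  Then

        P(s=0 | Y) = (1/2) / [ (1/2) + (1/2) * E_prior L(pi, mu, sigma) ]

    since the slab-only likelihood is identically 1 and the uniform pi0
    prior contributes E[pi0] = 1/2.  The continuous marginal of pi is the
    (mu, sigma)-averaged likelihood, normalised.

    Intended for small subsets (guideline n <= 200).  With
    ``check_refinement`` the computation is repeated at double resolution
    and a ``ResolutionError`` is raised if P(s=0) moves by more than
    ``refine_tol``.
    """
    spec = spec or MixtureModelSpec()
    y = np.asarray(y, dtype=float).reshape(-1)
    if y.size and (np.any(~np.isfinite(y)) or np.any((y <= 0) | (y >= 1))):
        raise ValueError("all observations must lie strictly in (0,1)")

    def solve(n_pi, n_mu, n_sigma):
        pi_grid = (np.arange(n_pi) + 0.5) / n_pi
        mu_grid = spec.mu_max * (np.arange(n_mu) + 0.5) / n_mu
        sigma_grid = stats.expon.ppf((np.arange(n_sigma) + 0.5) / n_sigma,
                                     scale=1.0 / spec.sigma_rate)
        if y.size == 0:
            w = np.full(n_pi, 1.0 / n_pi)
            return 0.5, pi_grid, w, mu_grid, sigma_grid, None
        log_l = _log_lik_grid(y, pi_grid, mu_grid, sigma_grid)
        log_mean = logsumexp(log_l) - math.log(log_l.size)
        p0 = 1.0 / (1.0 + math.exp(log_mean))
        log_w = logsumexp(log_l, axis=(1, 2))
        w = np.exp(log_w - logsumexp(log_w))
        return p0, pi_grid, w, mu_grid, sigma_grid, log_l

    p0, pi_grid, w, mu_grid, sigma_grid, log_l = solve(n_pi, n_mu, n_sigma)
    if check_refinement:
        p0_fine = solve(2 * n_pi, 2 * n_mu, 2 * n_sigma)[0]
        if abs(p0_fine - p0) > refine_tol:
            raise ResolutionError(
                f"grid too coarse: P(s=0) moved by {abs(p0_fine - p0):.2e} "
                f"under refinement (tol {refine_tol:g})")

    if log_l is not None:
        lw_mu = logsumexp(log_l, axis=(0, 2))
        lw_sg = logsumexp(log_l, axis=(0, 1))
        mu_w = np.exp(lw_mu - logsumexp(lw_mu))
        sg_w = np.exp(lw_sg - logsumexp(lw_sg))
    else:
        mu_w = np.full(mu_grid.size, 1.0 / mu_grid.size)
        sg_w = np.full(sigma_grid.size, 1.0 / sigma_grid.size)

    return GridPosterior(
        p_no_spike=p0, pi_grid=pi_grid, pi_weights=w,
        mu_grid=mu_grid, mu_weights=mu_w,
        sigma_grid=sigma_grid, sigma_weights=sg_w,
    )


class ResolutionError(RuntimeError):
    """Raised when grid refinement shows the quadrature is not converged."""
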