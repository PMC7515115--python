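"""Bayesian mutual-information estimator for asymmetric discrete variables.

Model
-----
Y (few states, well sampled) has empirical marginal ``q̂_y``; the conditionals
``q_{y|x}`` of the many, undersampled x states are given an i.i.d. Dirichlet
prior centered at ``q̂_y`` with concentration β.  Large β means conditionals
huddle around the marginal (little information); small β pushes them to the
corners of the simplex (much information).  The β-marginal likelihood of the
counts is available in closed form and develops a peak as soon as the data
contain a few coincidences — x states sampled at least twice.  The posterior
mean and variance of I given β are then closed-form digamma/trigamma
expressions, evaluated either at the maximum-likelihood β (default) or
integrated over an information-uniform prior on log β (mandatory when the
evidence holds ≤ 2 coincidences).

An optional Dirichlet-process prior on the x marginal (concentration α)
shifts part of the posterior weight toward the prior information, accounting
for never-observed x states.

All internal math is in nats and log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp, polygamma, psi, xlogy

from .baselines import plugin_entropy
from .counts import CountsTable, Multiplicities, multiplicities_from_counts

__all__ = [
    "HyperParams",
    "PosteriorSummary",
    "NoPeakError",
    "log_marginal_likelihood_beta",
    "beta_map",
    "prior_mean_information",
    "posterior_mean_information",
    "posterior_variance_information",
    "log_beta_prior",
    "log_marginal_likelihood_alpha",
    "alpha_map",
    "posterior_mean_information_dp",
    "estimate",
    "default_beta_grid",
    "sample_beta_from_prior",
]

LN2 = float(np.log(2.0))

# log-spaced beta grid bounds and size; the +inf sentinel is evaluated at
# BETA_INF_EVAL where a numeric value is needed.
BETA_GRID_LO = 1e-4
BETA_GRID_HI = 1e5
BETA_GRID_SIZE = 400
BETA_INF_EVAL = 1e12

ALPHA_GRID_LO = 1e-2
ALPHA_GRID_HI = 1e8
ALPHA_GRID_SIZE = 400


class NoPeakError(ValueError):
    """The β likelihood has no interior peak (no coincidences in the data)."""


@dataclass(frozen=True)
class HyperParams:
    """Concentration hyper-parameters and the Dirichlet center.

    beta:   conditional concentration (>0, or +inf sentinel).
    alpha:  optional Dirichlet-process concentration for the x marginal.
    center: the Y marginal the conditional prior is centered at (simplex).
    """

    beta: float
    center: np.ndarray
    alpha: float | None = None

    def __post_init__(self):
        center = np.asarray(self.center, dtype=float)
        object.__setattr__(self, "center", center)
        if not (self.beta > 0):
            raise ValueError("beta must be positive")
        if self.alpha is not None and not (self.alpha > 0):
            raise ValueError("alpha must be positive")
        if (center <= 0).any() or abs(center.sum() - 1.0) > 1e-9:
            raise ValueError("center must be a strictly positive simplex vector")


def _center_of(c: CountsTable, center=None) -> np.ndarray:
    if center is None:
        return c.q_y_hat
    center = np.asarray(center, dtype=float)
    if center.size != c.k_y:
        raise ValueError("center length must equal k_y")
    return center


# ---------------------------------------------------------------------------
# beta marginal likelihood


def _loglike_patterns(patterns: np.ndarray, mult: np.ndarray, center: np.ndarray,
                      betas: np.ndarray) -> np.ndarray:
    """β-dependent part of log p(n|β), grouped over multiplicity patterns.

    patterns: (P, k_y) counts; mult: (P,) multiplicities; betas: (B,).
    Returns (B,) log likelihoods.
    """
    b = betas[:, None, None]                        # (B,1,1)
    a = b * center[None, None, :]                   # (B,1,k_y)
    r = patterns.sum(axis=1)[None, :]               # (1,P)
    per_state = (
        gammaln(betas)[:, None]
        - gammaln(r + betas[:, None])
        + (gammaln(patterns[None, :, :] + a) - gammaln(a)).sum(axis=2)
    )                                               # (B,P)
    return per_state @ mult


def log_marginal_likelihood_beta(c: CountsTable | Multiplicities, beta,
                                 center=None) -> float | np.ndarray:
    """β-dependent part of log p(n|β) (the likelihood is stated up to a
    β-free constant)::

        sum_x [ log Γ(β) - log Γ(n_x + β)
                + sum_y ( log Γ(n_xy + β q̂_y) - log Γ(β q̂_y) ) ]

    Accepts a CountsTable or its Multiplicities (grouped form; identical
    result).  ``beta`` may be a scalar or an array.
    """
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    if (beta_arr <= 0).any():
        raise ValueError("beta must be positive")
    if isinstance(c, Multiplicities):
        if center is None:
            if not c.symmetric:
                raise ValueError("asymmetric multiplicities need an explicit center")
            center = np.full(c.k_y, 1.0 / c.k_y)
        patterns = np.array(sorted(c.table), dtype=float)
        mult = np.array([c.table[tuple(int(v) for v in p)] for p in patterns], dtype=float)
    else:
        center = _center_of(c, center)
        m = multiplicities_from_counts(c)
        # grouped evaluation is exact for the symmetric-canonical patterns
        # only when the center is symmetric; otherwise patterns keep y order
        patterns = np.array(sorted(m.table), dtype=float)
        mult = np.array([m.table[tuple(int(v) for v in p)] for p in patterns], dtype=float)
    center = np.asarray(center, dtype=float)
    out = _loglike_patterns(patterns, mult, center, beta_arr)
    return float(out[0]) if np.isscalar(beta) or np.ndim(beta) == 0 else out


def default_beta_grid(num: int = BETA_GRID_SIZE) -> np.ndarray:
    return np.geomspace(BETA_GRID_LO, BETA_GRID_HI, num)


def beta_map(m: Multiplicities, c: CountsTable | None = None, center=None,
             grid: np.ndarray | None = None) -> float:
    """β maximizing the marginal likelihood p(n|β).

    For binary symmetric data with at most pairwise coincidences the closed
    form applies: with f11 the fraction of 2-count states split one-and-one,
    β* = f11 / (1/2 - f11) for f11 < 1/2 and +inf otherwise.  In all other
    cases the log-likelihood is maximized numerically on a log-β grid with
    golden-section refinement; both routes agree to 1e-6 relative where both
    apply.

    Raises :class:`NoPeakError` when the data contain no coincidences (the
    likelihood is then flat in β and has no interior peak).
    """
    if m.coincidences == 0:
        raise NoPeakError("no coincidences: the beta likelihood has no peak")
    if m.k_y == 2 and m.symmetric and m.max_count <= 2 and center is None:
        f11 = m.f11
        if f11 is None:  # cannot happen with coincidences > 0 and max_count <= 2
            raise NoPeakError("no 2-count states")
        if f11 >= 0.5:
            return np.inf
        if f11 == 0.0:
            # boundary: likelihood increases toward beta -> 0
            return BETA_GRID_LO
        return f11 / (0.5 - f11)
    if center is None:
        if c is not None:
            center = c.q_y_hat
        elif m.symmetric:
            center = np.full(m.k_y, 1.0 / m.k_y)
        else:
            raise ValueError("asymmetric multiplicities need a center or table")
    center = np.asarray(center, dtype=float)
    if grid is None:
        grid = default_beta_grid()
    ll = log_marginal_likelihood_beta(m, grid, center=center)
    i = int(np.argmax(ll))
    if i == len(grid) - 1:
        # increasing up to the top of the grid: treat as +inf
        return np.inf
    if i == 0:
        return float(grid[0])
    lo, hi = np.log(grid[i - 1]), np.log(grid[i + 1])
    res = minimize_scalar(
        lambda lb: -log_marginal_likelihood_beta(m, float(np.exp(lb)), center=center),
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-12},
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# posterior moments of the information


def prior_mean_information(h: HyperParams) -> float:
    """Expected information under the prior alone (no data)::

        <I|0,β> = H(q̂_y) - ψ0(β+1) + Σ_y q̂_y ψ0(β q̂_y + 1)

    Strictly decreasing in β; tends to H(q̂_y) as β→0 and to 0 as β→∞.
    """
    if np.isinf(h.beta):
        return 0.0
    q = h.center
    return float(plugin_entropy(q) - psi(h.beta + 1) + q @ psi(h.beta * q + 1))


def _row_posterior_params(c: CountsTable, h: HyperParams):
    a = h.beta * h.center[None, :] + c.counts        # (k_x, k_y)
    A = h.beta + c.n_x                               # (k_x,)
    return a, A


def posterior_mean_information(c: CountsTable, h: HyperParams) -> float:
    """Posterior expected information at fixed β::

        <I|n,β> = Ĥ(Y) - Σ_x (n_x/N) [ ψ0(β+n_x+1)
                  - Σ_y (β q̂_y + n_xy)/(β + n_x) ψ0(β q̂_y + n_xy + 1) ]

    Ĥ(Y) is the plug-in marginal entropy (Y is presumed well sampled).  At
    the β=+inf sentinel all conditionals are pinned at the center and the
    information is 0.
    """
    if np.isinf(h.beta):
        return 0.0
    a, A = _row_posterior_params(c, h)
    h_rows = psi(A + 1) - ((a / A[:, None]) * psi(a + 1)).sum(axis=1)
    hy = plugin_entropy(c.q_y_hat)
    return float(hy - c.q_x_hat @ h_rows)


def _dirichlet_entropy_moments(a: np.ndarray, A: np.ndarray):
    """Mean and variance of the Shannon entropy of Dirichlet(a) rows.

    a: (k_x, k_y) concentration rows, A their totals.  Closed forms via the
    first two posterior moments of -Σ q log q (digamma/trigamma algebra).
    """
    Acol = A[:, None]
    mean = psi(A + 1) - ((a / Acol) * psi(a + 1)).sum(axis=1)
    psiA2 = psi(A + 2)[:, None]
    t1A2 = polygamma(1, A + 2)[:, None]
    di1 = psi(a + 1) - psiA2
    di2 = psi(a + 2) - psiA2
    J = di2 ** 2 + polygamma(1, a + 2) - t1A2
    s1 = (a * di1).sum(axis=1)
    s2 = (a ** 2 * di1 ** 2).sum(axis=1)
    cross = s1 ** 2 - s2 - t1A2[:, 0] * (A ** 2 - (a ** 2).sum(axis=1))
    second = (cross + (a * (a + 1) * J).sum(axis=1)) / (A * (A + 1))
    var = np.maximum(second - mean ** 2, 0.0)
    return mean, var


def posterior_variance_information(c: CountsTable, h: HyperParams) -> float:
    """Posterior variance of the information at fixed β (nats²).

    With Ĥ(Y) treated as a constant and the per-state conditionals
    a-posteriori independent Dirichlet(β q̂_y + n_x·), the variance is the
    quadratically weighted sum of per-state entropy variances::

        σ²(I|n,β) = Σ_x (n_x/N)² Var[H(q_{y|x})]

    Replicating the same multiplicity pattern over more states halves the
    weights faster than it adds terms, so the variance scales as 1/k_x.
    """
    if np.isinf(h.beta):
        return 0.0
    a, A = _row_posterior_params(c, h)
    _, var_rows = _dirichlet_entropy_moments(a, A)
    w = c.q_x_hat
    return float((w ** 2 * var_rows).sum())


# ---------------------------------------------------------------------------
# prior on log beta (information-uniform)


def log_beta_prior(beta: float, center) -> float:
    """Log density (in log β) of the information-uniform prior::

        p(log β) = β |Σ_y q̂_y² ψ1(β q̂_y + 1) - ψ1(β + 1)| / H(q̂_y)

    i.e. |d <I|0,β> / d log β| normalized by the total prior-information
    range H(q̂_y); for the symmetric binary center this is
    β/(2 log 2) |2 ψ1(β+1) - ψ1(β/2+1)|.  Integrates to 1 over β ∈ (0, ∞).
    """
    if np.ndim(beta) == 0 and beta <= 0:
        raise ValueError("beta must be positive")
    q = np.asarray(center, dtype=float)
    b = np.asarray(beta, dtype=float)
    h = plugin_entropy(q)
    if h <= 0:
        raise ValueError("degenerate center: H(center) = 0")
    slope = b * np.abs(
        (q ** 2 * polygamma(1, np.multiply.outer(b, q) + 1)).sum(axis=-1)
        - polygamma(1, b + 1)
    )
    out = np.log(slope) - np.log(h)
    return float(out) if np.ndim(beta) == 0 else out


def sample_beta_from_prior(center, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw β from the information-uniform prior by inverting the monotone
    map β ↦ <I|0,β>: u ~ U(0, H(center)) and β solves <I|0,β> = u."""
    q = np.asarray(center, dtype=float)
    h = plugin_entropy(q)
    lgrid = np.linspace(np.log(1e-8), np.log(1e12), 4001)
    bgrid = np.exp(lgrid)
    info = plugin_entropy(q) - psi(bgrid + 1) + (q[None, :] * psi(bgrid[:, None] * q + 1)).sum(axis=1)
    # info is strictly decreasing in beta
    u = rng.uniform(0.0, h, size=size)
    lb = np.interp(u, info[::-1], lgrid[::-1])
    return np.exp(lb)


# ---------------------------------------------------------------------------
# Dirichlet-process prior on the x marginal


def log_marginal_likelihood_alpha(c: CountsTable, alpha) -> float | np.ndarray:
    """α-dependent part of log p(n_x|α) under a DP(α) prior on q_x::

        log Γ(1+α) - log Γ(N+α) + (k1 - 1) log α

    (the Pitman–Yor evidence with zero discount), where k1 is the number of
    observed x states.
    """
    a = np.asarray(alpha, dtype=float)
    if (a <= 0).any():
        raise ValueError("alpha must be positive")
    m = multiplicities_from_counts(c)
    out = gammaln(1 + a) - gammaln(c.N + a) + (m.k1 - 1) * np.log(a)
    return float(out) if np.ndim(alpha) == 0 else out


def alpha_map(c: CountsTable, grid: np.ndarray | None = None) -> tuple[float, bool]:
    """MAP of α on a log grid.  Returns (alpha, diverged): ``diverged`` is
    True when the likelihood is still increasing at the top of the grid
    (no coincidences — every sample opened a new state)."""
    if grid is None:
        grid = np.geomspace(ALPHA_GRID_LO, ALPHA_GRID_HI, ALPHA_GRID_SIZE)
    ll = log_marginal_likelihood_alpha(c, grid)
    i = int(np.argmax(ll))
    # the top of the grid within float noise of the max means the likelihood
    # is still climbing at alpha -> inf (every sample opened a new state)
    if i == len(grid) - 1 or ll.max() - ll[-1] < 1e-6:
        return float(grid[-1]), True
    if i == 0:
        return float(grid[0]), False
    res = minimize_scalar(
        lambda la: -log_marginal_likelihood_alpha(c, float(np.exp(la))),
        bounds=(np.log(grid[i - 1]), np.log(grid[i + 1])),
        method="bounded", options={"xatol": 1e-10},
    )
    return float(np.exp(res.x)), False


def posterior_mean_information_dp(c: CountsTable, h: HyperParams) -> float:
    """Posterior mean information with a DP(α) prior on the x marginal::

        <I|n,α,β> = N/(N+α) <I|n,β>_observed + α/(N+α) <I|0,β>

    The unobserved states contribute the prior information, weighted by the
    fraction of posterior mass the DP assigns to new states.
    """
    if h.alpha is None:
        raise ValueError("HyperParams.alpha required for the DP-corrected mean")
    w = c.N / (c.N + h.alpha)
    return float(w * posterior_mean_information(c, h) + (1 - w) * prior_mean_information(h))


# ---------------------------------------------------------------------------
# the full estimator


@dataclass
class PosteriorSummary:
    """Posterior summary of the mutual information for one counts table."""

    I_mean: float
    I_sd: float
    beta_map: float
    method: str                      # "map" or "integrate"
    HY_hat: float
    units: str = "nats"
    alpha_map: float | None = None
    beta_grid: np.ndarray | None = None
    beta_loglike: np.ndarray | None = None
    N: int = 0
    k1: int = 0
    coincidences: int = 0
    f11: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "I_mean": self.I_mean,
            "I_sd": self.I_sd,
            "units": self.units,
            "beta_map": ("inf" if np.isinf(self.beta_map) else self.beta_map),
            "alpha_map": self.alpha_map,
            "method": self.method,
            "HY_hat": self.HY_hat,
            "N": self.N,
            "k1": self.k1,
            "coincidences": self.coincidences,
            "f11": self.f11,
            "warnings": list(self.warnings),
        }


def _integrate_over_beta(c: CountsTable, center: np.ndarray,
                         grid: np.ndarray) -> tuple[float, float]:
    """Posterior mean and variance of I integrating over the log-β grid with
    the information-uniform prior; trapezoid weights in log β."""
    logw = log_marginal_likelihood_beta(c, grid, center=center) + log_beta_prior(grid, center)
    trap = np.ones(len(grid))
    trap[0] = trap[-1] = 0.5
    logw = logw + np.log(trap)
    w = np.exp(logw - logsumexp(logw))
    keep = w > 1e-14
    w = w[keep] / w[keep].sum()
    means = np.empty(w.size)
    vars_ = np.empty(w.size)
    for j, b in enumerate(grid[keep]):
        h = HyperParams(beta=float(b), center=center)
        means[j] = posterior_mean_information(c, h)
        vars_[j] = posterior_variance_information(c, h)
    mean = float(w @ means)
    var = float(w @ (vars_ + means ** 2) - mean ** 2)
    return mean, max(var, 0.0)


def estimate(
    c: CountsTable,
    method: str | None = None,
    dp: bool = False,
    units: str = "nats",
    beta_grid: np.ndarray | None = None,
    min_ny_warn: int = 10,
) -> PosteriorSummary:
    """Estimate the mutual information of a counts table.

    method:
        "map" evaluates the posterior moments at the β maximizing the
        marginal likelihood; "integrate" averages over the information-
        uniform prior on log β.  Default (None) uses MAP, falling back to
        integration whenever the data hold ≤ 2 coincidences (too little
        evidence for a well-defined likelihood peak).
    dp:
        additionally infer a DP concentration α for the x marginal and mix
        the prior information in with weight α/(N+α).
    """
    if units not in ("nats", "bits"):
        raise ValueError("units must be 'nats' or 'bits'")
    warns: list[str] = []
    if (c.n_y == 0).any():
        keep = c.n_y > 0
        dropped = [y for y, k in zip(c.y_ids, keep) if not k]
        warns.append(f"y categories with zero counts dropped: {dropped}")
        c = CountsTable(c.x_ids, tuple(y for y, k in zip(c.y_ids, keep) if k),
                        c.counts[:, keep])
    if c.k_y < 2:
        warns.append("k_y = 1: Y is constant, information is 0 by definition")
        return PosteriorSummary(0.0, 0.0, np.inf, "map", 0.0, units=units,
                                N=c.N, k1=c.k_x, coincidences=0, warnings=warns)
    if c.n_y.min() < min_ny_warn:
        warns.append(
            f"Y may be undersampled (min n_y = {int(c.n_y.min())}); "
            "the estimator presumes a well-sampled Y marginal"
        )
    center = c.q_y_hat
    m = multiplicities_from_counts(c)
    grid = default_beta_grid() if beta_grid is None else beta_grid
    loglike = log_marginal_likelihood_beta(c, grid, center=center)

    chosen = method
    if chosen is None:
        chosen = "integrate" if m.coincidences <= 2 else "map"
        if m.coincidences <= 2 and method is None:
            warns.append(
                f"only {m.coincidences} coincidence(s); integrating over the prior on log beta"
            )

    try:
        b_star = beta_map(m, c, grid=grid)
    except NoPeakError:
        b_star = np.inf
        warns.append("no coincidences; the beta likelihood has no peak")
        chosen = "integrate"

    if chosen == "map":
        if np.isinf(b_star):
            i_mean, i_var = 0.0, 0.0
            warns.append("beta* = +inf (data look independent); information estimate is 0")
        else:
            h = HyperParams(beta=b_star, center=center)
            i_mean = posterior_mean_information(c, h)
            i_var = posterior_variance_information(c, h)
    elif chosen == "integrate":
        i_mean, i_var = _integrate_over_beta(c, center, grid)
    else:
        raise ValueError(f"unknown method {chosen!r}")

    a_star = None
    if dp:
        a_star, diverged = alpha_map(c)
        if diverged:
            warns.append("alpha MAP diverged (no coincidences); DP correction disabled")
            a_star = None
        elif not np.isinf(b_star) and chosen == "map":
            h = HyperParams(beta=b_star, center=center, alpha=a_star)
            i_mean = posterior_mean_information_dp(c, h)
        elif chosen == "integrate":
            w = c.N / (c.N + a_star)
            # mix the prior information in, beta-averaged with the same weights
            logw = loglike + log_beta_prior(grid, center)
            ww = np.exp(logw - logsumexp(logw))
            prior_terms = np.array([
                prior_mean_information(HyperParams(beta=float(b), center=center)) for b in grid
            ])
            i_mean = w * i_mean + (1 - w) * float(ww @ prior_terms)

    hy = plugin_entropy(center)
    i_mean = max(float(i_mean), 0.0)
    i_sd = float(np.sqrt(max(i_var, 0.0)))
    scale = 1.0 if units == "nats" else 1.0 / LN2
    return PosteriorSummary(
        I_mean=i_mean * scale,
        I_sd=i_sd * scale,
        beta_map=b_star,
        alpha_map=a_star,
        method=chosen,
        HY_hat=hy * scale,
        units=units,
        beta_grid=grid,
        beta_loglike=loglike,
        N=c.N,
        k1=m.k1,
        coincidences=m.coincidences,
        f11=m.f11,
        warnings=warns,
    )
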