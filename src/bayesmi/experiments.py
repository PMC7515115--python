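"""Benchmark curves and the Bayesian calibration study, at desk scale.

``bias_vs_samples`` and ``bias_vs_information`` reproduce the benchmark
protocol: fix a ground-truth joint model, sample tables repeatedly, and
compare estimator means/SDs against the exact information.

``calibration_study`` checks the Bayesian semantics of the posterior
moments: many joint distributions are drawn from the generative ensemble
the estimator's prior describes (DP marginal, Beta conditionals with an
information-uniform concentration), a handful of small samples is taken
from each, cases are grouped by their multiplicity set, and the empirical
mean/SD of the true information within each class is compared against the
posterior mean/SD predicted from the multiplicities alone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .baselines import plugin_information
from .counts import CountsTable, counts_from_samples
from .estimator import (
    HyperParams,
    _integrate_over_beta,
    default_beta_grid,
    estimate,
    sample_beta_from_prior,
)
from .generators import (
    ParityModel,
    make_parity_model,
    make_py_beta_model,
    make_sphere_model,
    sample_beta_conditionals,
    sample_counts,
    sample_py_marginal,
)

__all__ = [
    "BiasCurveResult",
    "CalibrationResult",
    "default_estimators",
    "bias_vs_samples",
    "bias_vs_information",
    "calibration_study",
]


def default_estimators() -> dict:
    return {
        "bayes": lambda c: estimate(c).I_mean,
        "plugin": plugin_information,
    }


@dataclass
class BiasCurveResult:
    """Mean and SD of each estimator across replicates, per grid point."""

    grid_name: str
    grid: np.ndarray
    truth: np.ndarray
    means: dict[str, np.ndarray]
    sds: dict[str, np.ndarray]
    replicates: int
    seed: int
    failures: dict[str, int] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.grid):
            for name in self.means:
                rows.append({
                    self.grid_name: g,
                    "truth": self.truth[i],
                    "estimator": name,
                    "mean": self.means[name][i],
                    "sd": self.sds[name][i],
                })
        return pd.DataFrame(rows)


def _run_replicates(model, n: int, replicates: int, estimators: dict,
                    seeds) -> tuple[dict, dict, dict]:
    vals: dict[str, list] = defaultdict(list)
    fails: Counter = Counter()
    for r in range(replicates):
        c = sample_counts(model, n, seed=np.random.default_rng(seeds[r]))
        for name, fn in estimators.items():
            try:
                vals[name].append(float(fn(c)))
            except Exception:
                fails[name] += 1
                vals[name].append(np.nan)
    means = {k: float(np.nanmean(v)) for k, v in vals.items()}
    sds = {k: float(np.nanstd(v)) for k, v in vals.items()}
    return means, sds, dict(fails)


def bias_vs_samples(model, n_grid, replicates: int = 50, estimators: dict | None = None,
                    seed: int = 0) -> BiasCurveResult:
    """Estimates of I as a function of the number of samples N, for a fixed
    ground-truth model; truth is the model's exact information."""
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    estimators = default_estimators() if estimators is None else estimators
    n_grid = np.asarray(list(n_grid), dtype=int)
    ss = np.random.SeedSequence(seed)
    truth = float(model.information)
    means = {k: [] for k in estimators}
    sds = {k: [] for k in estimators}
    failures: Counter = Counter()
    for n, child in zip(n_grid, ss.spawn(len(n_grid))):
        m, s, f = _run_replicates(model, int(n), replicates, estimators, child.spawn(replicates))
        for k in estimators:
            means[k].append(m[k])
            sds[k].append(s[k])
        failures.update(f)
    return BiasCurveResult(
        grid_name="N", grid=n_grid, truth=np.full(len(n_grid), truth),
        means={k: np.array(v) for k, v in means.items()},
        sds={k: np.array(v) for k, v in sds.items()},
        replicates=replicates, seed=seed, failures=dict(failures),
    )


def bias_vs_information(family: str, sweep, n: int, replicates: int = 50,
                        estimators: dict | None = None, seed: int = 0,
                        **family_kwargs) -> BiasCurveResult:
    """Bias as a function of the true information, swept via the family's
    information-controlling parameter: the conditional concentration β for
    ``py_beta``, the sigmoid gain for ``sphere``, q0 for ``parity``.

    For ``py_beta`` the x marginal is drawn once and shared across the sweep;
    fresh conditionals are drawn per sweep point.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    estimators = default_estimators() if estimators is None else estimators
    sweep = np.asarray(list(sweep), dtype=float)
    ss = np.random.SeedSequence(seed)
    gen_rng = np.random.default_rng(ss.spawn(1)[0])

    if family == "py_beta":
        d = family_kwargs.pop("d", 0.55)
        alpha = family_kwargs.pop("alpha", 50.0)
        q_x = sample_py_marginal(d, alpha, seed=gen_rng, **family_kwargs)

        def model_for(value):
            from .baselines import JointModel
            q_cond = sample_beta_conditionals(value, np.array([0.5, 0.5]), q_x.size, seed=gen_rng)
            return JointModel(q_x, q_cond)
    elif family == "sphere":
        def model_for(value):
            return make_sphere_model(target_info=None, gain=value, **family_kwargs)
    elif family == "parity":
        def model_for(value):
            return make_parity_model(q0=float(value), seed=int(gen_rng.integers(2 ** 31)),
                                     **family_kwargs)
    else:
        raise ValueError(f"unknown family {family!r}")

    truth, means, sds = [], {k: [] for k in estimators}, {k: [] for k in estimators}
    failures: Counter = Counter()
    for value, child in zip(sweep, ss.spawn(len(sweep))):
        model = model_for(value)
        truth.append(float(model.information))
        m, s, f = _run_replicates(model, n, replicates, estimators, child.spawn(replicates))
        for k in estimators:
            means[k].append(m[k])
            sds[k].append(s[k])
        failures.update(f)
    return BiasCurveResult(
        grid_name=("beta" if family == "py_beta" else "gain" if family == "sphere" else "q0"),
        grid=sweep, truth=np.array(truth),
        means={k: np.array(v) for k, v in means.items()},
        sds={k: np.array(v) for k, v in sds.items()},
        replicates=replicates, seed=seed, failures=dict(failures),
    )


# ---------------------------------------------------------------------------
# calibration study


@dataclass
class CalibrationResult:
    """Per-multiplicity-class comparison of empirical vs predicted moments."""

    total_cases: int
    coverage_top: float              # fraction of cases in the top_k classes
    top_k: int
    classes: pd.DataFrame            # key, count, emp_mean, emp_sd, pred_mean, pred_sd
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return self.classes


def _multiplicity_key(n1: np.ndarray, n0: np.ndarray) -> tuple:
    pats = Counter()
    for a, b in zip(n1.tolist(), n0.tolist()):
        pats[(max(a, b), min(a, b))] += 1
    return tuple(sorted(pats.items()))


def _canonical_table(key: tuple) -> CountsTable:
    """Rebuild a counts table from a multiplicity class, splitting each
    pattern's states as evenly as possible between the two y columns so the
    empirical Y marginal is as balanced as the class allows."""
    rows = []
    for (n, nprime), mult in key:
        for i in range(mult):
            rows.append((n, nprime) if i % 2 == 0 else (nprime, n))
    counts = np.array(rows, dtype=np.int64)
    # balance the columns further by greedily flipping asymmetric rows
    for i in np.argsort(-(counts[:, 0] - counts[:, 1])):
        diff = counts[:, 0].sum() - counts[:, 1].sum()
        if diff > 0 and counts[i, 0] > counts[i, 1] and diff >= counts[i, 0] - counts[i, 1]:
            counts[i] = counts[i, ::-1]
    labels = tuple(f"x{i}" for i in range(len(rows)))
    return CountsTable(labels, (0, 1), counts)


def calibration_study(
    n_models: int = 13500,
    sets_per_model: int = 5,
    n: int = 40,
    alphas=(np.exp(4), np.exp(5), np.exp(6)),
    seed: int = 0,
    top_k: int = 100,
    truncation: float = 1e-8,
) -> CalibrationResult:
    """Draw ``n_models`` joint distributions (q_x ~ DP(α) with α equiprobable
    over ``alphas``; binary conditionals Beta(β/2, β/2) with log β from the
    information-uniform prior), take ``sets_per_model`` samples of size ``n``
    from each, group the resulting cases by multiplicity set, and compare the
    empirical mean/SD of the true information within each of the ``top_k``
    most frequent classes against the posterior mean/SD predicted from the
    multiplicities (integrated over the prior on log β)."""
    rng = np.random.default_rng(seed)
    center = np.array([0.5, 0.5])
    alphas = np.asarray(alphas, dtype=float)
    betas = sample_beta_from_prior(center, n_models, rng)

    cases: dict[tuple, list[float]] = defaultdict(list)
    for i in range(n_models):
        a = float(alphas[rng.integers(len(alphas))])
        q_x = sample_py_marginal(0.0, a, truncation=truncation, seed=rng)
        q1 = rng.beta(betas[i] / 2, betas[i] / 2, size=q_x.size)
        q_y1 = float(q_x @ q1)
        h_cond = -(xlogy(q1, q1) + xlogy(1 - q1, 1 - q1))
        h_y = float(-(xlogy(q_y1, q_y1) + xlogy(1 - q_y1, 1 - q_y1)))
        true_i = float(h_y - q_x @ h_cond)
        cum = np.cumsum(q_x)
        for _ in range(sets_per_model):
            xs = np.searchsorted(cum, rng.random(n), side="right")
            xs = np.minimum(xs, q_x.size - 1)
            ys = rng.random(n) < q1[xs]
            uniq, inv = np.unique(xs, return_inverse=True)
            n1 = np.bincount(inv, weights=ys).astype(int)
            n0 = np.bincount(inv, weights=~ys).astype(int)
            cases[_multiplicity_key(n1, n0)].append(true_i)

    total = sum(len(v) for v in cases.values())
    ranked = sorted(cases.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]
    covered = sum(len(v) for _, v in ranked)
    grid = default_beta_grid()
    rows = []
    for key, truths in ranked:
        tbl = _canonical_table(key)
        pred_mean, pred_var = _integrate_over_beta(tbl, center, grid)
        truths = np.asarray(truths)
        rows.append({
            "key": str(key),
            "count": truths.size,
            "emp_mean": float(truths.mean()),
            "emp_sd": float(truths.std(ddof=1)) if truths.size > 1 else np.nan,
            "pred_mean": pred_mean,
            "pred_sd": float(np.sqrt(pred_var)),
        })
    return CalibrationResult(
        total_cases=total,
        coverage_top=covered / total,
        top_k=top_k,
        classes=pd.DataFrame(rows),
        seed=seed,
    )
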