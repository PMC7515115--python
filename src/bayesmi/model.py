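"""Model/Results interface over the estimator, in the statsmodels idiom.

``MutualInfoModel`` is built from contingency data (a :class:`CountsTable`,
paired samples, a DataFrame or a file); ``fit`` returns a
:class:`MutualInfoResults` carrying the posterior mean and SD of the mutual
information, the selected hyper-parameters, diagnostics and a ``summary()``
table.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import counts as _counts
from .baselines import plugin_information
from .counts import CountsTable, Multiplicities, counts_from_samples, multiplicities_from_counts
from .estimator import (
    PosteriorSummary,
    estimate,
    log_marginal_likelihood_alpha,
    log_marginal_likelihood_beta,
)

__all__ = ["MutualInfoModel", "MutualInfoResults"]


class MutualInfoModel:
    """Bayesian mutual-information model for a counts table.

    Parameters
    ----------
    counts : CountsTable
        Observed contingency data; one row per observed x state, one column
        per y category.  Y should be well sampled (few categories, large
        column totals); X may be severely undersampled.

    Examples
    --------
    >>> model = MutualInfoModel.from_pairs([("a", 0), ("a", 1), ("b", 0), ("b", 0)])
    >>> res = model.fit()
    >>> res.info  # doctest: +SKIP
    """

    def __init__(self, counts: CountsTable):
        if not isinstance(counts, CountsTable):
            raise TypeError("counts must be a CountsTable; see the from_* constructors")
        self.counts = counts

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs, y_ids=None) -> "MutualInfoModel":
        return cls(counts_from_samples(pairs, y_ids=y_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, y: str, count: str | None = None
                       ) -> "MutualInfoModel":
        """Build from a long DataFrame: one row per sample (``count`` None)
        or per (x, y) cell with a count column."""
        if count is None:
            return cls.from_pairs(list(zip(df[x], df[y])))
        pivot = df.pivot_table(index=x, columns=y, values=count, aggfunc="sum", fill_value=0)
        pivot = pivot.sort_index().sort_index(axis=1)
        return cls(CountsTable(tuple(pivot.index), tuple(pivot.columns), pivot.to_numpy()))

    @classmethod
    def from_file(cls, path, format: str = "long") -> "MutualInfoModel":
        reader = {"long": _counts.read_long_tsv, "dense": _counts.read_dense_csv,
                  "pairs": _counts.read_pairs}.get(format)
        if reader is None:
            raise ValueError(f"unknown format {format!r}; choose long, dense or pairs")
        return cls(reader(path))

    # -- model surface -----------------------------------------------------
    @property
    def multiplicities(self) -> Multiplicities:
        return multiplicities_from_counts(self.counts)

    def loglike_beta(self, beta):
        """β-marginal log likelihood of the data (up to a β-free constant)."""
        return log_marginal_likelihood_beta(self.counts, beta)

    def loglike_alpha(self, alpha):
        """α-marginal log likelihood of the x occupation pattern (DP prior)."""
        return log_marginal_likelihood_alpha(self.counts, alpha)

    def fit(self, method: str | None = None, dp: bool = False, units: str = "nats",
            **kwargs) -> "MutualInfoResults":
        """Fit the model; see :func:`bayesmi.estimator.estimate` for options."""
        summary = estimate(self.counts, method=method, dp=dp, units=units, **kwargs)
        return MutualInfoResults(self, summary)


class MutualInfoResults:
    """Posterior estimates of the mutual information and diagnostics."""

    def __init__(self, model: MutualInfoModel, summary: PosteriorSummary):
        self.model = model
        self._summary = summary

    # -- primary estimates -------------------------------------------------
    @property
    def info(self) -> float:
        """Posterior mean mutual information."""
        return self._summary.I_mean

    @property
    def info_sd(self) -> float:
        """Posterior standard deviation of the mutual information."""
        return self._summary.I_sd

    @property
    def units(self) -> str:
        return self._summary.units

    @property
    def beta_map(self) -> float:
        return self._summary.beta_map

    @property
    def alpha_map(self) -> float | None:
        return self._summary.alpha_map

    @property
    def method(self) -> str:
        return self._summary.method

    @property
    def HY_hat(self) -> float:
        return self._summary.HY_hat

    @property
    def warnings(self) -> list[str]:
        return list(self._summary.warnings)

    @property
    def beta_profile(self) -> pd.DataFrame:
        """The β grid with its marginal log likelihood."""
        return pd.DataFrame({"beta": self._summary.beta_grid,
                             "loglike": self._summary.beta_loglike})

    def conf_int(self, z: float = 1.96) -> tuple[float, float]:
        """Central posterior interval from a normal approximation, floored
        at 0 (the information cannot be negative)."""
        return (max(self.info - z * self.info_sd, 0.0), self.info + z * self.info_sd)

    @property
    def plugin(self) -> float:
        """Plug-in information of the same table, for reference."""
        scale = 1.0 if self.units == "nats" else 1.0 / np.log(2.0)
        return plugin_information(self.model.counts) * scale

    def to_dict(self) -> dict:
        return self._summary.to_dict()

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        s = self._summary
        lo, hi = self.conf_int()
        c = self.model.counts
        lines = [
            "        Bayesian Mutual Information",
            "=" * 46,
            f"I (posterior mean)    {s.I_mean:12.6f} {s.units}",
            f"I (posterior sd)      {s.I_sd:12.6f} {s.units}",
            f"95% interval          [{lo:.6f}, {hi:.6f}]",
            f"H(Y) plug-in          {s.HY_hat:12.6f} {s.units}",
            f"plug-in I             {self.plugin:12.6f} {s.units}",
            "-" * 46,
            f"beta (MAP)            {'+inf' if np.isinf(s.beta_map) else format(s.beta_map, '12.6g')}",
            f"alpha (MAP)           {s.alpha_map if s.alpha_map is not None else '---'}",
            f"method                {s.method}",
            f"N                     {s.N}",
            f"observed x states     {s.k1}  (k_y = {c.k_y})",
            f"coincidences          {s.coincidences}",
            f"f11                   {s.f11 if s.f11 is not None else '---'}",
            "=" * 46,
        ]
        for w in s.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<MutualInfoResults I={self.info:.4f}±{self.info_sd:.4f} "
                f"{self.units}, beta*={self.beta_map:g}, method={self.method}>")
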