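"""Reference quantities: plug-in entropies/information and exact information
of fully specified joint models.

The plug-in estimator substitutes observed frequencies for probabilities.
It is consistent but, for mutual information in the undersampled regime, it
is biased upward — the motivating failure mode for the Bayesian estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr, xlogy

from .counts import CountsTable

__all__ = ["JointModel", "plugin_entropy", "plugin_information", "true_information"]


def plugin_entropy(freqs, miller_madow: bool = False, n: int | None = None) -> float:
    """Shannon entropy (nats) of a probability vector, with 0 log 0 = 0.

    ``miller_madow`` adds the (k-1)/(2n) first-order bias correction; this is
    offered only for context and is not used anywhere by the estimator.
    """
    q = np.asarray(freqs, dtype=float)
    if (q < 0).any():
        raise ValueError("negative probabilities")
    s = q.sum()
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {s}, not 1")
    h = float(-xlogy(q, q).sum())
    if miller_madow:
        if n is None:
            raise ValueError("Miller-Madow correction requires the sample size n")
        h += (np.count_nonzero(q) - 1) / (2 * n)
    return h


def plugin_information(c: CountsTable) -> float:
    """Plug-in mutual information (nats): H(X) + H(Y) - H(X,Y) from frequencies."""
    q_xy = c.counts / c.N
    h_x = plugin_entropy(q_xy.sum(axis=1))
    h_y = plugin_entropy(q_xy.sum(axis=0))
    h_xy = float(-xlogy(q_xy, q_xy).sum())
    return max(h_x + h_y - h_xy, 0.0)


@dataclass(frozen=True)
class JointModel:
    """Ground-truth joint distribution q_xy = q_x * q_{y|x} with exact entropies.

    Used to validate generators and to provide the truth in benchmark curves.
    """

    q_x: np.ndarray          # (k_x,)
    q_cond: np.ndarray       # (k_x, k_y) rows on the simplex

    def __post_init__(self):
        qx = np.asarray(self.q_x, dtype=float)
        qc = np.asarray(self.q_cond, dtype=float)
        object.__setattr__(self, "q_x", qx)
        object.__setattr__(self, "q_cond", qc)
        if qx.ndim != 1 or qc.ndim != 2 or qc.shape[0] != qx.size:
            raise ValueError("inconsistent shapes")
        if (qx < 0).any() or (qc < 0).any():
            raise ValueError("negative probabilities")
        if abs(qx.sum() - 1.0) > 1e-9:
            raise ValueError("q_x must sum to 1")
        if np.abs(qc.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("rows of q_cond must sum to 1")

    @property
    def k_x(self) -> int:
        return self.q_x.size

    @property
    def k_y(self) -> int:
        return self.q_cond.shape[1]

    @property
    def q_y(self) -> np.ndarray:
        return self.q_x @ self.q_cond

    @property
    def H_x(self) -> float:
        return plugin_entropy(self.q_x)

    @property
    def H_y(self) -> float:
        return plugin_entropy(self.q_y)

    @property
    def H_y_given_x(self) -> float:
        return float(self.q_x @ (-xlogy(self.q_cond, self.q_cond)).sum(axis=1))

    @property
    def H_xy(self) -> float:
        return self.H_x + self.H_y_given_x

    @property
    def information(self) -> float:
        return true_information(self)

    def sample_pairs(self, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
        """Draw n i.i.d. (x, y) pairs, labels being integer state indices."""
        cum = np.cumsum(self.q_x)
        xs = np.searchsorted(cum, rng.random(n), side="right")
        xs = np.minimum(xs, self.k_x - 1)
        ccond = np.cumsum(self.q_cond, axis=1)
        ys = (ccond[xs] < rng.random(n)[:, None]).sum(axis=1)
        return list(zip(xs.tolist(), ys.tolist()))


def true_information(m: JointModel) -> float:
    """Exact mutual information I(X;Y) = sum_x q_x D_KL(q_{y|x} || q_y), in nats.

    Agrees with H(Y) - H(Y|X) to 1e-12 by construction; the KL form is used
    because it is non-negative term by term.
    """
    q_y = m.q_y
    kl_rows = rel_entr(m.q_cond, q_y[None, :]).sum(axis=1)
    return float(m.q_x @ kl_rows)
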