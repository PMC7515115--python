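"""Contingency data and multiplicity sufficient statistics.

The estimator operates on paired observations of a severely undersampled
discrete variable X and a well-sampled discrete variable Y.  The data enter
through the contingency table ``n_xy`` (one row per *observed* x state) and,
for hyper-parameter inference, only through the *multiplicities*: the number
of x states sharing a given per-y count pattern.  States sampled once carry
no evidence about the concentration hyper-parameter; only coincidences
(states with two or more samples) do.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import psi

__all__ = [
    "CountsTable",
    "Multiplicities",
    "counts_from_samples",
    "multiplicities_from_counts",
    "conditional_entropy_by_multiplicities",
    "binary_pattern_entropy",
    "read_long_tsv",
    "read_dense_csv",
    "read_pairs",
    "write_long_tsv",
    "write_dense_csv",
    "write_pairs",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class CountsTable:
    """Observed contingency table with one row per observed x state.

    Unobserved x states are never stored; their posterior weight is handled
    by the Dirichlet-process correction in the estimator.  Y categories that
    were declared but never observed are dropped (with a warning): the method
    presumes Y well sampled, and a zero marginal makes the Dirichlet center
    singular.
    """

    x_ids: tuple
    y_ids: tuple
    counts: np.ndarray  # (k_x, k_y) non-negative ints

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if c.shape != (len(self.x_ids), len(self.y_ids)):
            raise ValueError("counts shape does not match label lists")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("empty table: N = 0")
        if (c.sum(axis=1) == 0).any():
            raise ValueError("every stored x row must have n_x >= 1")

    # -- marginals ---------------------------------------------------------
    @property
    def n_x(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n_y(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def k_x(self) -> int:
        return len(self.x_ids)

    @property
    def k_y(self) -> int:
        return len(self.y_ids)

    @property
    def q_x_hat(self) -> np.ndarray:
        return self.n_x / self.N

    @property
    def q_y_hat(self) -> np.ndarray:
        return self.n_y / self.N

    @property
    def symmetric_center(self) -> bool:
        """True when the empirical Y marginal is uniform to float tolerance."""
        return bool(np.all(np.abs(self.q_y_hat - 1.0 / self.k_y) < _SYMMETRY_TOL))


def counts_from_samples(
    pairs: Sequence[tuple],
    y_ids: Sequence | None = None,
) -> CountsTable:
    """Tally paired samples ``(x_label, y_label)`` into a :class:`CountsTable`.

    Rows and columns are ordered lexicographically by label (ties cannot
    occur: labels are keys).  A declared ``y_ids`` entry never observed is
    dropped with a warning rather than kept with a singular zero marginal.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no samples given")
    tally: Counter = Counter(pairs)
    xs = sorted({x for x, _ in tally}, key=lambda v: str(v))
    obs_y = {y for _, y in tally}
    if y_ids is None:
        ys = sorted(obs_y, key=lambda v: str(v))
    else:
        declared = list(y_ids)
        missing = [y for y in declared if y not in obs_y]
        if missing:
            warnings.warn(
                f"declared y categories never observed and dropped: {missing}",
                stacklevel=2,
            )
        ys = sorted((y for y in declared if y in obs_y), key=lambda v: str(v))
        extra = obs_y - set(declared)
        if extra:
            raise ValueError(f"observed y labels not in declared set: {sorted(map(str, extra))}")
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: j for j, y in enumerate(ys)}
    mat = np.zeros((len(xs), len(ys)), dtype=np.int64)
    for (x, y), c in tally.items():
        mat[xi[x], yi[y]] += c
    return CountsTable(tuple(xs), tuple(ys), mat)


@dataclass(frozen=True)
class Multiplicities:
    """Multiplicity sufficient statistics of a :class:`CountsTable`.

    ``table`` maps a per-y count pattern (a k_y tuple) to the number of x
    states exhibiting it.  When the empirical Y marginal is symmetric the
    pattern is canonicalised by sorting descending (the likelihood is then
    invariant under permuting the y slots); otherwise the y order is kept.
    """

    table: Mapping[tuple, int]
    k_y: int
    N: int
    symmetric: bool

    @property
    def k1(self) -> int:
        """Number of observed x states."""
        return int(sum(self.table.values()))

    @property
    def coincidences(self) -> int:
        """Number of x states with two or more samples."""
        return int(sum(m for pat, m in self.table.items() if sum(pat) >= 2))

    @property
    def max_count(self) -> int:
        return max(sum(pat) for pat in self.table)

    def m(self, *pattern: int) -> int:
        """Multiplicity of a pattern; symmetric lookup when the center is."""
        key = tuple(sorted(pattern, reverse=True)) if self.symmetric else tuple(pattern)
        return int(self.table.get(key, 0))

    @property
    def f11(self) -> float | None:
        """Fraction of 2-count states with one sample of each y value.

        Defined for binary Y only when at least one 2-count state exists.
        Near 1/2 under independence, small under strong dependence.
        """
        if self.k_y != 2:
            return None
        m11 = self.m(1, 1)
        two = m11 + self.m(2, 0) + (0 if self.symmetric else self.m(0, 2))
        if two == 0:
            return None
        return m11 / two

    @property
    def f_r(self) -> dict[int, float]:
        """Fraction of the N samples falling in x states with r counts."""
        out: dict[int, float] = {}
        for pat, m in self.table.items():
            r = sum(pat)
            out[r] = out.get(r, 0.0) + r * m / self.N
        return out

    @property
    def f_pattern(self) -> dict[tuple, float]:
        """Within each total r, the fraction of r-count states per pattern."""
        per_r: dict[int, int] = {}
        for pat, m in self.table.items():
            per_r[sum(pat)] = per_r.get(sum(pat), 0) + m
        return {pat: m / per_r[sum(pat)] for pat, m in self.table.items()}

    def to_json(self) -> str:
        payload = {
            "k_y": self.k_y,
            "N": self.N,
            "symmetric": self.symmetric,
            "k1": self.k1,
            "coincidences": self.coincidences,
            "f11": self.f11,
            "multiplicities": [
                {"pattern": list(pat), "count": m} for pat, m in sorted(self.table.items())
            ],
        }
        return json.dumps(payload, indent=1)


def multiplicities_from_counts(c: CountsTable) -> Multiplicities:
    sym = c.symmetric_center
    tab: Counter = Counter()
    for row in c.counts:
        pat = tuple(sorted(row, reverse=True)) if sym else tuple(int(v) for v in row)
        tab[tuple(int(v) for v in pat)] += 1
    return Multiplicities(dict(tab), k_y=c.k_y, N=c.N, symmetric=sym)


def binary_pattern_entropy(n: int, nprime: int, beta: float) -> float:
    """Posterior expected entropy of a symmetric binary conditional after
    observing counts ``{n, n'}``::

        H_nn'(b) = psi(n + n' + b + 1)
                   - [(n + b/2) psi(n + b/2 + 1) + (n' + b/2) psi(n' + b/2 + 1)]
                     / (n + n' + b)

    in nats.  Satisfies H_00 = H_10 (a lone extra count is no evidence of
    imbalance) and tends to log 2 as b -> infinity.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = n + nprime
    num = (n + beta / 2) * psi(n + beta / 2 + 1) + (nprime + beta / 2) * psi(nprime + beta / 2 + 1)
    return float(psi(r + beta + 1) - num / (r + beta))


def conditional_entropy_by_multiplicities(m: Multiplicities, beta: float) -> float:
    """Grouped evaluation of the posterior conditional entropy <H(Y|X)>(beta)
    for symmetric binary Y: sum_r f_r sum_{n+n'=r} f_nn' H_nn'(beta).

    Must agree (to float tolerance) with the per-state sum over the table.
    """
    if m.k_y != 2:
        raise ValueError("multiplicity form of the conditional entropy requires binary Y")
    if not m.symmetric:
        raise ValueError("multiplicity form requires a symmetric Y marginal")
    f_r = m.f_r
    f_pat = m.f_pattern
    total = 0.0
    for pat, fp in f_pat.items():
        r = sum(pat)
        total += f_r[r] * fp * binary_pattern_entropy(pat[0], pat[1], beta)
    return total


# ---------------------------------------------------------------------------
# readers / writers


def read_long_tsv(path) -> CountsTable:
    """Long-format TSV with header columns x_id, y_id, count."""
    df = pd.read_csv(path, sep="\t", dtype={"x_id": str, "y_id": str})
    for col in ("x_id", "y_id", "count"):
        if col not in df.columns:
            raise ValueError(f"long TSV requires column {col!r}")
    pivot = df.pivot_table(index="x_id", columns="y_id", values="count", aggfunc="sum", fill_value=0)
    pivot = pivot.sort_index().sort_index(axis=1)
    return CountsTable(tuple(pivot.index), tuple(pivot.columns), pivot.to_numpy())


def read_dense_csv(path) -> CountsTable:
    """Dense CSV: first column x labels, remaining columns one per y label."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.sort_index().sort_index(axis=1)
    return CountsTable(tuple(df.index), tuple(df.columns), df.to_numpy())


def read_pairs(path) -> CountsTable:
    """Two whitespace-separated columns per line: x label, y label."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise ValueError(f"malformed pair line: {line!r}")
            pairs.append((parts[0], parts[1]))
    return counts_from_samples(pairs)


def write_long_tsv(c: CountsTable, path) -> None:
    rows = [
        {"x_id": str(x), "y_id": str(y), "count": int(c.counts[i, j])}
        for i, x in enumerate(c.x_ids)
        for j, y in enumerate(c.y_ids)
        if c.counts[i, j] > 0
    ]
    pd.DataFrame(rows, columns=["x_id", "y_id", "count"]).to_csv(path, sep="\t", index=False)


def write_dense_csv(c: CountsTable, path) -> None:
    pd.DataFrame(c.counts, index=[str(x) for x in c.x_ids], columns=[str(y) for y in c.y_ids]).to_csv(path)


def write_pairs(c: CountsTable, path) -> None:
    with open(path, "w") as fh:
        for i, x in enumerate(c.x_ids):
            for j, y in enumerate(c.y_ids):
                for _ in range(int(c.counts[i, j])):
                    fh.write(f"{x} {y}\n")
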