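"""Synthetic joint distributions and samplers for benchmarking.

Three benchmark families, in increasing order of mismatch with the
estimator's Dirichlet prior:

* ``py_beta`` — heavy-tailed Pitman–Yor marginal over x, symmetric Beta
  conditionals.  This is exactly the world the prior describes.
* ``sphere`` — 12 points on a sphere, x a subset of them (4096 equiprobable
  states), conditional probability a sigmoid of a rotation-invariant
  spherical-spectrum score.  The conditional ensemble is rough but the
  marginal structure is benign.
* ``parity`` — x a sparse Bernoulli bit vector of dimension 40, conditionals
  a three-atom mixture keyed to the parity of the bit sum.  No single
  Dirichlet concentration describes all three atoms.

A fourth family (``dp_beta``: Dirichlet-process marginal with Beta
conditionals) backs the Bayesian calibration study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import sph_harm_y
from scipy.special import expit

from .baselines import JointModel
from .counts import CountsTable, counts_from_samples

__all__ = [
    "GeneratorConfig",
    "sample_py_marginal",
    "sample_beta_conditionals",
    "make_py_beta_model",
    "make_sphere_model",
    "sphere_scores",
    "icosahedron_vertices",
    "ParityModel",
    "make_parity_model",
    "sample_counts",
    "py_expected_entropy",
    "build_model",
]

DEFAULT_TRUNCATION = 1e-8
DEFAULT_MAX_ATOMS = 1 << 20


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Pitman-Yor / Dirichlet-process marginals


def sample_py_marginal(
    d: float,
    alpha: float,
    truncation: float = DEFAULT_TRUNCATION,
    seed=None,
    max_atoms: int = DEFAULT_MAX_ATOMS,
) -> np.ndarray:
    """Draw one probability vector from a Pitman–Yor process by stick
    breaking: V_i ~ Beta(1-d, alpha + i*d), w_i = V_i * prod_{j<i}(1-V_j).

    Breaking stops when the residual stick mass falls below ``truncation``
    or ``max_atoms`` sticks have been broken (the cap binds for heavy tails:
    with discount d the residual only decays like k^{-(1-d)/d}).  Weights are
    sorted descending and renormalized.  d = 0 is the Dirichlet process.
    """
    if not (0 <= d < 1):
        raise ValueError("discount d must lie in [0, 1)")
    if not alpha > 0:
        raise ValueError("concentration alpha must be positive")
    if not truncation > 0:
        raise ValueError("truncation must be positive")
    rng = _rng(seed)
    blocks: list[np.ndarray] = []
    log_residual = 0.0
    start = 1
    while True:
        size = min(4096, max_atoms - (start - 1))
        if size <= 0:
            break
        i = np.arange(start, start + size)
        v = rng.beta(1.0 - d, alpha + i * d)
        v = np.clip(v, 1e-300, 1.0 - 1e-16)
        log1mv = np.log1p(-v)
        logw = log_residual + np.log(v) + np.concatenate(([0.0], np.cumsum(log1mv[:-1])))
        blocks.append(np.exp(logw))
        log_residual += float(log1mv.sum())
        start += size
        if log_residual < np.log(truncation):
            break
    w = np.concatenate(blocks)
    w = np.sort(w)[::-1]
    return w / w.sum()


def py_expected_entropy(d: float, alpha: float) -> float:
    """Closed-form expected Shannon entropy (nats) of a PY(d, alpha) draw:
    psi(alpha+1) - psi(1-d).  The d=0 case is the Dirichlet-process value."""
    from scipy.special import psi

    return float(psi(alpha + 1) - psi(1 - d))


def sample_beta_conditionals(beta: float, center, k_x: int, seed=None) -> np.ndarray:
    """k_x i.i.d. Dirichlet(beta * center) conditional rows; for a symmetric
    binary center each row is Beta(beta/2, beta/2).

    For very small beta the underlying Gamma draws can underflow to an
    all-zero row; such rows are resolved to a simplex corner drawn from the
    center (the correct beta -> 0 limit).
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    center = np.asarray(center, dtype=float)
    rng = _rng(seed)
    g = rng.gamma(beta * center, size=(k_x, center.size))
    s = g.sum(axis=1)
    dead = s == 0.0
    if dead.any():
        corners = rng.choice(center.size, size=int(dead.sum()), p=center)
        g[dead] = 0.0
        g[dead, corners] = 1.0
        s = g.sum(axis=1)
    return g / s[:, None]


def make_py_beta_model(
    beta: float = 2.3,
    d: float = 0.55,
    alpha: float = 50.0,
    k_y: int = 2,
    seed=None,
    truncation: float = DEFAULT_TRUNCATION,
    max_atoms: int = DEFAULT_MAX_ATOMS,
) -> JointModel:
    """Benchmark family 1: q_x ~ PY(d, alpha), q_{y|x} ~ Dirichlet(beta/k_y, ...)."""
    rng = _rng(seed)
    q_x = sample_py_marginal(d, alpha, truncation=truncation, seed=rng, max_atoms=max_atoms)
    center = np.full(k_y, 1.0 / k_y)
    q_cond = sample_beta_conditionals(beta, center, q_x.size, seed=rng)
    return JointModel(q_x, q_cond)


# ---------------------------------------------------------------------------
# sphere example


def icosahedron_vertices() -> np.ndarray:
    """The 12 unit vertices of a regular icosahedron — the unique
    equally-spaced 12-point arrangement on the sphere."""
    phi = (1 + np.sqrt(5)) / 2
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def sphere_scores() -> np.ndarray:
    """Rotation-invariant score pi0 - pi1 - pi2 for each of the 2^12 subsets
    of the icosahedron vertices, where pi_l = sum_m |sum_i x_i Y_lm|^2 is the
    degree-l power of the spherical spectrum of the chosen delta functions."""
    verts = icosahedron_vertices()
    theta = np.arccos(np.clip(verts[:, 2], -1, 1))       # polar angle
    phi = np.arctan2(verts[:, 1], verts[:, 0])           # azimuth
    comps = []
    degs = []
    for ell in range(3):
        for m in range(-ell, ell + 1):
            comps.append(sph_harm_y(ell, m, theta, phi))
            degs.append(ell)
    Y = np.array(comps).T                                 # (12, 9) complex
    degs = np.array(degs)
    n_states = 1 << 12
    bits = ((np.arange(n_states)[:, None] >> np.arange(12)[None, :]) & 1).astype(float)
    amps = bits @ Y                                       # (4096, 9)
    power = np.abs(amps) ** 2
    pi = np.stack([power[:, degs == ell].sum(axis=1) for ell in range(3)], axis=1)
    return pi[:, 0] - pi[:, 1] - pi[:, 2]


def make_sphere_model(
    target_info: float | None = 0.5,
    target_qy: float = 0.5,
    gain: float | None = None,
    return_params: bool = False,
):
    """Benchmark family 2: enumerate the 4096 equiprobable subset states,
    set q(1|x) = sigmoid(g * (score(x) - s0)).

    The offset s0 is tuned by bisection so the Y marginal hits ``target_qy``
    and, unless an explicit ``gain`` is given, the gain g is tuned so the
    mutual information hits ``target_info`` (nats).  The construction is
    rotation-class invariant because the score is.
    """
    scores = sphere_scores()
    lo, hi = float(scores.min()) - 1.0, float(scores.max()) + 1.0

    def tune_offset(g: float) -> float:
        return brentq(lambda s0: expit(g * (scores - s0)).mean() - target_qy, lo, hi,
                      xtol=1e-12)

    def model_for(g: float) -> JointModel:
        s0 = tune_offset(g)
        q1 = expit(g * (scores - s0))
        q_cond = np.column_stack([1 - q1, q1])
        return JointModel(np.full(scores.size, 1.0 / scores.size), q_cond)

    if gain is None:
        if target_info is None:
            raise ValueError("either gain or target_info must be given")
        gain = brentq(lambda g: model_for(g).information - target_info, 1e-4, 1e4,
                      xtol=1e-10)
    model = model_for(gain)
    if return_params:
        return model, {"gain": float(gain), "offset": float(tune_offset(gain))}
    return model


# ---------------------------------------------------------------------------
# parity example


_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


def _splitmix64(z: np.ndarray) -> np.ndarray:
    """Stateless 64-bit mixing function; used as a keyed hash so that each
    odd-parity state gets a reproducible fair branch assignment."""
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
    return z ^ (z >> np.uint64(31))


@dataclass(frozen=True)
class ParityModel:
    """Benchmark family 3, kept lazy (2^D states are never enumerated).

    x ~ Bernoulli(p)^D.  Even-parity states have q(1|x) = 1/2; odd-parity
    states get q0 or 1-q0, the branch chosen by a keyed hash of the bit
    pattern (fair in distribution, fixed within a run).  The exact
    information follows from the three-class aggregation {even, odd-q0,
    odd-(1-q0)} with P(even) = (1 + (1-2p)^D)/2.
    """

    p: float = 0.05
    D: int = 40
    q0: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p < 1):
            raise ValueError("p must lie in (0, 1)")
        if self.D < 1 or self.D > 62:
            raise ValueError("D must lie in [1, 62]")
        if not (0 < self.q0 <= 0.5):
            raise ValueError("q0 must lie in (0, 1/2]")

    @property
    def p_even(self) -> float:
        return (1 + (1 - 2 * self.p) ** self.D) / 2

    @property
    def q_y(self) -> float:
        return 0.5  # odd states split evenly between q0 and 1-q0

    @property
    def information(self) -> float:
        """Exact I (nats): log2 - [P(even) log2 + P(odd) H2(q0)]."""
        h2 = -self.q0 * np.log(self.q0) - (1 - self.q0) * np.log(1 - self.q0)
        if self.q0 == 0.5:
            h2 = np.log(2.0)
        return float(np.log(2.0) - (self.p_even * np.log(2.0) + (1 - self.p_even) * h2))

    def branch_bits(self, states: np.ndarray) -> np.ndarray:
        """Fair branch bit per state (1 -> conditional 1-q0, 0 -> q0)."""
        h = _splitmix64(states.astype(np.uint64) ^ np.uint64(self.seed))
        return (h & np.uint64(1)).astype(np.int64)

    def conditional_q1(self, states: np.ndarray) -> np.ndarray:
        pops = np.zeros(states.size, dtype=np.int64)
        s = states.astype(np.uint64).copy()
        for _ in range(self.D):
            pops += (s & np.uint64(1)).astype(np.int64)
            s >>= np.uint64(1)
        odd = pops % 2 == 1
        q1 = np.full(states.size, 0.5)
        bb = self.branch_bits(states)
        q1[odd] = np.where(bb[odd] == 1, 1 - self.q0, self.q0)
        return q1

    def sample_pairs(self, n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
        bits = rng.random((n, self.D)) < self.p
        states = (bits.astype(np.uint64) << np.arange(self.D, dtype=np.uint64)).sum(axis=1)
        q1 = self.conditional_q1(states)
        ys = (rng.random(n) < q1).astype(int)
        return list(zip(states.astype(int).tolist(), ys.tolist()))


def make_parity_model(p: float = 0.05, D: int = 40, q0: float = 0.1, seed: int = 0) -> ParityModel:
    return ParityModel(p=p, D=D, q0=q0, seed=seed)


# ---------------------------------------------------------------------------
# sampling counts


def sample_counts(model, n: int, seed=None) -> CountsTable:
    """Draw N i.i.d. (x, y) pairs from a JointModel or ParityModel and tally
    them.  Deterministic for a fixed seed."""
    if n < 1:
        raise ValueError("need at least one sample")
    rng = _rng(seed)
    pairs = model.sample_pairs(n, rng)
    return counts_from_samples(pairs)


# ---------------------------------------------------------------------------
# configs


@dataclass
class GeneratorConfig:
    """Declarative generator configuration (JSON-serializable)."""

    family: str                      # py_beta | sphere | parity | dp_beta
    params: dict = field(default_factory=dict)
    seed: int = 0
    truncation: float = DEFAULT_TRUNCATION

    _ADMISSIBLE = {"py_beta", "sphere", "parity", "dp_beta"}

    def __post_init__(self):
        if self.family not in self._ADMISSIBLE:
            raise ValueError(f"unknown family {self.family!r}; choose from {sorted(self._ADMISSIBLE)}")

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        return cls(**json.loads(text))

    def to_json(self) -> str:
        return json.dumps({"family": self.family, "params": self.params,
                           "seed": self.seed, "truncation": self.truncation})


def build_model(config: GeneratorConfig):
    """Materialize the model a config describes."""
    p = dict(config.params)
    if config.family == "py_beta":
        return make_py_beta_model(seed=config.seed, truncation=config.truncation, **p)
    if config.family == "dp_beta":
        p.setdefault("d", 0.0)
        return make_py_beta_model(seed=config.seed, truncation=config.truncation, **p)
    if config.family == "sphere":
        return make_sphere_model(**p)
    if config.family == "parity":
        return make_parity_model(seed=config.seed, **p)
    raise AssertionError
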