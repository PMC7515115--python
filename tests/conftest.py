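import numpy as np
import pytest

from bayesmi.counts import CountsTable, counts_from_samples


@pytest.fixture
def rng():
    return np.random.default_rng(20240623)


@pytest.fixture
def balanced_table():
    """Symmetric binary table: m11=1, m20=3, two singletons; q_y = (1/2, 1/2)."""
    pairs = [("a", 0), ("a", 1), ("b", 0), ("b", 0), ("c", 0), ("c", 0),
             ("d", 1), ("d", 1), ("e", 1), ("f", 1)]
    return counts_from_samples(pairs)


@pytest.fixture
def small_random_tables():
    """A handful of random tables with N <= 12, k_x <= 4, k_y = 2."""
    gen = np.random.default_rng(7)
    tables = []
    while len(tables) < 8:
        k_x = int(gen.integers(1, 5))
        counts = gen.integers(0, 4, size=(k_x, 2))
        if counts.sum() == 0 or counts.sum() > 12 or (counts.sum(axis=1) == 0).any():
            continue
        if (counts.sum(axis=0) == 0).any():  # both y categories observed
            continue
        tables.append(CountsTable(tuple(f"x{i}" for i in range(k_x)), (0, 1), counts))
    return tables


def mc_information_moments(table, beta, center, n_draws, seed):
    """Conjugate-posterior Monte-Carlo oracle for the posterior mean and
    variance of I = H_hat(Y) - sum_x q_hat_x H(q_{y|x}), with
    q_{y|x} ~ Dirichlet(beta*center + n_x.) independently per row.

    Returns (mean, se_mean, var, se_var)."""
    g = np.random.default_rng(seed)
    a = beta * center[None, :] + table.counts
    q0 = g.beta(a[:, 0], a[:, 1], size=(n_draws, table.k_x))
    with np.errstate(divide="ignore", invalid="ignore"):
        H = -(q0 * np.log(q0) + (1 - q0) * np.log1p(-q0))
    H = np.nan_to_num(H)
    qy = table.q_y_hat
    hy = float(-(qy * np.log(qy)).sum()) if (qy > 0).all() else 0.0
    I = hy - (table.q_x_hat[None, :] * H).sum(axis=1)
    mean = I.mean()
    se_mean = I.std(ddof=1) / np.sqrt(n_draws)
    var = I.var(ddof=1)
    m4 = np.mean((I - mean) ** 4)
    se_var = np.sqrt(max(m4 - var ** 2, 0.0) / n_draws)
    return float(mean), float(se_mean), float(var), float(se_var)
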