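import numpy as np
import pytest

from mrexsurv import GeneBlock, SurvivalTable


def correlated_block(rng, n, p, rho=0.5):
    """Standardized n x p CpG block with exchangeable correlation rho."""
    u = rng.standard_normal((n, 1))
    e = rng.standard_normal((n, p))
    m = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
    return (m - m.mean(axis=0)) / m.std(axis=0, ddof=1)


def make_block(rng, n=120, p=15, rho=0.5, pve=0.4, architecture="polygenic", k_causal=2):
    from mrexsurv import simulate_expression

    M = correlated_block(rng, n, p, rho)
    G, w = simulate_expression(M, architecture, pve, rng, k_causal=k_causal)
    return GeneBlock("g1", G, M, [f"cg{i:03d}" for i in range(p)]), w


def dense_reml_grid(G, M, n_grid=100_000):
    """Independent REML oracle: dense eigendecomposition of the CpG kernel and
    a log-ratio grid evaluation of the restricted likelihood (intercept only)."""
    from scipy import linalg

    n, p = M.shape
    K = M @ M.T / p
    lam, U = linalg.eigh(K)
    z = U.T @ G
    zx = U.T @ np.ones(n)
    gamma = np.exp(np.linspace(-12, 12, n_grid))
    d = gamma[:, None] * lam[None, :] + 1.0
    yVy = (z**2 / d).sum(axis=1)
    xVx = (zx**2 / d).sum(axis=1)
    xVy = (zx * z / d).sum(axis=1)
    ypy = yVy - xVy**2 / xVx
    ll = -0.5 * (np.log(d).sum(axis=1) + np.log(xVx) + (n - 1) * np.log(ypy))
    g = gamma[np.argmax(ll)]
    return g / (1.0 + g)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def three_subjects():
    """The hand-checkable dataset: times 1,2,3, all deaths, x = (0,1,0)."""
    surv = SurvivalTable(["s1", "s2", "s3"], [1.0, 2.0, 3.0], [1, 1, 1])
    x = np.array([[0.0], [1.0], [0.0]])
    return surv, x


@pytest.fixture
def small_fixture_dir(tmp_path):
    from mrexsurv import SimConfig, make_fixture

    cfg = SimConfig(n=130, genes=6, p_per_gene=12, pve=0.4, b=0.9,
                    n_signal_genes=2, censor_target=0.3, seed=11)
    paths, truth = make_fixture(cfg, tmp_path / "fx")
    return cfg, paths, truth
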