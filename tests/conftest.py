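import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rankenrich.geneset import GeneSetLibrary
from rankenrich.simulation import random_library, random_profile, run_power_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ranked(rng):
    """A 200-gene, 3-contrast null ranked matrix."""
    return random_profile(200, 3, rng)


@pytest.fixture
def small_library(small_ranked, rng):
    return random_library(small_ranked.index, 30, 20, rng)


@pytest.fixture(scope="session")
def power_grid():
    """Full-size five-contrast rank-shift benchmark, 100 replications per SD.

    Shared by the accuracy checks: n=15240 genes, 1000 random sets of 50,
    20 sets with injected enrichment, SD grid 0..0.25, calls at 5% and 1% FDR.
    """
    return run_power_benchmark(
        s_sd_grid=(0.0, 0.05, 0.10, 0.15, 0.20, 0.25),
        fdr_cutoffs=(0.05, 0.01),
        replications=100,
        seed=0,
    )


def hotelling_t2_pvalue(X1: np.ndarray, X2: np.ndarray) -> float:
    """Independent oracle: classical two-sample Hotelling T^2 p-value.

    T^2 = (n1 n2 / n) d' S_pooled^{-1} d with the pooled covariance, then
    F = (n - k - 1) / (k (n - 2)) * T^2 on (k, n - k - 1) df.
    """
    n1, k = X1.shape
    n2 = X2.shape[0]
    n = n1 + n2
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S_pooled = ((n1 - 1) * np.cov(X1.T, ddof=1) + (n2 - 1) * np.cov(X2.T, ddof=1)) / (n - 2)
    S_pooled = np.atleast_2d(S_pooled)
    t2 = n1 * n2 / n * d @ np.linalg.solve(S_pooled, d)
    F = (n - k - 1) / (k * (n - 2)) * t2
    return float(stats.f.sf(F, k, n - k - 1))


def pillai_trace_eig(X1: np.ndarray, X2: np.ndarray) -> float:
    """Independent oracle: Pillai-Bartlett trace via the general eigen path.

    Builds the between-group (H) and within-group (E) SSCP matrices
    explicitly and returns V = tr(H (H + E)^{-1}).
    """
    grand = np.vstack([X1, X2]).mean(axis=0)
    H = np.zeros((X1.shape[1], X1.shape[1]))
    E = np.zeros_like(H)
    for X in (X1, X2):
        m = X.mean(axis=0)
        H += len(X) * np.outer(m - grand, m - grand)
        Xc = X - m
        E += Xc.T @ Xc
    return float(np.trace(H @ np.linalg.inv(H + E)))


def brute_force_s(ranked: pd.DataFrame, members) -> np.ndarray:
    """Enrichment score straight from its definition: s = 2 (R1 - R2) / n."""
    inside = ranked.index.isin(set(members))
    r1 = ranked[inside].mean(axis=0).to_numpy()
    r2 = ranked[~inside].mean(axis=0).to_numpy()
    return 2.0 * (r1 - r2) / len(ranked)
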