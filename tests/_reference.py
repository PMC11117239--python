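"""Naive dense-matrix reference implementations used as independent
oracles: ridge penalties from the full hat matrix, componentwise boosting
as a literal loop over dense least-squares solves.  Deliberately slow and
simple; shares no code with the package internals."""

import numpy as np
from scipy.optimize import brentq


def hat_trace(Z: np.ndarray, lam: float) -> float:
    L = Z.shape[1]
    return float(np.trace(Z @ np.linalg.solve(Z.T @ Z + lam * np.eye(L), Z.T)))


def lambda_for_df(Z: np.ndarray, df: float) -> float:
    rank = np.linalg.matrix_rank(Z)
    df = min(df, rank)
    if df == rank:
        return 0.0
    hi = 1.0
    while hat_trace(Z, hi) > df:
        hi *= 10.0
    return brentq(lambda lam: hat_trace(Z, lam) - df, 0.0, hi, xtol=1e-12)


def naive_boost(Zs, y, mstop, nu, df):
    """Step-by-step componentwise L2 boosting over dense indicator blocks.

    Returns (intercept, per-block coefficient arrays, selection path).
    Ties in the RSS comparison go to the lowest block index.
    """
    y = np.asarray(y, dtype=float)
    lams = [lambda_for_df(Z, df) for Z in Zs]
    intercept = float(y.mean())
    r = y - intercept
    coefs = [np.zeros(Z.shape[1]) for Z in Zs]
    path = []
    for _ in range(mstop):
        best_rss, best_j, best_c = np.inf, -1, None
        for j, Z in enumerate(Zs):
            c = np.linalg.solve(Z.T @ Z + lams[j] * np.eye(Z.shape[1]), Z.T @ r)
            rss = float(np.sum((r - Z @ c) ** 2))
            if rss < best_rss:
                best_rss, best_j, best_c = rss, j, c
        coefs[best_j] += nu * best_c
        r = r - nu * (Zs[best_j] @ best_c)
        path.append(best_j)
    return intercept, coefs, path


def random_instance(rng, n_max=50, max_blocks=4):
    """Random boosting instance in which every level of every block is
    observed at least once (keeps the unpenalized limit nonsingular)."""
    n_blocks = int(rng.integers(1, max_blocks + 1))
    level_counts = [int(rng.integers(2, 6)) for _ in range(n_blocks)]
    n = int(rng.integers(max(level_counts) + 2, n_max + 1))
    codes = []
    for L in level_counts:
        c = np.concatenate([np.arange(L), rng.integers(0, L, n - L)])
        rng.shuffle(c)
        codes.append(c.astype(np.intp))
    y = rng.integers(0, 2, n).astype(float)
    return codes, level_counts, y
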