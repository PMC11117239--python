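"""Componentwise L2 gradient boosting with ridge-penalized categorical
base-learners.

Each of the eight predictor variables is represented by one base-learner:
a one-hot indicator block for its observed levels (unknown included) fitted
by ridge-penalized least squares.  The ridge penalty lambda is chosen per
block so that the trace of the hat matrix Z (Z'Z + lambda I)^-1 Z' — the
effective degrees of freedom — equals a common target, equalizing the
flexibility of factors with many and few levels ("random-effects" style
base-learners).  Boosting then iterates: compute residuals of the binary
outcome, fit every base-learner to them, add a shrunken copy (step length
nu) of the single best-fitting learner's coefficients to the model.

Because indicator columns within a block are orthogonal, Z'Z is diagonal
with the level sample sizes on the diagonal; the penalized solve reduces to
``group_sum(residuals) / (count + lambda)``, which keeps full permutation
studies cheap.  A dense-matrix reference implementation used in the test
suite verifies this closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import MODEL_VARIABLES, Cohort


@dataclass(frozen=True)
class DesignBlock:
    """One categorical variable's indicator block, stored as level codes."""

    variable: str
    levels: tuple[str, ...]
    codes: np.ndarray  # shape (n_records,), integer codes into `levels`

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.intp)
        object.__setattr__(self, "codes", codes)
        if codes.size and (codes.min() < 0 or codes.max() >= len(self.levels)):
            raise ValueError(f"{self.variable}: codes out of range")

    @property
    def n_records(self) -> int:
        return self.codes.shape[0]

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def counts(self) -> np.ndarray:
        """Per-level sample sizes (the indicator column sums)."""
        return np.bincount(self.codes, minlength=self.n_levels)

    @property
    def rank(self) -> int:
        return int((self.counts > 0).sum())

    def indicator(self) -> np.ndarray:
        """Dense n x L zero/one indicator matrix (each row sums to 1)."""
        Z = np.zeros((self.n_records, self.n_levels))
        Z[np.arange(self.n_records), self.codes] = 1.0
        return Z


@dataclass(frozen=True)
class BoostHyperparams:
    """mstop boosting iterations, step length nu, target df per base-learner."""

    mstop: int = 100
    nu: float = 0.1
    df: float = 4.0

    def __post_init__(self) -> None:
        if self.mstop < 0:
            raise ValueError("mstop must be >= 0")
        if not (0 < self.nu <= 1):
            raise ValueError("nu must be in (0, 1]")
        if self.df <= 0:
            raise ValueError("df must be > 0")


@dataclass
class BoostFit:
    """Fitted componentwise boosting model."""

    intercept: float
    coefficients: dict[str, np.ndarray]  # variable -> per-level coefficients
    levels: dict[str, tuple[str, ...]]
    selection_path: list[str]
    hyperparams: BoostHyperparams
    loss_trace: np.ndarray  # length mstop+1; entry 0 is the offset-only RSS
    lambdas: dict[str, float] = field(default_factory=dict)


def build_design(
    cohort: Cohort, variables: Sequence[str] = MODEL_VARIABLES
) -> list[DesignBlock]:
    """One indicator block per predictor variable, levels sorted
    lexicographically; the unknown level is kept as a modeled level."""
    blocks = []
    for var in variables:
        values = cohort.categorical_values(var)  # raises KeyError if unknown
        levels = tuple(sorted(set(values)))
        index = {lv: i for i, lv in enumerate(levels)}
        codes = np.fromiter((index[v] for v in values), dtype=np.intp, count=len(values))
        blocks.append(DesignBlock(var, levels, codes))
    return blocks


def ridge_lambda_for_df(block: DesignBlock, df: float, tol: float = 1e-8) -> float:
    """Ridge penalty achieving hat-matrix trace df for one indicator block.

    With orthogonal indicator columns, the hat-matrix eigenvalues are
    ``c / (c + lambda)`` for each level count c, so the trace is
    ``sum_l c_l / (c_l + lambda)``: strictly decreasing in lambda from the
    block rank (lambda=0) to 0 (lambda -> inf).  Solved by bracketed root
    finding to within ``tol``.
    """
    counts = block.counts[block.counts > 0].astype(float)
    rank = counts.size
    if df > rank:
        raise ValueError(f"{block.variable}: df={df} exceeds block rank {rank}")
    if df == rank:
        return 0.0

    def trace_minus_df(lam: float) -> float:
        return float(np.sum(counts / (counts + lam))) - df

    hi = 1.0
    while trace_minus_df(hi) > 0:
        hi *= 10.0
    return float(brentq(trace_minus_df, 0.0, hi, xtol=tol))


def fit_base_learner(
    block: DesignBlock, residuals: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Penalized least-squares fit of one block to the residual vector.

    Returns ``(coefficients, RSS)`` with coefficients
    ``(Z'Z + lambda I)^-1 Z' r = group_sum(r) / (count + lambda)``.
    The unpenalized system is singular when a level is unobserved.
    """
    r = np.asarray(residuals, dtype=float)
    if r.shape[0] != block.n_records:
        raise ValueError("residuals length must equal the number of records")
    counts = block.counts.astype(float)
    if lam == 0 and np.any(counts == 0):
        raise np.linalg.LinAlgError(
            f"{block.variable}: unpenalized fit singular (unobserved level)"
        )
    s = np.bincount(block.codes, weights=r, minlength=block.n_levels)
    coef = s / (counts + lam)
    rss = float(r @ r - 2.0 * (coef @ s) + np.sum(counts * coef**2))
    return coef, rss


def _block_lambdas(blocks: Sequence[DesignBlock], hp: BoostHyperparams) -> list[float]:
    """Per-block penalties at effective df = min(df, rank)."""
    return [ridge_lambda_for_df(b, min(hp.df, b.rank)) for b in blocks]


def fit_boost(
    blocks: Sequence[DesignBlock],
    y: np.ndarray,
    hyperparams: BoostHyperparams = BoostHyperparams(),
) -> BoostFit:
    """Componentwise L2 boosting of a binary (0/1) outcome.

    The offset is mean(y).  At each of mstop iterations every block is
    fitted to the current residuals at its df-matched penalty; the block
    with the smallest fitted RSS (ties: lowest block index) contributes
    ``nu`` times its coefficients.  ``loss_trace[k]`` is the residual sum
    of squares after k iterations and is non-increasing.
    """
    y = np.asarray(y, dtype=float)
    if len(blocks) == 0:
        raise ValueError("at least one design block is required")
    n = blocks[0].n_records
    if n == 0:
        raise ValueError("empty cohort")
    if y.shape[0] != n:
        raise ValueError("y length must equal the number of records")
    for b in blocks:
        if b.n_records != n:
            raise ValueError("all blocks must cover the same records")

    hp = hyperparams
    lambdas = _block_lambdas(blocks, hp)
    intercept = float(np.mean(y))
    r = y - intercept
    acc = {b.variable: np.zeros(b.n_levels) for b in blocks}
    path: list[str] = []
    loss = np.empty(hp.mstop + 1)
    loss[0] = float(r @ r)

    for m in range(hp.mstop):
        best_rss = np.inf
        best = -1
        best_coef = None
        for j, b in enumerate(blocks):
            coef, rss = fit_base_learner(b, r, lambdas[j])
            if rss < best_rss:
                best_rss, best, best_coef = rss, j, coef
        b = blocks[best]
        acc[b.variable] += hp.nu * best_coef
        r = r - hp.nu * best_coef[b.codes]
        path.append(b.variable)
        loss[m + 1] = float(r @ r)

    return BoostFit(
        intercept=intercept,
        coefficients=acc,
        levels={b.variable: b.levels for b in blocks},
        selection_path=path,
        hyperparams=hp,
        loss_trace=loss,
        lambdas={b.variable: lam for b, lam in zip(blocks, lambdas)},
    )


def fit_boost_multi(
    blocks: Sequence[DesignBlock],
    Y: np.ndarray,
    hyperparams: BoostHyperparams = BoostHyperparams(),
) -> dict[str, np.ndarray]:
    """Boosting of many outcome vectors at once (columns of ``Y``).

    Used by the permutation study: each column is an independently
    permuted outcome and is fitted exactly as :func:`fit_boost` fits a
    single vector (same penalties, same tie-breaking), with the per-block
    group sums vectorized across columns.  Returns
    ``{variable: (n_levels, n_columns) coefficient array}``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (records x outcome vectors)")
    if len(blocks) == 0:
        raise ValueError("at least one design block is required")
    n, B = Y.shape
    if n == 0:
        raise ValueError("empty cohort")
    hp = hyperparams
    lambdas = np.array(_block_lambdas(blocks, hp))

    # Stable sort per block so per-level group sums become reduceat calls.
    orders = []
    starts = []
    for b in blocks:
        order = np.argsort(b.codes, kind="stable")
        sorted_codes = b.codes[order]
        boundary = np.flatnonzero(np.r_[True, sorted_codes[1:] != sorted_codes[:-1]])
        present = sorted_codes[boundary]  # level ids actually observed
        orders.append((order, boundary, present))
        starts.append(present)

    R = Y - Y.mean(axis=0, keepdims=True)
    acc = {b.variable: np.zeros((b.n_levels, B)) for b in blocks}
    counts = [b.counts.astype(float) for b in blocks]

    for _ in range(hp.mstop):
        sumsq = np.einsum("ij,ij->j", R, R)
        rss = np.empty((len(blocks), B))
        coefs = []
        for j, b in enumerate(blocks):
            order, boundary, present = orders[j]
            S = np.zeros((b.n_levels, B))
            S[present] = np.add.reduceat(R[order], boundary, axis=0)
            coef = S / (counts[j] + lambdas[j])[:, None]
            rss[j] = sumsq - 2.0 * np.einsum("lj,lj->j", coef, S) + \
                np.einsum("l,lj->j", counts[j], coef**2)
            coefs.append(coef)
        sel = np.argmin(rss, axis=0)  # ties resolve to the lowest index
        for j, b in enumerate(blocks):
            cols = np.flatnonzero(sel == j)
            if cols.size == 0:
                continue
            coef_sel = coefs[j][:, cols]
            acc[b.variable][:, cols] += hp.nu * coef_sel
            R[:, cols] -= hp.nu * coef_sel[b.codes]
    return acc


def predict(fit: BoostFit, blocks: Sequence[DesignBlock]) -> np.ndarray:
    """Fitted values: intercept plus the sum of block contributions.

    Blocks may come from a new cohort; levels unseen at fit time raise a
    ``KeyError`` naming the level.
    """
    if not blocks:
        raise ValueError("at least one design block is required")
    out = np.full(blocks[0].n_records, fit.intercept)
    for b in blocks:
        if b.variable not in fit.coefficients:
            raise KeyError(f"variable {b.variable!r} was not in the fitted design")
        fit_levels = fit.levels[b.variable]
        index = {lv: i for i, lv in enumerate(fit_levels)}
        try:
            remap = np.array([index[lv] for lv in b.levels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"level {exc.args[0]!r} of {b.variable!r} was unseen at fit time"
            ) from None
        out = out + fit.coefficients[b.variable][remap[b.codes]]
    return out


def extract_effects(fit: BoostFit, blocks: Sequence[DesignBlock]) -> pd.DataFrame:
    """Per-level effect table: one row per observed level with its sample
    size and accumulated coefficient (0 if the variable was never
    selected).  Positive effects associate with the non-neoplastic outcome
    under the default coding."""
    rows = []
    for b in blocks:
        if tuple(fit.levels.get(b.variable, ())) != b.levels:
            raise ValueError(f"blocks do not match the fit for {b.variable!r}")
        counts = b.counts
        coef = fit.coefficients[b.variable]
        for i, level in enumerate(b.levels):
            rows.append((b.variable, level, int(counts[i]), float(coef[i])))
    return pd.DataFrame(rows, columns=["variable", "level", "n", "effect"])
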