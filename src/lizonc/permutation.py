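"""Permutation-calibrated significance for boosted per-level effects.

The null distribution of each level's effect is obtained by refitting the
full componentwise boosting model on uniformly permuted outcome vectors
(the design stays fixed; only y is shuffled, which preserves every
covariate marginal and breaks every covariate-outcome link).  A level's
observed effect is then compared to its own B null effects two-sided, by
default via the absolute-value tail rule with the +1 finite-sample
correction

    p = (1 + #{b : |null_b| >= |observed|}) / (B + 1),

which is exactly valid at finite B under exchangeability.  A percentile
rule (observed outside the null's [alpha/2, 1-alpha/2] quantiles) is
available as an alternative.  Significance is only assessed for levels
carried by at least ``min_n`` individuals (default 2); smaller levels are
reported with significance suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .boosting import BoostHyperparams, DesignBlock, fit_boost_multi

DIRECTION_POSITIVE = "non_neoplastic"
DIRECTION_NEGATIVE = "neoplasia_death"


@dataclass(frozen=True)
class PermutationResult:
    variable: str
    level: str
    sample_size: int
    observed_effect: float
    null_effects: np.ndarray
    p_value: float
    significant: bool
    direction: str


def permute_outcomes(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of the outcome vector."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("y must be nonempty")
    return rng.permutation(y)


def null_distributions(
    blocks: Sequence[DesignBlock],
    y: np.ndarray,
    B: int,
    hyperparams: BoostHyperparams = BoostHyperparams(),
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-level null effect arrays from B permuted-outcome refits.

    Returns ``{variable: (n_levels, B) array}``; column b holds the
    effects of the model fitted to the b-th permuted outcome.  Reproducible
    for a fixed seed.
    """
    if B < 0:
        raise ValueError("B must be >= 0")
    y = np.asarray(y, dtype=float)
    if B == 0:
        return {b.variable: np.zeros((b.n_levels, 0)) for b in blocks}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = np.column_stack([rng.permutation(y) for _ in range(B)])
    return fit_boost_multi(blocks, Y, hyperparams)


def _two_sided_p(observed: float, nulls: np.ndarray, rule: str, alpha: float) -> float:
    B = nulls.size
    if rule == "absolute":
        return float((1 + np.sum(np.abs(nulls) >= abs(observed))) / (B + 1))
    if rule == "percentile":
        lo = (1 + np.sum(nulls <= observed)) / (B + 1)
        hi = (1 + np.sum(nulls >= observed)) / (B + 1)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError("tail rule must be 'absolute' or 'percentile'")


def significance_table(
    effects: pd.DataFrame,
    nulls: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_n: int = 2,
    tail_rule: str = "absolute",
) -> pd.DataFrame:
    """Two-sided permutation p-values and significance flags per level.

    ``effects`` is the table from :func:`lizonc.boosting.extract_effects`;
    ``nulls`` comes from :func:`null_distributions` on the same blocks.
    A level is significant iff p < alpha and its sample size is at least
    ``min_n``.  Output columns: variable, level, n, effect, p_value,
    significant, direction.
    """
    rows = []
    for variable, group in effects.groupby("variable", sort=False):
        if variable not in nulls:
            raise KeyError(f"no null distribution for variable {variable!r}")
        null_block = nulls[variable]
        B = null_block.shape[1]
        if B == 0:
            raise ValueError("B=0: no null distribution to compare against")
        if null_block.shape[0] != len(group):
            raise ValueError(f"null levels do not match effects for {variable!r}")
        for i, (_, row) in enumerate(group.iterrows()):
            obs = float(row["effect"])
            p = _two_sided_p(obs, null_block[i], tail_rule, alpha)
            suppressed = int(row["n"]) < min_n
            rows.append({
                "variable": variable,
                "level": row["level"],
                "n": int(row["n"]),
                "effect": obs,
                "p_value": p,
                "significant": bool(p < alpha and not suppressed),
                "direction": DIRECTION_NEGATIVE if obs < 0 else DIRECTION_POSITIVE,
            })
    return pd.DataFrame(rows)


def permutation_results(
    effects: pd.DataFrame,
    nulls: dict[str, np.ndarray],
    alpha: float = 0.05,
    min_n: int = 2,
    tail_rule: str = "absolute",
) -> list[PermutationResult]:
    """Same information as :func:`significance_table`, as typed records
    that keep each level's raw null sample."""
    table = significance_table(effects, nulls, alpha, min_n, tail_rule)
    out = []
    level_pos = {
        (v, lv): i
        for v, grp in effects.groupby("variable", sort=False)
        for i, lv in enumerate(grp["level"])
    }
    for _, row in table.iterrows():
        i = level_pos[(row["variable"], row["level"])]
        out.append(PermutationResult(
            variable=row["variable"],
            level=row["level"],
            sample_size=int(row["n"]),
            observed_effect=float(row["effect"]),
            null_effects=nulls[row["variable"]][i].copy(),
            p_value=float(row["p_value"]),
            significant=bool(row["significant"]),
            direction=row["direction"],
        ))
    return out
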