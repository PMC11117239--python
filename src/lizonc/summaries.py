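"""Descriptive cohort summaries: frequency tables, species-union
accounting, metastasis prevalence, survival-time and treatment summaries.

Percentages are rounded half-up to one decimal (table cells) or to a whole
percent (headline figures); all summaries are invariant to record order.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    Metastasis,
    PURSUED_TREATMENTS,
    SCHEMA_FIELDS,
    Source,
    TreatmentCategory,
)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def frequency_table(
    cohort: Cohort, field: str, by_source: bool = False
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Level counts with denominator and one-decimal percent.

    With ``by_source=True`` returns ``{source: table}`` with per-source
    denominators (the per-source cohort sizes).
    """
    if field not in SCHEMA_FIELDS:
        raise KeyError(f"unknown schema field {field!r}")
    if by_source:
        return {
            s.value: frequency_table(cohort.subset(s), field)
            for s in Source
        }
    values = cohort.categorical_values(field)
    denom = len(values)
    counts = pd.Series(values).value_counts().sort_index() if values else pd.Series(dtype=int)
    rows = [
        (level, int(c), denom, round_half_up(100.0 * c / denom, 1))
        for level, c in counts.items()
    ]
    return pd.DataFrame(rows, columns=["level", "count", "denominator", "percent"])


@dataclass(frozen=True)
class SpeciesUnion:
    n_total_unique: int
    n_literature: int
    n_escra: int
    n_shared: int


def combined_species_count(cohort: Cohort) -> SpeciesUnion:
    """Distinct scientific-name counts per source and their union.

    Inclusion-exclusion (total = literature + registry - shared) is
    asserted as a consistency check.
    """
    lit = {r.species_scientific for r in cohort if r.source is Source.literature}
    esc = {r.species_scientific for r in cohort if r.source is Source.escra}
    total = lit | esc
    shared = lit & esc
    assert len(total) == len(lit) + len(esc) - len(shared)
    return SpeciesUnion(len(total), len(lit), len(esc), len(shared))


@dataclass(frozen=True)
class MetastasisSummary:
    percent_present: float       # one decimal
    percent_absent: float
    percent_unknown: float
    percent_unknown_headline: int  # whole percent


def metastasis_summary(cohort: Cohort) -> MetastasisSummary:
    """Metastasis prevalence over the full cohort (unknown included)."""
    n = len(cohort)
    if n == 0:
        raise ValueError("empty cohort")
    counts = {m: 0 for m in Metastasis}
    for r in cohort:
        counts[r.metastasis] += 1
    pct = {m: 100.0 * counts[m] / n for m in Metastasis}
    return MetastasisSummary(
        percent_present=round_half_up(pct[Metastasis.present], 1),
        percent_absent=round_half_up(pct[Metastasis.absent], 1),
        percent_unknown=round_half_up(pct[Metastasis.unknown], 1),
        percent_unknown_headline=int(round_half_up(pct[Metastasis.unknown], 0)),
    )


@dataclass(frozen=True)
class SurvivalTimeSummary:
    n_known: int
    min: float | None
    max: float | None
    mean: float | None
    median: float | None


def survival_time_summary(
    cohort: Cohort, by_source: bool = False
) -> SurvivalTimeSummary | dict[str, SurvivalTimeSummary]:
    """Descriptive statistics of known survival times only."""
    if by_source:
        return {
            s.value: survival_time_summary(cohort.subset(s)) for s in Source
        }
    known = np.array([r.survival_months for r in cohort if r.survival_months is not None])
    if known.size == 0:
        return SurvivalTimeSummary(0, None, None, None, None)
    return SurvivalTimeSummary(
        n_known=int(known.size),
        min=float(known.min()),
        max=float(known.max()),
        mean=float(known.mean()),
        median=float(np.median(known)),
    )


@dataclass(frozen=True)
class TreatmentSummary:
    table: pd.DataFrame
    n_pursued: int
    n_not_pursued: int        # explicit no_treatment
    n_unknown: int            # unknown_treatment


def treatment_summary(
    cohort: Cohort, by_source: bool = False
) -> TreatmentSummary | dict[str, TreatmentSummary]:
    """Frequency of treatment categories plus the pursued / not-pursued
    split (pursued = any category except no_treatment / unknown)."""
    if by_source:
        return {s.value: treatment_summary(cohort.subset(s)) for s in Source}
    table = frequency_table(cohort, "treatment")
    pursued = sum(1 for r in cohort if r.treatment in PURSUED_TREATMENTS)
    none = sum(1 for r in cohort if r.treatment is TreatmentCategory.no_treatment)
    unknown = sum(1 for r in cohort if r.treatment is TreatmentCategory.unknown_treatment)
    return TreatmentSummary(table, pursued, none, unknown)
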