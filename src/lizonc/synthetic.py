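"""Synthetic cohort generator.

Generates cohorts with the structure the analysis assumes: two sources
(literature and registry), eight categorical covariates with heavy
"unknown" mass, a binary outcome (non-neoplastic vs death due to
neoplasia) linked to configured per-level effects, and right-censored
survival times.  The default configuration draws its covariate marginals
from the synthetic table reconstructions in :mod:`lizonc.datasets`, so a
generated cohort mirrors the published cohort's composition (e.g. unknown
sex on about 138/219 of literature records, green iguanas on 55/219).

Covariates are sampled independently across variables — the analysis
models each variable through its own base-learner and the source tables
publish only marginals — so species-by-diagnosis dependence present in
real data is deliberately not emulated.  Event times are exponential per
outcome-by-treatment group (the minimal constant-rate model for
contrasting group mortality rates), and censored animals are recorded as
alive at their censoring time.

All randomness flows from one root seed through named, deterministically
derived substreams, so identical configurations and seeds give identical
cohorts regardless of which stages run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .cohort import (
    CaseRecord,
    Cohort,
    LifeStage,
    Malignancy,
    Metastasis,
    MODEL_VARIABLES,
    Outcome,
    Sex,
    Source,
    TreatmentCategory,
    UNKNOWN,
)
from . import datasets


class ConfigError(ValueError):
    """Invalid synthetic-cohort configuration."""


#: Default exponential mean event/censoring times (months).  Untreated
#: neoplasia deaths are fast, treated ones slower, non-neoplastic deaths
#: slower still; censoring (still-alive) times are on the follow-up scale.
DEFAULT_SURVIVAL_MEANS = {
    "neoplasia_death_no_treatment": 2.0,
    "neoplasia_death_treated": 10.0,
    "non_neoplastic_death": 20.0,
    "censoring": 24.0,
}

#: Default log-odds effects, qualitatively mirroring the direction of the
#: reported associations (treatment protective, no treatment harmful,
#: benign behavior protective).  Positive = toward the non-neoplastic
#: outcome.
DEFAULT_TRUE_EFFECTS: dict[str, dict[str, float]] = {
    "treatment": {
        TreatmentCategory.surgery_only.value: 1.0,
        TreatmentCategory.radiation_only.value: 1.0,
        TreatmentCategory.no_treatment.value: -1.0,
    },
    "malignancy": {
        Malignancy.benign.value: 1.0,
        Malignancy.undetermined.value: -0.5,
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the generator; see the module docstring for defaults.

    ``level_frequencies`` maps source -> variable -> {level: probability};
    each distribution must sum to 1 within 1e-9.  ``true_effects`` maps
    variable -> {level: additive effect on the linear predictor}
    (log-odds under the logistic link, probability units under the
    linear-probability link).
    """

    n_records: int = 274
    source_split: float = 219 / 274  # P(source = literature)
    level_frequencies: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=dict
    )
    baseline_p: float = 0.5
    true_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    outcome_link: str = "logistic"  # or "linear_probability"
    survival_means_months: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SURVIVAL_MEANS)
    )
    censor_prob: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be >= 0")
        if not (0 <= self.source_split <= 1):
            raise ConfigError("source_split must be in [0, 1]")
        if not (0 <= self.baseline_p <= 1):
            raise ConfigError("baseline_p must be in [0, 1]")
        if not (0 <= self.censor_prob <= 1):
            raise ConfigError("censor_prob must be in [0, 1]")
        if self.outcome_link not in ("logistic", "linear_probability"):
            raise ConfigError("outcome_link must be 'logistic' or 'linear_probability'")
        for key in DEFAULT_SURVIVAL_MEANS:
            if self.survival_means_months.get(key, 1.0) <= 0:
                raise ConfigError(f"survival mean {key!r} must be > 0")
        for source, per_var in self.level_frequencies.items():
            for var, dist in per_var.items():
                probs = np.array(list(dist.values()), dtype=float)
                if np.any(probs < 0) or np.any(probs > 1):
                    raise ConfigError(f"{source}/{var}: probabilities outside [0, 1]")
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigError(
                        f"{source}/{var}: level frequencies sum to {probs.sum()!r}, not 1"
                    )


def _empirical_marginals(cohort: Cohort) -> dict[str, dict[str, float]]:
    n = len(cohort)
    out: dict[str, dict[str, float]] = {}
    for var in MODEL_VARIABLES:
        values = cohort.categorical_values(var)
        dist: dict[str, float] = {}
        for v in values:
            dist[v] = dist.get(v, 0.0) + 1.0 / n
        # renormalize away float accumulation error
        total = sum(dist.values())
        out[var] = {k: v / total for k, v in sorted(dist.items())}
    return out


def default_config(n_records: int = 274, seed: int = 0) -> SyntheticConfig:
    """Configuration emulating the published cohort structure.

    Covariate marginals are the empirical level frequencies of the
    synthetic table reconstructions (so e.g. the literature species
    marginal puts mass 55/219 on *Iguana iguana* and the treatment
    marginal 25/219 on surgery only), and effects default to
    :data:`DEFAULT_TRUE_EFFECTS`.
    """
    freqs = {
        Source.literature.value: _empirical_marginals(datasets.synthetic_literature_cohort()),
        Source.escra.value: _empirical_marginals(datasets.synthetic_escra_cohort()),
    }
    cfg = SyntheticConfig(
        n_records=n_records,
        level_frequencies=freqs,
        true_effects={k: dict(v) for k, v in DEFAULT_TRUE_EFFECTS.items()},
        seed=seed,
    )
    cfg.validate()
    return cfg


def global_null_config(n_records: int = 274, seed: int = 0) -> SyntheticConfig:
    """Default structure with every true effect set to zero (for
    calibration studies)."""
    return replace(default_config(n_records=n_records, seed=seed), true_effects={})


def power_study_config(
    n_records: int = 300,
    effect: float = 0.3,
    variable: str = "treatment",
    level: str = TreatmentCategory.surgery_only.value,
    level_prob: float = 0.2,
    seed: int = 0,
) -> SyntheticConfig:
    """One nonzero effect on a well-represented level, on the probability
    scale (linear-probability link), for power/recovery studies.

    The carrier level's marginal probability is raised to ``level_prob``
    in both sources so the level reliably carries a sizeable subgroup
    (about ``level_prob * n_records`` records); all other effects are
    zero and the baseline outcome probability is 1/2.
    """
    cfg = global_null_config(n_records=n_records, seed=seed)
    freqs = {s: {v: dict(d) for v, d in per.items()}
             for s, per in cfg.level_frequencies.items()}
    for per_var in freqs.values():
        dist = per_var[variable]
        others = [lv for lv in dist if lv != level]
        rest = sum(dist[lv] for lv in others)
        scale = (1.0 - level_prob) / rest
        for lv in others:
            dist[lv] *= scale
        dist[level] = level_prob
    cfg = replace(
        cfg,
        level_frequencies=freqs,
        outcome_link="linear_probability",
        baseline_p=0.5,
        true_effects={variable: {level: effect}},
    )
    cfg.validate()
    return cfg


_STAGE_NAMES = ("source", "covariates", "outcome", "survival")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STAGE_NAMES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGE_NAMES, children)}


_SPECIES_COMMON = {
    r.species_scientific: r.species_common
    for r in datasets.synthetic_combined_cohort()
}


def _linear_predictor(config: SyntheticConfig, levels: dict[str, str]) -> float:
    if config.outcome_link == "logistic":
        base = math.log(config.baseline_p / (1 - config.baseline_p)) \
            if 0 < config.baseline_p < 1 else math.inf * (1 if config.baseline_p else -1)
    else:
        base = config.baseline_p
    eta = base
    for var, per_level in config.true_effects.items():
        eta += per_level.get(levels.get(var, ""), 0.0)
    return eta


def _prob(config: SyntheticConfig, eta: float) -> float:
    if config.outcome_link == "logistic":
        return 1.0 / (1.0 + math.exp(-eta))
    return min(1.0, max(0.0, eta))


def generate_cohort(config: SyntheticConfig, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort from the configuration.

    Per record: a source, then each of the eight covariates independently
    from that source's marginal, then the binary outcome from the link
    applied to the summed effects (y=1 non-neoplastic), then an
    exponential event or censoring time.  Censored records carry
    outcome=alive; neoplasia deaths carry outcome=died_neoplasia.
    """
    config.validate()
    rngs = _substreams(config.seed if seed is None else seed)
    n = config.n_records

    sources = np.where(
        rngs["source"].random(n) < config.source_split,
        Source.literature.value,
        Source.escra.value,
    )

    # Vectorized covariate draws: per source, per variable, one multinomial
    # draw over the whole block of records of that source.
    cov_rng = rngs["covariates"]
    fallback = {
        var: (UNKNOWN if var != "malignancy" else Malignancy.undetermined.value)
        for var in MODEL_VARIABLES
    }
    columns: dict[str, np.ndarray] = {
        var: np.array([fallback[var]] * n, dtype=object) for var in MODEL_VARIABLES
    }
    for src in (Source.literature.value, Source.escra.value):
        idx = np.flatnonzero(sources == src)
        per_var = config.level_frequencies.get(src, {})
        for var in MODEL_VARIABLES:
            if idx.size == 0 or var not in per_var:
                continue
            dist = per_var[var]
            lv_names = np.array(list(dist.keys()), dtype=object)
            lv_probs = np.array(list(dist.values()), dtype=float)
            draws = cov_rng.choice(len(lv_names), size=idx.size, p=lv_probs)
            columns[var][idx] = lv_names[draws]

    out_rng = rngs["outcome"]
    surv_rng = rngs["survival"]
    records = []
    for i in range(n):
        src = sources[i]
        levels: dict[str, str] = {var: columns[var][i] for var in MODEL_VARIABLES}

        p = _prob(config, _linear_predictor(config, levels))
        non_neoplastic = out_rng.random() < p

        treated = levels["treatment"] not in (
            TreatmentCategory.no_treatment.value,
            TreatmentCategory.unknown_treatment.value,
        )
        means = config.survival_means_months
        if not non_neoplastic:
            outcome = Outcome.died_neoplasia
            mean = means["neoplasia_death_treated" if treated
                         else "neoplasia_death_no_treatment"]
        elif surv_rng.random() < config.censor_prob:
            outcome = Outcome.alive
            mean = means["censoring"]
        else:
            outcome = Outcome.died_other
            mean = means["non_neoplastic_death"]
        survival = float(surv_rng.exponential(mean))

        scientific = levels["species_scientific"]
        records.append(CaseRecord(
            record_id=f"SYN-{i + 1:05d}",
            source=Source(src),
            species_common=_SPECIES_COMMON.get(scientific, scientific),
            species_scientific=scientific,
            age_months=None,
            life_stage=LifeStage(levels["life_stage"]),
            sex=Sex(levels["sex"]),
            diagnosis=levels["diagnosis"],
            malignancy=Malignancy(levels["malignancy"]),
            metastasis=Metastasis(levels["metastasis"]),
            tumor_location=levels["tumor_location"],
            treatment=TreatmentCategory(levels["treatment"]),
            outcome=outcome,
            survival_months=survival,
        ))
    return Cohort(records)


def inject_missingness(
    cohort: Cohort,
    rates: Mapping[str, float],
    seed: int | None = None,
) -> Cohort:
    """Replace field values with the unknown level independently at the
    given per-field rates.

    Supported fields: the categorical model variables plus ``age_months``
    and ``survival_months`` (set to unknown/None) and ``outcome`` (death
    records degrade to died_unknown_cause).
    """
    for f, rate in rates.items():
        if not (0 <= rate <= 1):
            raise ConfigError(f"missingness rate for {f!r} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    unknown_value = {
        "sex": Sex.unknown,
        "life_stage": LifeStage.unknown,
        "malignancy": Malignancy.undetermined,
        "metastasis": Metastasis.unknown,
        "treatment": TreatmentCategory.unknown_treatment,
        "diagnosis": UNKNOWN,
        "tumor_location": UNKNOWN,
        "species_scientific": UNKNOWN,
    }
    new_records = []
    for r in cohort:
        changes: dict = {}
        for f, rate in rates.items():
            if rate == 0 or rng.random() >= rate:
                continue
            if f in unknown_value:
                changes[f] = unknown_value[f]
                if f == "species_scientific":
                    changes["species_common"] = UNKNOWN
            elif f in ("age_months", "survival_months"):
                changes[f] = None
            elif f == "outcome":
                if r.outcome in (Outcome.died_neoplasia, Outcome.died_other):
                    changes[f] = Outcome.died_unknown_cause
            else:
                raise ConfigError(f"cannot inject missingness into field {f!r}")
        new_records.append(replace(r, **changes) if changes else r)
    return Cohort(new_records)
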