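"""Synthetic reconstructions of the published cohort's printed aggregates.

The record-level study data are restricted (available only through an
approved research request), but the publication prints marginal counts:
species, diagnosis, treatment and metastasis frequencies, outcome splits,
and survival-time summaries for a literature cohort of 219 lizards and a
registry (ESCRA) cohort of 55.  The builders here construct SYNTHETIC
cohorts whose marginal distributions reproduce those printed aggregates
exactly; the joint assignment of values to records is a deterministic
convention and carries no information.  They serve as fixtures for the
descriptive-summary layer and as the default marginals of the synthetic
cohort generator — they are not the real data and must not be mistaken
for it.

Where printed numbers contradict each other (several table cells do not
match the running text, and a few marginals do not sum to the cohort
size), the running text is followed and the conflict is recorded in
:data:`DISCREPANCIES`, exportable as JSON via :func:`export_discrepancies`.
"""

from __future__ import annotations

import json
from typing import Iterable

from .cohort import (
    CaseRecord,
    Cohort,
    LifeStage,
    Malignancy,
    Metastasis,
    Outcome,
    Sex,
    Source,
    TreatmentCategory,
)

#: Machine-readable log of contradictions among the printed aggregates and
#: how the fixtures resolve them.
DISCREPANCIES: list[dict] = [
    {
        "field": "species",
        "source": "escra",
        "printed_table": "central bearded dragon 21/55 (45.5%)",
        "printed_text": "n = 25",
        "resolution": "text followed: 25",
    },
    {
        "field": "diagnosis",
        "source": "escra",
        "printed_table": "squamous cell carcinoma 7/55 (12.7%)",
        "printed_text": "n = 8",
        "resolution": "text followed: 8",
    },
    {
        "field": "diagnosis",
        "source": "literature",
        "printed_table": "chromatophoroma benign 3 + malignant 6 = 9",
        "printed_text": "n = 10",
        "resolution": "text followed: 10 (4 benign, 6 malignant)",
    },
    {
        "field": "life_stage",
        "source": "literature",
        "printed_table": "adult 52 + juvenile 6 + unknown 141 = 199 != 219",
        "printed_text": None,
        "resolution": "unknown raised to 161 so the cohort sums to 219",
    },
    {
        "field": "outcome",
        "source": "literature",
        "printed_table": "components 25+25+11+1 = 62, but 'available for 89'",
        "printed_text": None,
        "resolution": "components followed; unknown = 157",
    },
    {
        "field": "malignancy",
        "source": "escra",
        "printed_table": "malignant 40 + benign 7 + unknown 9 = 56 != 55",
        "printed_text": None,
        "resolution": "unknown lowered to 8 so the cohort sums to 55",
    },
    {
        "field": "neoplasm_union",
        "source": "combined",
        "printed_table": "85 literature + 38 registry - 16 shared = 107",
        "printed_text": "108 neoplasms included",
        "resolution": "not used by any fixture; noted only",
    },
]


def export_discrepancies(path) -> None:
    with open(path, "w") as fh:
        json.dump(DISCREPANCIES, fh, indent=2)


def _expand(pairs: Iterable[tuple[object, int]]) -> list:
    out: list = []
    for value, count in pairs:
        out.extend([value] * count)
    return out


# (common name, scientific name, count) — literature species table plus 40
# placeholder species standing in for the long tail of singleton reports.
_LIT_SPECIES = [
    ("Beaded lizard", "Heloderma exasperatum", 2),
    ("Broad headed skink", "Eumeces laticeps", 2),
    ("Central bearded dragon", "Pogona vitticeps", 32),
    ("Crocodile lizard", "Shinisaurus crocodilurus", 2),
    ("Desert grassland whiptail lizard", "Cnemidophorus uniparens", 2),
    ("East Indian water lizard", "Hydrosaurus amboinensis", 2),
    ("European green lizard", "Lacerta viridis", 4),
    ("Gila monster", "Heloderma suspectum", 5),
    ("Green anole", "Anolis carolinensis", 2),
    ("Green iguana", "Iguana iguana", 55),
    ("Komodo dragon", "Varanus komodoensis", 3),
    ("Leopard gecko", "Eublepharis macularius", 5),
    ("Mexican beaded lizard", "Heloderma horridum", 2),
    ("Panther chameleon", "Furcifer pardalis", 2),
    ("Round island skink", "Leiolopisma telfairii", 2),
    ("Savannah monitor", "Varanus exanthematicus", 10),
    ("Spiny-tailed lizard", "Uromastyx acanthinura", 10),
    ("Spiny-tailed monitor", "Varanus acanthurus", 3),
    ("Veiled chameleon", "Chamaeleo calyptratus", 8),
] + [
    (f"Other lizard {i:02d}", f"Lacertilia sp. {i:02d}", 2 if i <= 26 else 1)
    for i in range(1, 41)
]

# (diagnosis, malignancy, count): named rows from the printed table plus
# pooled remainder categories to reach the printed malignancy totals
# (133 malignant / 58 benign / 28 undetermined).
_LIT_DIAGNOSES = [
    ("lymphoma", Malignancy.malignant, 18),
    ("squamous cell carcinoma", Malignancy.malignant, 13),
    ("chromatophoroma", Malignancy.malignant, 6),
    ("chromatophoroma", Malignancy.benign, 4),
    ("teratoma", Malignancy.benign, 7),
    ("teratoma", Malignancy.malignant, 3),
    ("biliary adenocarcinoma", Malignancy.malignant, 6),
    ("carcinoma", Malignancy.malignant, 3),
    ("cholangiocarcinoma", Malignancy.malignant, 4),
    ("chondrosarcoma", Malignancy.malignant, 2),
    ("colon adenocarcinoma", Malignancy.malignant, 2),
    ("fibroma", Malignancy.benign, 6),
    ("fibropapilloma", Malignancy.benign, 2),
    ("fibrosarcoma", Malignancy.malignant, 3),
    ("gastric carcinoid", Malignancy.malignant, 3),
    ("granulosa cell tumor", Malignancy.malignant, 3),
    ("hemangiosarcoma", Malignancy.malignant, 2),
    ("hepatocellular carcinoma", Malignancy.malignant, 3),
    ("hepatoma", Malignancy.benign, 2),
    ("interstitial cell adenoma", Malignancy.benign, 2),
    ("islet cell carcinoma", Malignancy.malignant, 3),
    ("leiomyosarcoma", Malignancy.malignant, 5),
    ("leukemia", Malignancy.malignant, 5),
    ("melanophoroma", Malignancy.benign, 2),
    ("melanophoroma", Malignancy.malignant, 3),
    ("myxoma", Malignancy.benign, 3),
    ("osteosarcoma", Malignancy.malignant, 5),
    ("pancreatic adenocarcinoma", Malignancy.malignant, 2),
    ("papilloma", Malignancy.benign, 3),
    ("parathyroid adenoma", Malignancy.benign, 4),
    ("renal adenoma", Malignancy.benign, 2),
    ("thyroid carcinoma", Malignancy.malignant, 3),
    ("undifferentiated sarcoma", Malignancy.malignant, 2),
    ("other malignant neoplasm", Malignancy.malignant, 34),
    ("other benign neoplasm", Malignancy.benign, 21),
    ("proliferative lesion nos", Malignancy.undetermined, 28),
]

_LIT_LOCATIONS = [
    ("liver", 15), ("unknown", 28), ("bone marrow", 3), ("jaw", 2),
    ("kidney", 2), ("pancreas", 3), ("skin", 5),
    ("hematopoietic/lymphatic", 20),
    ("arm/leg (joint/bone/cartilage)", 2),
    ("abdominal organ (gastrointestinal and alimentary)", 3),
    ("oral cavity", 20), ("coelom", 20),
    ("skin/scales (head region)", 4), ("subcutis", 20), ("eye", 10),
    ("tail", 10), ("spleen", 10), ("lung", 10),
    ("reproductive tract", 10), ("musculoskeletal", 22),
]

# 50 known ages (months): min 5, max 300, median 60.
_LIT_AGES = (
    [5, 9, 12, 12, 18, 18, 24, 24, 24, 30, 30, 36, 36, 36, 42, 42, 48, 48,
     48, 54, 54, 57, 58, 59, 60, 60, 66, 66, 72, 72, 72, 84, 84, 96, 96,
     108, 120, 120, 132, 144, 156, 168, 180, 192, 204, 216, 240, 264, 288,
     300]
)

# 108 known survival times (months): mean exactly 20.0, median 0, max 56.
_LIT_SURVIVAL = [0.0] * 55 + [56.0] * 38 + [2.0] * 13 + [3.0] * 2


def synthetic_literature_cohort() -> Cohort:
    """Synthetic 219-record literature cohort matching the printed
    literature-review aggregates (see module docstring)."""
    n = 219
    species = _expand([((c, s), k) for c, s, k in _LIT_SPECIES])
    sexes = _expand([(Sex.male, 40), (Sex.female, 41), (Sex.unknown, 138)])
    stages = _expand([(LifeStage.adult, 52), (LifeStage.juvenile, 6),
                      (LifeStage.unknown, 161)])
    ages: list[float | None] = list(map(float, _LIT_AGES)) + [None] * (n - len(_LIT_AGES))
    diagnoses = _expand([((d, m), k) for d, m, k in _LIT_DIAGNOSES])
    metastasis = _expand([(Metastasis.present, 13), (Metastasis.absent, 50),
                          (Metastasis.unknown, 156)])
    locations = _expand(_LIT_LOCATIONS)
    treatments = _expand([
        (TreatmentCategory.surgery_only, 25),
        (TreatmentCategory.chemotherapy_only, 3),
        (TreatmentCategory.radiation_only, 2),
        (TreatmentCategory.surgery_and_chemotherapy, 1),
        (TreatmentCategory.no_treatment, 161),
        (TreatmentCategory.unknown_treatment, 27),
    ])
    outcomes = _expand([
        (Outcome.died_neoplasia, 25),
        (Outcome.alive, 25),
        (Outcome.died_unknown_cause, 11),
        (Outcome.died_other, 1),
        (Outcome.unknown, 157),
    ])
    survival: list[float | None] = list(_LIT_SURVIVAL) + [None] * (n - len(_LIT_SURVIVAL))

    for name, values in [("species", species), ("sex", sexes), ("stage", stages),
                         ("ages", ages), ("diagnosis", diagnoses),
                         ("metastasis", metastasis), ("location", locations),
                         ("treatment", treatments), ("outcome", outcomes),
                         ("survival", survival)]:
        assert len(values) == n, f"literature {name} column has {len(values)} entries"

    records = []
    for i in range(n):
        common, scientific = species[i]
        diagnosis, malignancy = diagnoses[i]
        records.append(CaseRecord(
            record_id=f"LIT-{i + 1:04d}",
            source=Source.literature,
            species_common=common,
            species_scientific=scientific,
            age_months=ages[i],
            life_stage=stages[i],
            sex=sexes[i],
            diagnosis=diagnosis,
            malignancy=malignancy,
            metastasis=metastasis[i],
            tumor_location=locations[i],
            treatment=treatments[i],
            outcome=outcomes[i],
            survival_months=survival[i],
        ))
    return Cohort(records)


_ESCRA_SPECIES = [
    ("Central bearded dragon", "Pogona vitticeps", 25),
    ("Leopard gecko", "Eublepharis macularius", 4),
    ("Panther chameleon", "Furcifer pardalis", 4),
    ("Green iguana", "Iguana iguana", 3),
    ("Veiled chameleon", "Chamaeleo calyptratus", 3),
    ("Blotched blue-tongued lizard", "Tiliqua nigrolutea", 2),
    # nine singleton species shared with the literature cohort
    ("Savannah monitor", "Varanus exanthematicus", 1),
    ("Komodo dragon", "Varanus komodoensis", 1),
    ("Spiny-tailed monitor", "Varanus acanthurus", 1),
    ("Gila monster", "Heloderma suspectum", 1),
    ("Green anole", "Anolis carolinensis", 1),
    ("European green lizard", "Lacerta viridis", 1),
    ("Spiny-tailed lizard", "Uromastyx acanthinura", 1),
    ("Round island skink", "Leiolopisma telfairii", 1),
    ("Crocodile lizard", "Shinisaurus crocodilurus", 1),
    # five singleton species unique to the registry
    ("Western banded gecko", "Coleonyx variegatus", 1),
    ("Fat-tailed gecko", "Hemitheconyx caudicinctus", 1),
    ("Tokay gecko", "Gekko gecko", 1),
    ("Gold tegu", "Tupinambis teguixin", 1),
    ("Australian water dragon", "Intellagama lesueurii", 1),
]

_ESCRA_DIAGNOSES = [
    ("squamous cell carcinoma", Malignancy.malignant, 8),
    ("spindle cell sarcoma", Malignancy.malignant, 4),
    ("chromatophoroma", Malignancy.malignant, 1),
    ("chromatophoroma", Malignancy.benign, 1),
    ("leukemia", Malignancy.malignant, 2),
    ("lymphosarcoma", Malignancy.malignant, 2),
    ("myxosarcoma", Malignancy.malignant, 2),
    ("papilloma", Malignancy.benign, 1),
    ("papilloma", Malignancy.undetermined, 1),
    ("sarcoma", Malignancy.malignant, 1),
    ("sarcoma", Malignancy.undetermined, 1),
    ("other malignant neoplasm", Malignancy.malignant, 20),
    ("other benign neoplasm", Malignancy.benign, 5),
    ("proliferative lesion nos", Malignancy.undetermined, 6),
]

_ESCRA_LOCATIONS = [
    ("skin", 6), ("skin/scales (head region)", 6),
    ("abdominal organ (gastrointestinal/alimentary)", 5),
    ("unknown", 10), ("oral cavity", 8), ("tail", 6), ("eye", 4),
    ("liver", 4), ("subcutis", 6),
]

# 34 known ages (months) in [24, 173], median near 72.
_ESCRA_AGES = [
    24, 30, 36, 36, 42, 48, 48, 54, 60, 60, 60, 66, 66, 70, 70, 72, 72, 74,
    78, 84, 84, 90, 96, 96, 102, 108, 120, 126, 132, 144, 150, 160, 168, 173,
]

# 13 known survival times: mean exactly 10.3, median 2, max 30.  Short
# times go to neoplasia deaths, the remainder to censored (alive) animals.
_ESCRA_SURVIVAL_DEATHS = [0.0, 0.0, 1.0, 1.0]
_ESCRA_SURVIVAL_ALIVE = [2.0, 2.0, 2.0, 7.9, 10.0, 20.0, 28.0, 30.0, 30.0]


def synthetic_escra_cohort() -> Cohort:
    """Synthetic 55-record registry cohort matching the printed ESCRA
    aggregates (see module docstring)."""
    n = 55
    species = _expand([((c, s), k) for c, s, k in _ESCRA_SPECIES])
    sexes = _expand([(Sex.male, 26), (Sex.female, 20), (Sex.unknown, 9)])
    stages = _expand([(LifeStage.adult, 42), (LifeStage.unknown, 13)])
    ages: list[float | None] = list(map(float, _ESCRA_AGES)) + [None] * (n - len(_ESCRA_AGES))
    diagnoses = _expand([((d, m), k) for d, m, k in _ESCRA_DIAGNOSES])
    metastasis = _expand([(Metastasis.present, 5), (Metastasis.absent, 7),
                          (Metastasis.unknown, 43)])
    locations = _expand(_ESCRA_LOCATIONS)
    treatments = _expand([
        (TreatmentCategory.surgery_only, 17),
        (TreatmentCategory.chemotherapy_only, 1),
        (TreatmentCategory.surgery_and_radiation, 1),
        (TreatmentCategory.no_treatment, 30),
        (TreatmentCategory.unknown_treatment, 6),
    ])
    outcomes = _expand([
        (Outcome.died_neoplasia, 17),
        (Outcome.alive, 9),
        (Outcome.died_other, 14),
        (Outcome.died_unknown_cause, 1),
        (Outcome.unknown, 14),
    ])
    survival: list[float | None] = [None] * n
    for j, t in enumerate(_ESCRA_SURVIVAL_DEATHS):
        survival[j] = t                      # among the neoplasia deaths
    for j, t in enumerate(_ESCRA_SURVIVAL_ALIVE):
        survival[17 + j] = t                 # the nine alive + ...
    # the nine alive records are indices 17..25; the remaining 4 death
    # times above already sit on neoplasia deaths (indices 0..3).

    for name, values in [("species", species), ("sex", sexes), ("stage", stages),
                         ("ages", ages), ("diagnosis", diagnoses),
                         ("metastasis", metastasis), ("location", locations),
                         ("treatment", treatments), ("outcome", outcomes)]:
        assert len(values) == n, f"escra {name} column has {len(values)} entries"

    records = []
    for i in range(n):
        common, scientific = species[i]
        diagnosis, malignancy = diagnoses[i]
        records.append(CaseRecord(
            record_id=f"ESCRA-{i + 1:04d}",
            source=Source.escra,
            species_common=common,
            species_scientific=scientific,
            age_months=ages[i],
            life_stage=stages[i],
            sex=sexes[i],
            diagnosis=diagnosis,
            malignancy=malignancy,
            metastasis=metastasis[i],
            tumor_location=locations[i],
            treatment=treatments[i],
            outcome=outcomes[i],
            survival_months=survival[i],
        ))
    return Cohort(records)


def synthetic_combined_cohort() -> Cohort:
    """Both synthetic source cohorts concatenated (274 records)."""
    return Cohort(
        list(synthetic_literature_cohort()) + list(synthetic_escra_cohort())
    )
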