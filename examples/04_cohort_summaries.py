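"""Descriptive summaries of the reconstructed two-source cohort.

The synthetic table reconstructions carry the published cohort's marginal
composition; every number printed here is recomputed from the records.
"""

from lizonc import (
    combined_species_count, frequency_table, metastasis_summary,
    survival_time_summary, treatment_summary,
)
from lizonc.datasets import synthetic_combined_cohort

cohort = synthetic_combined_cohort()
print(f"combined cohort: {len(cohort)} lizards")

u = combined_species_count(cohort)
print(f"species: {u.n_literature} literature + {u.n_escra} registry "
      f"- {u.n_shared} shared = {u.n_total_unique} unique")

m = metastasis_summary(cohort)
print(f"metastasis: present {m.percent_present}%, absent {m.percent_absent}%, "
      f"unknown {m.percent_unknown_headline}%")

diag = frequency_table(cohort, "diagnosis", by_source=True)["literature"]
lymph = diag[diag.level == "lymphoma"].iloc[0]
print(f"lymphoma (literature): {lymph['count']}/{lymph.denominator} "
      f"({lymph.percent}%)")

t = treatment_summary(cohort, by_source=True)
for src in ("literature", "escra"):
    tab = t[src].table
    surg = int(tab[tab.level == "surgery_only"]["count"].iloc[0])
    print(f"surgery only ({src}): {surg}  "
          f"[pursued {t[src].n_pursued}, none {t[src].n_not_pursued}, "
          f"unknown {t[src].n_unknown}]")

s = survival_time_summary(cohort, by_source=True)
for src, stats in s.items():
    print(f"survival ({src}): n={stats.n_known}, mean {stats.mean:.1f} mo, "
          f"median {stats.median:.0f} mo, range {stats.min:.0f}-{stats.max:.0f}")
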