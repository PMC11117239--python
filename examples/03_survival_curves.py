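"""Kaplan-Meier survival contrasts by malignancy and treatment status.

Groups a synthetic cohort into malignant/benign times untreated/treated/
non-neoplastic-death strata, estimates product-limit curves with log-log
Greenwood 95% bands, prints each group's median survival, and writes a
step plot with '+' censor marks.
"""

from lizonc import default_config, generate_cohort, group_survival, median_survival
from lizonc.survival import plot_km

cohort = generate_cohort(default_config(n_records=274, seed=7))
grouped = group_survival(cohort)

print(f"records excluded for unknown survival time: "
      f"{grouped.n_excluded_unknown_survival}")
print(f"{'group':45s} {'n':>4s} {'median (mo)':>12s}")
for (malig, status), curve in grouped.curves.items():
    n = int(curve.n_events.sum() + curve.n_censored.sum())
    med = median_survival(curve)
    med_s = f"{med:.1f}" if med is not None else "not reached"
    print(f"{malig + ' / ' + status:45s} {n:4d} {med_s:>12s}")

plot_km(grouped.curves, "km_curves.png")
print("\nwrote km_curves.png — untreated neoplasia shows the fastest "
      "mortality, treated neoplasia the slowest, mirroring the configured "
      "event-time means.")
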