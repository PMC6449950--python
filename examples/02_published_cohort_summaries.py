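"""Summary statistics of the bundled 15-cell-line MAE frequency table.

Reproduces the cohort mean/SD and range for both genotype input sets and
the NRAS-vs-BRAF group comparison (Welch t-test).
"""

from maescan import cohort_summary, group_compare, datasets

for input_set in ("non-imputed", "imputed"):
    s = cohort_summary(datasets.sample_summaries(input_set))
    print(f"{input_set:>12}: mean {s['mean']:.2f} +- {s['sd']:.2f} "
          f"(range {s['min']:.2f}-{s['max']:.2f}, n={s['n']})")

g = group_compare(datasets.sample_summaries("non-imputed"))
nras, braf = g["groups"]["NRAS"], g["groups"]["BRAF"]
print(f"\nNRAS lines: mean {nras['mean']:.2f} SD {nras['sd']:.2f} (n={nras['n']})")
print(f"BRAF lines: mean {braf['mean']:.2f} SD {braf['sd']:.2f} (n={braf['n']})")
print(f"Welch t-test p = {g['p_value']:.2f} — no significant difference in MAE")
print("rate between the two mutation groups at this sample size.")
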