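"""Re-run every published comparison from the packaged 50-case cohort.

Prints one row per analysis: pooled t-tests of each metric between the two
blinded radiologist reading classes (and IDH1 status), and the ROC/AUC of
each metric as a discriminator, with DeLong 95% confidence intervals.
"""

from t2texture import reproduce_paper_stats

report = reproduce_paper_stats()

print(f"{'analysis':24s} {'kind':5s} {'estimate':>9s} {'95% CI':>18s} {'p':>9s}")
for row in report.to_records():
    ci = f"({row['ci95_low']:.2f}, {row['ci95_high']:.2f})"
    print(
        f"{row['analysis']:24s} {row['kind']:5s} {row['estimate']:9.4f} "
        f"{ci:>18s} {row['p']:9.2g}"
    )
print()
print("t-test estimates are mean differences (hetero - homo, well defined -")
print("vague, mutant - wild type); ROC estimates are AUCs with the same class")
print("as positive. Heterogeneity (entropy) separates IDH1 status; border")
print("sharpness (edge metrics) does not — the two edge~idh rows stay above")
print("p = 0.05.")
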