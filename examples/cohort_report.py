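"""End-to-end cohort analysis: simulate a young-adult cohort emulating
the reference study's group distributions, run QC, extract the
21-feature table and compute the statistics report.

Scaled down (8 cells per genotype, 500 bootstrap resamples) so it runs
in a few seconds; raise ``n_per_group``/``n_boot`` for smoother numbers.
"""

from picquant import run_report
from picquant.reference import reference_cohort_spec

spec = reference_cohort_spec(("P30-P60",), n_per_group=8, seed=5)
report = run_report(cohort_spec=spec, seed=5, n_boot=500)

print(f"cells simulated: {report['qc']['n_input']}, kept after QC: {report['qc']['n_kept']}")
print("\ngenotype effect sizes (mSOD1 - WT, young adult group):")
for row in report["group_comparisons"]:
    if row["feature"] in ("input_conductance", "pic_amplitude_asc", "rmp", "vthreshold"):
        print(f"  {row['feature']:<22} g = {row['g']:+.2f} "
              f"[{row['ci_low']:+.2f}, {row['ci_high']:+.2f}]")
print("\nascending vs descending concordance (r^2):")
for name, r2 in report["asc_desc_r2"].items():
    print(f"  {name:<22} {r2 if r2 is None else round(r2, 2)}")
if report["ancova"]:
    group, rep = next(iter(report["ancova"].items()))
    print(f"\nANCOVA ({group}): genotype effect at fixed conductance = "
          f"{rep['genotype_effect']:.2f} nA, p = {rep['genotype_p']:.2g}")
# Positive g on conductance and PIC amplitude with negative g on RMP and
# threshold mirrors the young-adult pattern the cohort emulates.
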