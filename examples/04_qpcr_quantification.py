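"""Hemolysis QC, comparative-CT quantification, and group comparison.

Simulates a serum qPCR panel (miR-21-5p target, four reference miRNAs,
patient and control groups, 10% hemolysed samples), excludes contaminated
samples via the dCT(miR-23a-3p - miR-451a) > 7 rule, quantifies expression
as 2^-dCT against the mean reference CT, and compares the log10 values
between groups with an unpaired t-test.
"""

from mirreg import compare_groups, simulate_ct_table
from mirreg.qpcr import expression_table, qc_table

table, truth = simulate_ct_table(seed=17)
refs = ["miR-93-5p", "miR-191-5p", "miR-423-4p", "miR-103a"]

qc = qc_table(table)
excluded = [r for r in qc if not r.passed]
print(f"{len(qc)} samples, {len(excluded)} excluded by hemolysis QC "
      f"(indicator dCT > 7):")
for r in excluded:
    print(f"  {r.sample_id}: dCT = {r.delta_ct_hemolysis:.2f}")

expr = expression_table(table, "miR-21-5p", refs, qc=qc)
by_group: dict[str, list[float]] = {}
for e in expr:
    by_group.setdefault(table.sample_groups[e.sample_id], []).append(e.log_value)

print(f"\nrelative miR-21-5p expression (2^-dCT, log10 for testing):")
cmp = compare_groups(by_group, design="two_group")
for g, d in sorted(cmp.descriptives.items()):
    print(f"  {g}: n={d.n}  mean log10 = {d.mean:.3f} +/- {d.sd:.3f} "
          f"(range {d.minimum:.3f} to {d.maximum:.3f})")
fold = 10 ** (cmp.descriptives["MG"].mean - cmp.descriptives["HC"].mean)
print(f"\nunpaired t-test: t = {cmp.statistic:.2f}, p = {cmp.p_value:.2e}")
print(f"MG/HC fold difference of group means: {fold:.2f}x "
      f"(the generator plants a dCT difference of 1.5 cycles ~ 2.8x)")
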