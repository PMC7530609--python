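"""Y-linked repeat classification and copy-number-corrected expression.

Classifies repeat families as male-specific from sex-resolved genomic
coverage, then asks whether their elevated expression in a two-Y karyotype
reflects transcriptional derepression or just genomic dosage.
"""

import numpy as np

import chromsink as cs
from chromsink.repeats import expression_cpm_per_kb

genome = cs.build_genome_model(seed=77)

cov = cs.simulate_sex_coverage(genome, male_depth=20.0, female_depth=20.0, seed=78)
out = cs.classify_male_specific(cov)
truth = out["true_label"] == "male_specific"
called = out["label"] == "male_specific"
print(f"families: {len(out)}, truly Y-linked: {truth.sum()}, called male-specific: {called.sum()}")
print(f"sensitivity: {(truth & called).sum() / truth.sum():.2f}, "
      f"false discovery rate: {(called & ~truth).sum() / max(called.sum(), 1):.2f}")

effects = cs.ExpressionEffects(n_genes=500, n_y_responsive=0)
gene_counts, rep, _ = cs.simulate_rnaseq(genome, (cs.XY, cs.XYY), effects, seed=55)
fam = genome.repeat_families.set_index("name")
cpm = expression_cpm_per_kb(rep, fam["length"],
                            library_size=gene_counts.sum(axis=0) + rep.sum(axis=0))
ratios = {}
for k in (cs.XY, cs.XYY):
    cn = genome.repeat_copy_number(k)
    per_copy, _ = cs.cn_corrected_expression(
        cpm[[f"{k.label}_rep1", f"{k.label}_rep2"]].mean(axis=1).to_numpy(), cn)
    ratios[k.label] = per_copy
ratio = ratios["XYY"] / ratios["XY"]
y = (fam["true_label"] == "male_specific").to_numpy()
dere = y & fam["derepressed"].to_numpy()
plain = y & ~fam["derepressed"].to_numpy()
print("\nper-copy expression, XYY relative to XY (median):")
print(f"  derepressed Y-linked families: {np.median(ratio[dere]):.2f}  "
      "(the 3x per-copy activation survives correction)")
print(f"  dosage-only Y-linked families: {np.median(ratio[plain]):.2f}  "
      "(raw counts double with the second Y, but per-copy rate is unchanged)")
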