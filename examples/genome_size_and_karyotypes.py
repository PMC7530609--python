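"""Genome-size arithmetic: from flow-cytometry fluorescence ratios to
heterochromatin content, and the karyotype gradient the toy genome encodes.

A sample's diploid genome size is the standard's known size (328 Mb) scaled
by the fluorescence ratio; heterochromatin is what exceeds the fixed
euchromatic portion (232 Mb with two X chromosomes, 210 Mb with one).
"""

import chromsink as cs

# fluorescence peak ratios chosen so the sizes land on the classic gradient
measurements = {
    cs.X0: 319 / 328, cs.XX: 357 / 328, cs.XY: 358 / 328,
    cs.XXY: 390 / 328, cs.XYY: 395 / 328,
}

print("karyotype  diploid_Mb  het_Mb  (euchromatin constant)")
for k, f in measurements.items():
    est = cs.estimate_genome_size(f, 1.0, k)
    print(f"{k.label:>9}  {est.diploid_size_mb:9.1f}  {est.het_content_mb:6.1f}"
          f"  ({est.euchromatin_constant_mb:.0f} Mb)")

print("\nToy genome model (1:100 scale; 1 kb here stands for 1 Mb):")
genome = cs.build_genome_model(seed=1)
for k in cs.STANDARD_KARYOTYPES:
    print(f"{k.label:>9}  het content {genome.het_content_bp(k) / 1000:6.0f} kb")
print("The ordering X0 < XX < XY < XXY < XYY is the repeat-content gradient "
      "that drives the heterochromatin sink downstream.")
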