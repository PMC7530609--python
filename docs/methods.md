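# Methods

This note documents the models, estimators, conventions and numerical
choices behind `chromsink`, and what the synthetic data do and do not
establish.

## The heterochromatin-sink model

The package's organizing hypothesis is that the machinery that writes and
maintains repressive chromatin (H3K9me2/3 and its readers/writers) exists in
a limited cellular pool. A genome with more repetitive DNA spreads that pool
thinner: per-window mark density at heterochromatin falls as total repeat
content rises, and vice versa. The generator encodes this as

    density(karyotype) = base x (reference_het / het_content(karyotype)) ^ exponent

floored at the euchromatic background (`SinkModel`). `exponent = 0` switches
the sink off (the null model: all karyotypes identical after normalization);
`exponent = 1` is strict stoichiometric dilution and is the default.
`het_content` is the diploid sum of heterochromatic block lengths times
chromosome copy number, so the five standard karyotypes fall on the gradient
X0 < XX < XY < XXY < XYY by construction.

Two secondary phenotypes of the same hypothesis are generated alongside:
karyotypes with a repeat *deficit* relative to the reference extend
heterochromatin past the annotated boundary, repeat-rich karyotypes retract
it. The shift is linear in the relative deficit
(`spreading_bp_per_unit_deficit`, default 150 kb at toy scale, i.e. ~40 kb of
spreading for the most repeat-poor karyotype). This is a generative rule, not
a fitted mechanism; it exists so that boundary-analysis code has a planted
truth to recover.

## The toy genome

Chromosome arms are tiled into fixed windows (default 5 kb). The default
genome is a 1:100 scale-down of the fly chromosome-arm arithmetic: four
autosomal arms with 235 kb euchromatin and 100–110 kb pericentromeric
heterochromatin each, a fully heterochromatic 40 kb dot, an X with 220 kb
euchromatin (the per-X euchromatin difference between the 232 and 210 Mb
diploid constants) and 160 kb heterochromatin, and a fully heterochromatic
400 kb Y. Diploid heterochromatin totals come out at 1090/1250/1490/1650/
1890 kb for X0/XX/XY/XXY/XYY — the measured ~109–185 Mb gradient at scale,
up to the additive idealization (measured XXY and XYY sizes are a few
percent below the sum of their parts; the model is strictly additive).
All downstream statistics are scale-free ratios, so the 1:100 scale only
reduces window counts; the methods-level note is that problem sizes in tests
and the acceptance script (hundreds of windows, depth 1–2 million
read-equivalents) were chosen as the smallest sizes at which sampling error
is clearly separated from the effects under test.

Boundary convention: each autosomal/X arm has exactly one
heterochromatin/euchromatin boundary; `het_side` records which end carries
the block, and a heterochromatin fraction of zero puts the boundary at
position 0 with the whole arm euchromatic. Windows are assigned to blocks
(and to boundary sides) by their midpoints, which bounds any
boundary-assignment error by one window width.

## Sequencing model

One sample contributes a fixed unit of target chromatin mass regardless of
genome size (a fixed amount of tissue), plus `spike_amount` units of
foreign-species chromatin (default 0.1, giving ~9% spike reads in input —
a small spike fraction, as in practice). Input reads sample chromatin mass;
ChIP reads sample mass x mark density; both are drawn as a single
multinomial of `depth` reads over all target and spike windows. The spike's
mark density is constant across samples — that constancy is the entire basis
of the normalization. A multiplicative GC bias `exp(beta (gc - 0.5))`
applies to reads of both species (default beta 0 in the generator; 0.6–1.0
in the tests that exercise correction). Cross-mapping is modeled as a
configured fraction (default 2.5%) of spike reads leaking into a masked
subset of target windows; masked windows are excluded from all analyses, and
library totals therefore carry a small (<1%) contamination, as real totals
do. Per-window GC is uniform on [0.20, 0.55] in heterochromatin (AT-rich)
and [0.35, 0.80] in euchromatin.

## Normalization estimators

Per-window signal:

    signal_w = [(c_w/(Mc+Sc)) / (i_w/(Mi+Si))] x factor,   factor = phi_input/phi_chip

with `phi = spike/(target+spike)`; algebraically `signal_w = (c_w/i_w)(Si/Sc)`.
The direction of the factor is fixed by the requirement that a genome-wide
dilution of the true mark density lowers the signal; the inverse reading
would reverse every contrast. Zero-input windows are missing rather than
zero; an optional pseudocount (default 0) is added to both coverages.

Global mark abundance is quantified by the relative recovery
`R = (Mc/Sc)/(Mi/Si)`, which equals the abundance-weighted mean target mark
density divided by the spike density and is therefore exactly proportional
to a planted global dilution. Note that the window-level `factor` itself is
not: its ratio across samples is `(dT+P)/(T+P)` for target/spike marked mass
`T, P` and dilution `d`, approaching `d` only for small spike fractions.
Cross-sample recovery comparisons use `R`.

The regression estimator fits a through-the-origin least-squares slope of
depth-normalized spike ChIP coverage on depth-normalized spike input
coverage over all spike windows genome-wide (the per-chromosome variant was
considered and rejected as needless at these window counts) and returns the
reciprocal slope. On noiseless data with proportional spike profiles it
equals the ratio estimator identically; the test suite asserts agreement to
1e-12 there and to 2% across dilutions.

The unspiked estimator `(c_w/Mc)/(i_w/Mi)` normalizes by target reads only,
as a spike-free library would; it preserves profile shape and is provably
blind to global dilution — the property the acceptance suite demonstrates.

## GC correction

Expected coverage is the mean over unmasked windows within GC bins of width
0.05; bins are half-open `[lo, hi)` with the top bin closed so GC = 1.0 is
not lost. Observed values are divided by their bin's expectation. Bins with
fewer than `min_windows` (default 10) windows are flagged unreliable (values
kept, flag returned); empty bins yield missing values, counted in track
metadata. The expectation is fitted per input library rather than pooled
(recorded in output metadata). An optional mean-preservation rescales the
corrected track to the raw mean. Repeat consensus coverage is corrected by
the same model keyed on the repeat's GC.

The binned estimator removes the *between-bin* trend but cannot remove the
residual trend *within* a bin; with bin width w the residual within-bin
variance of GC is w^2/12, so the post/pre slope ratio on a planted
exponential bias is approximately Var_within/Var_total of the GC
distribution. The correction-validation fixture therefore uses GC uniform on
[0.2, 0.8] (Var_total = 0.03, predicted residual ~0.7%); on a genome with a
much narrower GC distribution the same estimator leaves a proportionally
larger residual slope. This is a property of the method, not of the
implementation. GC correction is applied in the heterochromatic-mark
pipeline (where repeat GC extremes matter) and is optional elsewhere.

## Window statistics

Subtraction tracks are signed per-window differences (an absolute-value
variant is available); signed differences are needed to see the direction of
redistribution. Box summaries use type-7 (linear interpolation) quartiles —
the whisker reach depends on the convention, so it is fixed and documented —
with whiskers at the most extreme point within 1.5 IQR. Rank comparisons are
Mann–Whitney U, exact when the smaller sample has at most 8 observations and
the pooled data are tie-free, otherwise the normal approximation with tie
and continuity corrections; tests are two-sided by default. Multi-region,
multi-sample tables report unadjusted p plus Benjamini–Hochberg q-values.

The spreading index summarizes a boundary profile (default flank 1 Mb at
full scale, 100 kb at toy scale) as (i) the contrast
`(mean_in − mean_out)/(mean_in + mean_out)` of the heterochromatin versus
euchromatin side of the annotated boundary and (ii) the breakpoint of the
best least-squares step function over all inter-window breakpoints, signed
positive when heterochromatin extends into euchromatin. A step fit was
preferred over a sigmoid because it is exact on planted steps, has no
initialization or convergence failure modes, and its error is bounded by one
window; profiles whose best step explains essentially none of the variance
(relative SSE reduction < 1e-6) return no shift. Note that under strong
spreading the contrast against the *annotated* boundary shrinks even as
enrichment rises — the shift, not the contrast, is the spreading readout.

Per-gene signal is the length-weighted mean of overlapping window values;
genes overlapping masked windows are flagged, genes outside the assembly are
flagged rather than fatal. Concordance QC reports the Pearson correlation
and the top-q window overlap `|topA ∩ topB|/(qn)` (q = 0.40 by default).

## Repeat classification and expression

A family is called male-specific when its depth-normalized male coverage is
at least `min_male_cov` times single-copy coverage (default 5 — matching the
repeat-assembly notion that a repeat occurs at least five times) and the
female signal is either exactly zero or both below `max_female_ratio`
(default 0.1) and significantly below the equal-abundance expectation by a
one-sided binomial test on read counts at `alpha = 0.01` with Bonferroni
correction across families. The thresholds are unavoidably conventional
("high coverage", "significantly lower" are qualitative in the field); all
are config-exposed and echoed into the output table. Classification is
invariant to common rescaling of the two sexes' depths.

Copy number is input coverage divided by the mean input coverage of
annotated single-copy euchromatin. Expression is counts-per-million over the
joint gene+repeat universe, per kb of consensus, divided by copies; per-copy
expression is invariant under joint rescaling of expression and copies, so a
pure dosage change (a second Y doubling Y-linked copy numbers) corrects to
~1x while a planted 3x per-copy derepression survives.

## Overlap statistics

Genes are ranked by `|log2((CPM_A + pc)/(CPM_B + pc))|` with pseudocount 0.5
and deterministic tie-breaking by gene id (ranking by an externally supplied
p-value ordering is accepted as input; the |lfc| default is used because the
pipeline deliberately carries no dispersion model). rRNA-scaffold genes are
excluded before ranking via the `exclude` argument. The universe N defaults
to all retained genes and is always reported, because the chance expectation
`N (k/N)^m` depends on it; with m = 3, k = 1000 and N = 9535 that
expectation is 11.0 — the scale at which an observed overlap of several
hundred is decisive. The permutation null draws m independent uniform
k-subsets per iteration (gene labels exchangeable) — the minimal null
consistent with the closed form; p-values use the add-one estimator
`(1 + #{perm ≥ obs})/(n_perm + 1)` and are bounded below by `1/(n_perm+1)`.
A stricter null that permutes sample labels and re-ranks (preserving
inter-contrast correlation) is provided as `label_permutation_overlap`.

Calibration caveat: with an |lfc| ranking, even effect-free data produce
top-k sets that are mildly correlated across contrasts sharing samples or
gene-level means (low-expression genes are the noisiest everywhere), so
observed overlaps sit slightly above the independent-subset expectation
under the null. The uniformity of the permutation p-values is verified on
configurations where the overlap statistic is well spread (k/N = 1/2); for
very small k/N the statistic is coarsely discrete and p-values are valid but
conservative.

## Expression generator

Gene baselines are lognormal (median 50 counts, sigma 1.2); counts are
negative binomial with dispersion 0.05, two replicates per karyotype. The
planted structure is a set of Y-presence-responsive genes (default 660 of
3000, |lfc| 2, random sign) that are differential in every contrast
separating a Y-bearing from a Y-less karyotype — the shared signal the
top-k overlap detects. Repeat counts are Poisson around
copies x per-copy rate x length, with a 3x per-copy derepression applied to
flagged Y-linked families in karyotypes whose repeat content exceeds the
wildtype-male reference (XXY, XYY).

## What the synthetic data do not show

The generator reproduces the *statistical* structure the estimators consume,
not the biology or the sequencing process: no read-level simulation,
mappability, fragment-length or PCR effects (coverage is sampled at window
resolution); a single scalar mark density per block per karyotype rather
than locus-specific chromatin states; sink dilution that is exactly a power
law in repeat content; cross-mapping as a uniform leak rather than
homology-driven; repeat families without sequence, age structure or
truncation; and expression effects that are planted indicator-based fold
changes rather than regulatory responses. Passing tests therefore establish
that the estimators recover what they claim to recover under their stated
assumptions — unbiased dilution recovery, GC-trend removal to the binning
limit, boundary localization to one window, classification accuracy at
given depth — not that those assumptions hold in any particular real
data set. The flow-cytometry module likewise starts from fluorescence
ratios; gating and peak-finding on raw cytometry files are out of scope, as
are read alignment, dispersion-modeled differential expression, and GO
enrichment.
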