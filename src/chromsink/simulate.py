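"""Synthetic genomes, chromatin mixtures, and count tables.

The generator emulates the statistical structure of a two-species spike-in
ChIP experiment across fly karyotypes with differing repeat content:

* a toy genome of chromosome arms tiled into fixed windows, each arm split
  into euchromatin and a pericentromeric heterochromatin block (plus an
  all-heterochromatic dot chromosome and Y), at 1:100 the scale of the real
  assembly so the karyotype heterochromatin gradient (X0 < XX < XY < XXY <
  XYY) is reproduced by chromosome-arm arithmetic;
* a "heterochromatin sink": the per-window density of the repressive mark in
  heterochromatin scales inversely with the karyotype's total repeat content,
  embodying a fixed pool of silencing machinery spread over more or less
  repetitive DNA; karyotypes with a repeat deficit additionally spread
  heterochromatin past the annotated boundary, and repeat-rich karyotypes
  retract it;
* sequencing as multinomial sampling over target plus spike windows, with a
  multiplicative GC bias exp(beta * (gc - 0.5)) and a configurable fraction
  of spike reads cross-mapping into masked target windows;
* sex-resolved genomic coverage of repeat families (Y-linked families have
  zero true female coverage, plus a small cross-mapping background);
* RNA-seq count tables with negative-binomial noise and planted
  karyotype-dependent effects, including Y-presence-responsive genes shared
  across contrasts and copy-number-driven versus per-copy derepression of
  Y-linked repeats.

Every function is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import WindowTrack
from .karyotype import XY, KaryotypeSpec
from .spikenorm import LibraryComposition


# ---------------------------------------------------------------------------
# genome configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """One chromosome arm: total length, heterochromatic length, and kind.

    ``kind`` is one of ``autosome``, ``X``, ``Y``, ``dot``.  For ``Y`` and
    ``dot`` the whole arm is heterochromatic.  ``het_side`` says which end of
    the arm carries the pericentromeric block ("left" = block starts at 0).
    """

    name: str
    length: int
    het_length: int
    kind: str = "autosome"
    het_side: str = "left"

    def __post_init__(self) -> None:
        if self.kind not in ("autosome", "X", "Y", "dot"):
            raise ValueError(f"unknown arm kind {self.kind!r}")
        if not (0 <= self.het_length <= self.length):
            raise ValueError(f"arm {self.name}: heterochromatin fraction outside [0, 1]")
        if self.kind in ("Y", "dot") and self.het_length != self.length:
            raise ValueError(f"arm {self.name}: {self.kind} must be fully heterochromatic")
        if self.het_side not in ("left", "right"):
            raise ValueError("het_side must be 'left' or 'right'")


def default_arms() -> tuple[ArmSpec, ...]:
    """A 1:100 scale-down of the chromosome-arm arithmetic of the fly genome.

    Euchromatin 235 kb per autosomal arm and 220 kb on the X (the 22 Mb
    per-X euchromatin difference between the 232 and 210 Mb constants),
    pericentromeric blocks of ~1 Mb per diploid autosome set, a 40 kb fully
    heterochromatic dot, a 160 kb X heterochromatin block and a 400 kb fully
    heterochromatic Y.  Diploid heterochromatin totals per karyotype come out
    at 1090/1250/1490/1650/1890 kb for X0/XX/XY/XXY/XYY, i.e. the measured
    ~109-185 Mb gradient at 1:100 scale.
    """
    return (
        ArmSpec("2L", 340_000, 105_000, "autosome", "right"),
        ArmSpec("2R", 345_000, 110_000, "autosome", "left"),
        ArmSpec("3L", 335_000, 100_000, "autosome", "right"),
        ArmSpec("3R", 345_000, 110_000, "autosome", "left"),
        ArmSpec("4", 40_000, 40_000, "dot"),
        ArmSpec("X", 380_000, 160_000, "X", "right"),
        ArmSpec("Y", 400_000, 400_000, "Y"),
    )


@dataclass(frozen=True)
class RepeatLibraryConfig:
    """Composition of the synthetic repeat library."""

    n_families: int = 200
    n_y_linked: int = 20
    n_x_linked: int = 10
    n_derepressed: int = 5          # Y-linked families with planted per-copy derepression
    copy_range: tuple[int, int] = (5, 50)
    median_length: int = 101        # bp; lengths are lognormal around this
    length_sigma: float = 0.6
    derepression_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.n_y_linked + self.n_x_linked > self.n_families:
            raise ValueError("more sex-linked families than families")
        if self.n_derepressed > self.n_y_linked:
            raise ValueError("derepressed families must be Y-linked")


@dataclass(frozen=True)
class GenomeConfig:
    arms: tuple[ArmSpec, ...] = field(default_factory=default_arms)
    window_width: int = 5000
    crossmap_fraction: float = 0.025   # spike reads leaking into masked target windows
    gc_range_het: tuple[float, float] = (0.20, 0.55)   # AT-rich heterochromatin
    gc_range_eu: tuple[float, float] = (0.35, 0.80)
    n_spike_windows: int = 200
    repeats: RepeatLibraryConfig = field(default_factory=RepeatLibraryConfig)

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ValueError("window_width must be positive")
        if not (0 <= self.crossmap_fraction < 1):
            raise ValueError("crossmap_fraction must be in [0, 1)")
        if not self.arms or sum(a.length for a in self.arms) == 0:
            raise ValueError("zero-length genome")


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class GenomeModel:
    """Windowed toy genome with annotation, GC track, mask, and repeat stubs."""

    config: GenomeConfig
    windows: pd.DataFrame        # chrom, start, end, gc, block, arm_kind
    blocks: pd.DataFrame         # chrom, start, end, label
    boundaries: dict             # arm name -> {"position": bp, "het_side": str}
    crossmap_mask: np.ndarray    # bool per window, True = excluded
    repeat_families: pd.DataFrame
    spike_gc: np.ndarray
    seed: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def window_width(self) -> int:
        return self.config.window_width

    def track(self, values) -> WindowTrack:
        return WindowTrack(self.windows[["chrom", "start", "end"]].assign(value=np.asarray(values, float)))

    def window_ploidy(self, karyotype: KaryotypeSpec) -> np.ndarray:
        """Copy number of each window under the given sex-chromosome complement."""
        kind = self.windows["arm_kind"].to_numpy()
        ploidy = np.full(self.n_windows, karyotype.autosome_ploidy, dtype=float)
        ploidy[kind == "X"] = karyotype.n_X
        ploidy[kind == "Y"] = karyotype.n_Y
        return ploidy

    def het_content_bp(self, karyotype: KaryotypeSpec) -> float:
        """Total heterochromatin per diploid cell: sum of het block lengths x ploidy."""
        total = 0.0
        kinds = {a.name: a.kind for a in self.config.arms}
        for row in self.blocks.itertuples(index=False):
            if row.label == "euchromatin":
                continue
            kind = kinds[row.chrom]
            mult = {"autosome": karyotype.autosome_ploidy, "dot": karyotype.autosome_ploidy,
                    "X": karyotype.n_X, "Y": karyotype.n_Y}[kind]
            total += (row.end - row.start) * mult
        return total

    def repeat_copy_number(self, karyotype: KaryotypeSpec) -> np.ndarray:
        fam = self.repeat_families
        return (
            karyotype.autosome_ploidy * fam["copies_auto"].to_numpy(float)
            + karyotype.n_X * fam["copies_per_X"].to_numpy(float)
            + karyotype.n_Y * fam["copies_per_Y"].to_numpy(float)
        )


def _block_label(kind: str) -> str:
    return {"autosome": "pericentromere", "X": "pericentromere", "dot": "dot", "Y": "Y_het"}[kind]


def build_genome_model(config: GenomeConfig | None = None, seed: int = 0) -> GenomeModel:
    """Tile the configured arms into windows with GC, blocks, mask and repeats."""
    config = config or GenomeConfig()
    rng = np.random.default_rng(seed)

    win_rows, block_rows = [], []
    boundaries: dict[str, dict] = {}
    for arm in config.arms:
        eu_len = arm.length - arm.het_length
        if arm.het_side == "left":
            het_iv = (0, arm.het_length)
            eu_iv = (arm.het_length, arm.length)
            boundary = arm.het_length
        else:
            eu_iv = (0, eu_len)
            het_iv = (eu_len, arm.length)
            boundary = eu_len
        label = _block_label(arm.kind)
        if arm.het_length > 0:
            block_rows.append((arm.name, het_iv[0], het_iv[1], label))
        if eu_len > 0:
            block_rows.append((arm.name, eu_iv[0], eu_iv[1], "euchromatin"))
        if arm.kind in ("autosome", "X"):
            boundaries[arm.name] = {"position": boundary, "het_side": arm.het_side}
        n_win = -(-arm.length // config.window_width)  # ceil; partial last window kept
        for w in range(n_win):
            start = w * config.window_width
            end = min(start + config.window_width, arm.length)
            mid = (start + end) / 2
            in_het = het_iv[0] <= mid < het_iv[1] if arm.het_length > 0 else False
            win_rows.append((arm.name, start, end, label if in_het else "euchromatin", arm.kind))

    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end", "block", "arm_kind"])
    blocks = pd.DataFrame(block_rows, columns=["chrom", "start", "end", "label"]).sort_values(
        ["chrom", "start"], kind="mergesort").reset_index(drop=True)

    is_het = (windows["block"] != "euchromatin").to_numpy()
    lo_h, hi_h = config.gc_range_het
    lo_e, hi_e = config.gc_range_eu
    gc = np.where(is_het, rng.uniform(lo_h, hi_h, len(windows)), rng.uniform(lo_e, hi_e, len(windows)))
    windows.insert(3, "gc", gc)

    crossmap_mask = rng.random(len(windows)) < config.crossmap_fraction

    rc = config.repeats
    n = rc.n_families
    lengths = np.maximum(30, rng.lognormal(np.log(rc.median_length), rc.length_sigma, n)).astype(int)
    copies = rng.integers(rc.copy_range[0], rc.copy_range[1] + 1, n)
    copies_auto = np.zeros(n)
    copies_per_X = np.zeros(n)
    copies_per_Y = np.zeros(n)
    label = np.array(["shared"] * n, dtype=object)
    copies_per_Y[: rc.n_y_linked] = copies[: rc.n_y_linked]
    label[: rc.n_y_linked] = "male_specific"
    sl = slice(rc.n_y_linked, rc.n_y_linked + rc.n_x_linked)
    copies_per_X[sl] = copies[sl]
    copies_auto[rc.n_y_linked + rc.n_x_linked :] = copies[rc.n_y_linked + rc.n_x_linked :]
    derepressed = np.zeros(n, dtype=bool)
    derepressed[: rc.n_derepressed] = True
    repeat_families = pd.DataFrame({
        "name": [f"rep{i:04d}" for i in range(n)],
        "length": lengths,
        "gc": rng.uniform(0.2, 0.7, n),
        "copies_auto": copies_auto,
        "copies_per_X": copies_per_X,
        "copies_per_Y": copies_per_Y,
        "base_rate": rng.lognormal(np.log(5.0), 0.5, n),  # per-copy, per-kb expression rate
        "derepressed": derepressed,
        "true_label": label,
    })

    spike_gc = rng.uniform(0.25, 0.75, config.n_spike_windows)

    return GenomeModel(config, windows, blocks, boundaries, crossmap_mask,
                       repeat_families, spike_gc, seed)


# ---------------------------------------------------------------------------
# heterochromatin sink
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SinkModel:
    """Fixed pool of silencing machinery diluted over the genome's repeats.

    The per-window density of the repressive mark in heterochromatin is

        density(k) = base * (reference_het / het_content(k)) ** exponent

    floored at the euchromatic background.  ``exponent = 0`` switches the
    sink off (all karyotypes identical); ``exponent = 1`` is strict
    stoichiometric dilution.  Karyotypes whose repeat content falls below the
    reference additionally spread heterochromatin past the annotated
    boundary (and repeat-rich ones retract it), by
    ``spreading_bp_per_unit_deficit * (ref - het) / ref`` base pairs.
    """

    reference_het_content: float | None = None  # bp; default: XY content of the genome used
    mark_density_base: float = 10.0
    euchromatin_floor: float = 0.5
    exponent: float = 1.0
    spreading_bp_per_unit_deficit: float = 150_000.0

    def reference(self, genome: GenomeModel) -> float:
        if self.reference_het_content is not None:
            return self.reference_het_content
        return genome.het_content_bp(XY)

    def het_density(self, het_content: float, reference: float) -> float:
        d = self.mark_density_base * (reference / het_content) ** self.exponent
        return max(d, self.euchromatin_floor)

    def boundary_shift(self, het_content: float, reference: float) -> float:
        """Signed shift of the effective boundary, positive = into euchromatin."""
        return self.spreading_bp_per_unit_deficit * (reference - het_content) / reference


# ---------------------------------------------------------------------------
# ChIP experiment simulation
# ---------------------------------------------------------------------------

@dataclass
class ChipExperiment:
    """Paired ChIP and input libraries for one sample, plus simulation truth."""

    karyotype: KaryotypeSpec
    chip: LibraryComposition
    input: LibraryComposition
    spike_chip_cov: np.ndarray
    spike_input_cov: np.ndarray
    true_density: np.ndarray     # per-window mark density actually used
    het_content_bp: float
    params: dict = field(default_factory=dict)


def simulate_chip_experiment(genome: GenomeModel, karyotype: KaryotypeSpec,
                             sink: SinkModel, spike_amount: float = 0.1,
                             depth: int = 1_000_000, noise: bool = True, seed: int = 0,
                             gc_beta: float = 0.0, density_scale: float = 1.0,
                             boundary_shift_bp: float | None = None,
                             spike_mark_density: float = 5.0) -> ChipExperiment:
    """Simulate one spike-in ChIP experiment.

    The sample contributes one unit of target chromatin mass (independent of
    genome size -- a fixed amount of tissue) and ``spike_amount`` units of
    spike chromatin, constant across samples.  Input reads sample chromatin
    mass; ChIP reads sample mass x mark density.  Both are biased by
    exp(gc_beta * (gc - 0.5)) and drawn as one multinomial of ``depth`` reads
    over all target and spike windows (expected counts if ``noise`` is off).
    ``density_scale`` applies a global multiplicative dilution of the target
    mark (spike unaffected), the quantity spike-in normalization exists to
    recover.  True per-window densities are returned for parameter-recovery
    tests.
    """
    if depth < 10_000:
        raise ValueError("depth must be >= 1e4 read-equivalents")
    if spike_amount <= 0:
        raise ValueError("spike_amount must be positive")
    rng = np.random.default_rng(seed)

    reference = sink.reference(genome)
    het_content = genome.het_content_bp(karyotype)
    if het_content <= 0:
        raise ValueError(f"karyotype {karyotype.label} has zero heterochromatin content")
    het_density = sink.het_density(het_content, reference) * density_scale
    eu_density = sink.euchromatin_floor * density_scale
    if boundary_shift_bp is None:
        boundary_shift_bp = sink.boundary_shift(het_content, reference)

    win = genome.windows
    mid = (win["start"].to_numpy() + win["end"].to_numpy()) / 2
    is_het = (win["block"] != "euchromatin").to_numpy().copy()
    # effective boundary shift on arms that have a boundary
    for arm, info in genome.boundaries.items():
        on_arm = (win["chrom"] == arm).to_numpy()
        b = info["position"]
        if info["het_side"] == "left":
            is_het[on_arm] = mid[on_arm] < b + boundary_shift_bp
        else:
            is_het[on_arm] = mid[on_arm] >= b - boundary_shift_bp
    density = np.where(is_het, het_density, eu_density)

    ploidy = genome.window_ploidy(karyotype)
    width = (win["end"] - win["start"]).to_numpy(float)
    mass = ploidy * width
    mass = mass / mass.sum()  # one unit of target chromatin mass
    gcf = np.exp(gc_beta * (win["gc"].to_numpy() - 0.5))
    spike_mass = np.full(len(genome.spike_gc), spike_amount / len(genome.spike_gc))
    spike_gcf = np.exp(gc_beta * (genome.spike_gc - 0.5))

    def _sample(target_weight: np.ndarray, spike_weight: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cm = genome.config.crossmap_fraction
        tw, sw = target_weight.copy(), spike_weight * (1 - cm)
        masked = genome.crossmap_mask
        if masked.any() and cm > 0:
            leak = spike_weight.sum() * cm
            tw[masked] += leak * target_weight[masked] / max(target_weight[masked].sum(), 1e-300)
        probs = np.concatenate([tw, sw])
        probs = probs / probs.sum()
        if noise:
            counts = rng.multinomial(depth, probs).astype(float)
        else:
            counts = depth * probs
        return counts[: len(tw)], counts[len(tw):]

    in_t, in_s = _sample(mass * gcf, spike_mass * spike_gcf)
    chip_t, chip_s = _sample(mass * density * gcf,
                             spike_mass * spike_mark_density * spike_gcf)

    return ChipExperiment(
        karyotype=karyotype,
        chip=LibraryComposition(chip_t.sum(), chip_s.sum(), chip_t),
        input=LibraryComposition(in_t.sum(), in_s.sum(), in_t),
        spike_chip_cov=chip_s,
        spike_input_cov=in_s,
        true_density=density,
        het_content_bp=het_content,
        params={"spike_amount": spike_amount, "depth": depth, "noise": noise,
                "gc_beta": gc_beta, "density_scale": density_scale,
                "boundary_shift_bp": boundary_shift_bp, "seed": seed},
    )


# ---------------------------------------------------------------------------
# sex-resolved genomic coverage of repeats
# ---------------------------------------------------------------------------

def simulate_sex_coverage(genome: GenomeModel, male_depth: float = 20.0,
                          female_depth: float = 20.0, seed: int = 0,
                          read_length: int = 50, crossmap_rate: float = 0.005) -> pd.DataFrame:
    """Per-repeat male/female genomic coverage with truth labels.

    ``male_depth``/``female_depth`` are mean per-bp coverages per single
    genomic copy.  Coverage is proportional to copies x depth, Poisson-sampled
    at read resolution.  Families absent from a sex still receive a small
    cross-mapping background (``crossmap_rate`` x the other sex's level).
    """
    rng = np.random.default_rng(seed)
    fam = genome.repeat_families
    male = KaryotypeSpec("male", n_X=1, n_Y=1)
    female = KaryotypeSpec("female", n_X=2, n_Y=0)
    cn_m = genome.repeat_copy_number(male)
    cn_f = genome.repeat_copy_number(female)
    lengths = fam["length"].to_numpy(float)

    def _reads(cn, depth, other_cn, other_depth):
        cov = cn * depth + crossmap_rate * other_cn * other_depth
        lam = cov * lengths / read_length
        return rng.poisson(lam).astype(float)

    reads_m = _reads(cn_m, male_depth, cn_f, female_depth)
    reads_f = _reads(cn_f, female_depth, cn_m, male_depth)
    out = pd.DataFrame({
        "name": fam["name"],
        "length": fam["length"],
        "gc": fam["gc"],
        "male_reads": reads_m,
        "female_reads": reads_f,
        "male_cov": reads_m * read_length / lengths,
        "female_cov": reads_f * read_length / lengths,
        "true_label": fam["true_label"],
    })
    out.attrs["male_depth"] = male_depth
    out.attrs["female_depth"] = female_depth
    return out


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionEffects:
    """Planted karyotype-dependent expression structure.

    ``n_y_responsive`` genes respond to the presence of a Y chromosome with
    log2 fold change of magnitude ``lfc_y`` (random sign): these genes are
    differential in male-vs-female, X0-vs-XY and XX-vs-XXY contrasts alike,
    the shared signal the top-k overlap statistic detects.  Y-linked repeat
    families marked ``derepressed`` get ``derepression_factor`` times the
    per-copy transcription rate in karyotypes whose repeat content exceeds
    the wildtype-male reference (XXY, XYY).
    """

    n_genes: int = 3000
    n_y_responsive: int = 660
    lfc_y: float = 2.0
    base_mean: float = 50.0
    base_sigma: float = 1.2
    dispersion: float = 0.05
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.n_y_responsive > self.n_genes:
            raise ValueError("more responsive genes than genes")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")


def simulate_rnaseq(genome: GenomeModel, karyotypes, effects: ExpressionEffects | None = None,
                    seed: int = 0):
    """Gene and repeat count tables with replicates per karyotype, plus truth.

    Returns ``(gene_counts, repeat_counts, gene_truth)``: counts are gene x
    sample DataFrames with columns ``<label>_rep<j>``; ``gene_truth`` lists
    each gene's planted Y-response log2 fold change (0 for unaffected genes).
    Gene counts are negative-binomial around baseline x 2**(lfc * [n_Y > 0]);
    repeat counts are Poisson around copy_number x per-copy rate x length,
    with derepression applied per the effects config.
    """
    effects = effects or ExpressionEffects()
    rng = np.random.default_rng(seed)
    n = effects.n_genes
    base = rng.lognormal(np.log(effects.base_mean), effects.base_sigma, n)
    lfc = np.zeros(n)
    signs = rng.choice([-1.0, 1.0], effects.n_y_responsive)
    lfc[: effects.n_y_responsive] = effects.lfc_y * signs
    genes = [f"gene{i:05d}" for i in range(n)]

    fam = genome.repeat_families
    ref_het = genome.het_content_bp(XY)

    gene_cols, repeat_cols = {}, {}
    for k in karyotypes:
        mu = base * np.power(2.0, lfc * (1.0 if k.n_Y > 0 else 0.0))
        cn = genome.repeat_copy_number(k)
        derepress = np.where(
            fam["derepressed"].to_numpy() & (genome.het_content_bp(k) > ref_het),
            genome.config.repeats.derepression_factor, 1.0)
        rep_mu = cn * fam["base_rate"].to_numpy() * derepress * fam["length"].to_numpy() / 1000.0
        for j in range(1, effects.n_replicates + 1):
            if effects.dispersion > 0:
                shape = 1.0 / effects.dispersion
                gcounts = rng.negative_binomial(shape, shape / (shape + mu))
            else:
                gcounts = rng.poisson(mu)
            gene_cols[f"{k.label}_rep{j}"] = gcounts
            repeat_cols[f"{k.label}_rep{j}"] = rng.poisson(rep_mu)

    gene_counts = pd.DataFrame(gene_cols, index=pd.Index(genes, name="gene"))
    repeat_counts = pd.DataFrame(repeat_cols, index=pd.Index(fam["name"], name="name"))
    gene_truth = pd.DataFrame({"gene": genes, "lfc_y": lfc,
                               "y_responsive": lfc != 0}).set_index("gene")
    return gene_counts, repeat_counts, gene_truth
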