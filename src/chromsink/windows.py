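"""Cross-karyotype window comparisons.

Subtraction tracks between karyotypes, per-region boxplot summaries with
rank-sum tests against a designated reference sample, profiles across the
heterochromatin/euchromatin boundary, a spreading index quantifying boundary
movement, per-gene signal averages, and top-window concordance QC.

Quartiles use linear interpolation (numpy default, type 7); whiskers reach
the most extreme point within 1.5 x IQR of the box.  Rank-sum tests are
Mann-Whitney U: exact null when min(n) <= 8 with no ties, otherwise normal
approximation with tie and continuity correction.  Windows straddling a
boundary are assigned to a side by their midpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import WindowTrack
from .simulate import GenomeModel


# ---------------------------------------------------------------------------
# subtraction tracks
# ---------------------------------------------------------------------------

def subtraction_track(signal_a: WindowTrack, signal_b: WindowTrack,
                      absolute: bool = False) -> WindowTrack:
    """Per-window A - B (signed), or |A - B| with ``absolute``."""
    if not signal_a.same_windows(signal_b):
        raise ValueError("subtraction requires identical windows")
    diff = signal_a.values - signal_b.values
    if absolute:
        diff = np.abs(diff)
    return signal_a.with_values(diff, meta={"op": "abs_subtraction" if absolute else "subtraction"})


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U of ``x`` relative to ``y``; returns (U, p).

    Exact enumeration of the null when the smaller sample has <= 8
    observations and there are no ties across the pooled data; otherwise the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    """Boxplot-style summary of one region's window signal, with a test vs a reference."""

    region: str
    n_windows: int
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    mean: float
    reference: str | None = None
    statistic: float | None = None
    p_value: float | None = None


def _box_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    in_reach = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
    return q1, med, q3, float(in_reach.min()), float(in_reach.max())


def region_windows(signal: WindowTrack, genome: GenomeModel, region: str) -> np.ndarray:
    """Finite signal values of windows whose block label matches ``region``.

    ``region`` is a block label (``euchromatin``, ``pericentromere``, ``dot``,
    ``Y_het``) optionally suffixed with an arm name, e.g.
    ``pericentromere_2L``.
    """
    blocks = genome.windows["block"].to_numpy()
    chroms = genome.windows["chrom"].to_numpy()
    if "_" in region and region.rsplit("_", 1)[0] in set(blocks):
        label, arm = region.rsplit("_", 1)
        sel = (blocks == label) & (chroms == arm)
    else:
        sel = blocks == region
    if not sel.any():
        raise ValueError(f"region {region!r} matches no windows")
    vals = signal.values[sel]
    return vals[np.isfinite(vals)]


def region_summary(signal: WindowTrack, genome: GenomeModel, region: str,
                   reference_signal: WindowTrack | None = None,
                   reference_label: str | None = None,
                   alternative: str = "two-sided") -> RegionSummary:
    """Quartile/whisker summary of a region, with a rank-sum test against the
    same region in a designated reference sample."""
    vals = region_windows(signal, genome, region)
    if vals.size < 2:
        raise ValueError(f"region {region!r} has < 2 windows with signal")
    q1, med, q3, wlo, whi = _box_stats(vals)
    out = RegionSummary(region, vals.size, q1, med, q3, wlo, whi, float(vals.mean()))
    if reference_signal is not None:
        ref_vals = region_windows(reference_signal, genome, region)
        out.reference = reference_label
        out.statistic, out.p_value = rank_sum_test(vals, ref_vals, alternative=alternative)
    return out


def summarize_regions(signals: dict[str, WindowTrack], genome: GenomeModel,
                      regions: list[str], reference_of: dict[str, str]) -> pd.DataFrame:
    """Region x sample summary table with BH q-values over all tests.

    ``reference_of`` maps each sample label to the label it is tested against
    (samples absent from the map are summarized without a test).
    """
    rows = []
    for label, sig in signals.items():
        ref_label = reference_of.get(label)
        for region in regions:
            rs = region_summary(sig, genome, region,
                                reference_signal=signals[ref_label] if ref_label else None,
                                reference_label=ref_label)
            rows.append({"sample": label, **rs.__dict__})
    frame = pd.DataFrame(rows)
    tested = frame["p_value"].notna()
    frame["q_value"] = np.nan
    if tested.any():
        frame.loc[tested, "q_value"] = multipletests(frame.loc[tested, "p_value"], method="fdr_bh")[1]
    return frame


# ---------------------------------------------------------------------------
# boundary profiles and spreading
# ---------------------------------------------------------------------------

@dataclass
class BoundaryProfile:
    """Signal within +/- flank of a heterochromatin/euchromatin boundary."""

    arm: str
    boundary: int
    het_side: str                 # which side of the boundary is heterochromatin
    flank: int
    positions: np.ndarray = field(repr=False)   # window midpoints
    values: np.ndarray = field(repr=False)
    inside: np.ndarray = field(repr=False)      # True = heterochromatin side
    inside_mean: float = float("nan")
    inside_median: float = float("nan")
    outside_mean: float = float("nan")
    outside_median: float = float("nan")
    statistic: float = float("nan")
    p_value: float = float("nan")
    window_width: int = 0


def boundary_profile(signal: WindowTrack, genome: GenomeModel, arm: str,
                     flank: int = 1_000_000) -> BoundaryProfile:
    """Partition windows within ``flank`` of an arm's boundary by side and test
    heterochromatin-side versus euchromatin-side signal."""
    if arm not in genome.boundaries:
        raise ValueError(f"arm {arm!r} has no annotated boundary")
    info = genome.boundaries[arm]
    b, het_side = info["position"], info["het_side"]
    win = genome.windows
    on_arm = (win["chrom"] == arm).to_numpy()
    arm_len = int(win.loc[on_arm, "end"].max())
    if b - flank < 0 or b + flank > arm_len:
        warnings.warn(f"flank {flank} exceeds arm {arm} extent; truncated", stacklevel=2)
    mid = ((win["start"] + win["end"]) / 2).to_numpy()
    sel = on_arm & (mid >= b - flank) & (mid < b + flank)
    vals = signal.values[sel]
    pos = mid[sel]
    finite = np.isfinite(vals)
    vals, pos = vals[finite], pos[finite]
    inside = pos < b if het_side == "left" else pos >= b
    prof = BoundaryProfile(arm=arm, boundary=b, het_side=het_side, flank=flank,
                           positions=pos, values=vals, inside=inside,
                           window_width=genome.window_width)
    if inside.any() and (~inside).any():
        prof.inside_mean = float(vals[inside].mean())
        prof.inside_median = float(np.median(vals[inside]))
        prof.outside_mean = float(vals[~inside].mean())
        prof.outside_median = float(np.median(vals[~inside]))
        prof.statistic, prof.p_value = rank_sum_test(vals[inside], vals[~inside])
    return prof


def boundary_profile_frame(prof: BoundaryProfile) -> pd.DataFrame:
    """Long-format table of a boundary profile, suitable for plotting."""
    return pd.DataFrame({
        "arm": prof.arm, "position": prof.positions.astype(int),
        "distance_to_boundary": (prof.positions - prof.boundary).astype(int),
        "side": np.where(prof.inside, "heterochromatin", "euchromatin"),
        "value": prof.values,
    })


def spreading_index(profile: BoundaryProfile) -> tuple[float, float | None]:
    """Boundary contrast and estimated boundary shift from a profile.

    contrast = (mean_in - mean_out) / (mean_in + mean_out); the shift is the
    breakpoint of the best-fitting step function (least squares over all
    inter-window breakpoints) minus the annotated boundary, signed so that
    positive means heterochromatin extending into euchromatin (spreading) and
    negative means a retreating boundary.  For a flat profile (no detectable
    step) the shift is None.
    """
    if profile.inside.sum() < 10 or (~profile.inside).sum() < 10:
        raise ValueError("spreading_index needs >= 10 windows on each side")
    mi, mo = profile.inside_mean, profile.outside_mean
    denom = mi + mo
    contrast = (mi - mo) / denom if denom != 0 else float("nan")

    order = np.argsort(profile.positions)
    pos = profile.positions[order]
    vals = profile.values[order]
    n = len(vals)
    csum = np.cumsum(vals)
    csq = np.cumsum(vals ** 2)
    total, total_sq = csum[-1], csq[-1]
    ks = np.arange(1, n)  # breakpoint after the k-th window
    left_sum = csum[:-1]
    sse = (csq[ks - 1] - left_sum ** 2 / ks) + (
        (total_sq - csq[ks - 1]) - (total - left_sum) ** 2 / (n - ks))
    flat_sse = total_sq - total ** 2 / n
    if not np.isfinite(sse).any() or flat_sse <= 0 or (flat_sse - sse.min()) / flat_sse < 1e-6:
        return contrast, None
    k_best = int(ks[np.argmin(sse)])
    breakpoint = (pos[k_best - 1] + pos[k_best]) / 2
    if profile.het_side == "left":
        shift = breakpoint - profile.boundary
    else:
        shift = profile.boundary - breakpoint
    return contrast, float(shift)


# ---------------------------------------------------------------------------
# per-gene signal
# ---------------------------------------------------------------------------

def gene_signal(signal: WindowTrack, genes: pd.DataFrame,
                mask: np.ndarray | None = None) -> pd.DataFrame:
    """Length-weighted mean window signal per gene interval.

    ``genes`` needs columns ``chrom, start, end`` and, if present, ``name``.
    Genes overlapping masked windows are flagged; genes outside the assembly
    are flagged, not fatal.
    """
    win = signal.frame
    out = []
    by_chrom = {c: sub for c, sub in win.groupby("chrom", sort=False)}
    for i, g in genes.reset_index(drop=True).iterrows():
        name = g.get("name", f"gene{i}")
        sub = by_chrom.get(g["chrom"])
        if sub is None:
            out.append((name, np.nan, False, True))
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        overlap = np.minimum(ends, g["end"]) - np.maximum(starts, g["start"])
        hit = overlap > 0
        if not hit.any():
            out.append((name, np.nan, False, True))
            continue
        w = overlap[hit].astype(float)
        v = sub["value"].to_numpy()[hit]
        masked_hit = False
        if mask is not None:
            masked_hit = bool(np.asarray(mask, bool)[sub.index.to_numpy()[hit]].any())
        finite = np.isfinite(v)
        mean = float(np.sum(w[finite] * v[finite]) / w[finite].sum()) if finite.any() else np.nan
        out.append((name, mean, masked_hit, False))
    return pd.DataFrame(out, columns=["name", "mean_signal", "overlaps_mask", "outside_assembly"])


# ---------------------------------------------------------------------------
# concordance QC
# ---------------------------------------------------------------------------

def qc_concordance(signal_a: WindowTrack, signal_b: WindowTrack,
                   top_q: float = 0.40) -> tuple[float, float]:
    """Pearson correlation and top-quantile window overlap between two tracks.

    Overlap is |top_A intersect top_B| / (q * n) over windows finite in both
    tracks; 1.0 means the top q fractions coincide exactly.
    """
    if not (0 < top_q < 1):
        raise ValueError("top_q must be in (0, 1)")
    if not signal_a.same_windows(signal_b):
        raise ValueError("concordance requires identical windows")
    a, b = signal_a.values, signal_b.values
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 shared finite windows")
    a, b = a[ok], b[ok]
    r = float(np.corrcoef(a, b)[0, 1])
    m = int(round(top_q * len(a)))
    m = max(m, 1)
    top_a = set(np.argsort(-a, kind="stable")[:m])
    top_b = set(np.argsort(-b, kind="stable")[:m])
    return r, len(top_a & top_b) / m
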