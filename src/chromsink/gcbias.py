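"""GC-bias correction of windowed coverage.

Illumina coverage depends on fragment GC content, which is a problem for
repeat analysis because repeats often sit at extreme GC.  The correction is
the binned-expectation method: average the coverage of mappable windows
within GC bins of fixed width (5% by default) to get the expected coverage at
each GC, then divide every observed value by the expectation for its bin.
The same model corrects repeat-consensus coverage, keyed on the repeat's GC.

Bins are half-open [lo, hi) with the last bin closed so GC = 1.0 lands in the
top bin.  Bins with fewer windows than ``min_windows`` are marked unreliable;
values falling in empty bins become missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import WindowTrack


@dataclass
class GcModel:
    """Expected coverage per GC bin."""

    bin_edges: np.ndarray       # length n_bins + 1, partition of [0, 1]
    expected: np.ndarray        # per-bin mean coverage; NaN where no windows
    n_windows: np.ndarray       # windows contributing to each bin
    unreliable: np.ndarray      # True where 0 < n_windows < min_windows
    min_windows: int

    @property
    def n_bins(self) -> int:
        return len(self.expected)

    def bin_index(self, gc) -> np.ndarray:
        gc = np.asarray(gc, dtype=float)
        if np.any(gc < 0) or np.any(gc > 1):
            raise ValueError("GC fraction outside [0, 1]")
        width = self.bin_edges[1] - self.bin_edges[0]
        return np.minimum((gc / width).astype(int), self.n_bins - 1)

    def expected_for(self, gc) -> np.ndarray:
        return self.expected[self.bin_index(gc)]


def fit_gc_model(coverage, gc, mask: np.ndarray | None = None,
                 bin_width: float = 0.05, min_windows: int = 10) -> GcModel:
    """Mean coverage of unmasked windows per GC bin.

    ``mask`` flags windows to exclude (non-mappable / cross-mapping), True =
    excluded.  Bins actually used but holding fewer than ``min_windows``
    windows trigger a warning and are marked unreliable.
    """
    coverage = np.asarray(coverage, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if coverage.shape != gc.shape:
        raise ValueError("coverage and gc tracks must share the same windows")
    keep = np.isfinite(coverage)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    width = 1.0 / n_bins
    idx = np.minimum((gc[keep] / width).astype(int), n_bins - 1)
    n = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=coverage[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        expected = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
    unreliable = (n > 0) & (n < min_windows)
    if unreliable.any():
        bins = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in np.flatnonzero(unreliable)]
        warnings.warn(f"GC bins with < {min_windows} windows marked unreliable: {bins}",
                      stacklevel=2)
    return GcModel(edges, expected, n, unreliable, min_windows)


def gc_correct(values, gc, model: GcModel, mask: np.ndarray | None = None,
               preserve_mean: bool = False) -> np.ndarray:
    """Divide observed values by the expected coverage of their GC bin.

    Masked windows and windows in empty bins come back NaN.  With
    ``preserve_mean`` the corrected track is rescaled so its mean over finite
    windows equals the raw mean (keeps downstream ratios comparable).
    """
    values = np.asarray(values, dtype=float)
    expected = model.expected_for(gc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corrected = values / expected
    if mask is not None:
        corrected = np.where(np.asarray(mask, dtype=bool), np.nan, corrected)
    if preserve_mean:
        finite = np.isfinite(corrected) & np.isfinite(values)
        if finite.any() and np.nanmean(corrected[finite]) != 0:
            corrected = corrected * (values[finite].mean() / corrected[finite].mean())
    return corrected


def gc_correct_track(track: WindowTrack, gc, model: GcModel,
                     mask: np.ndarray | None = None, preserve_mean: bool = False) -> WindowTrack:
    corrected = gc_correct(track.values, gc, model, mask=mask, preserve_mean=preserve_mean)
    n_missing = int(np.isnan(corrected).sum() - np.isnan(track.values).sum())
    return track.with_values(corrected, meta={**track.meta, "gc_corrected": "yes",
                                              "gc_missing_windows": str(max(n_missing, 0))})


def gc_correct_repeat(repeat_coverage: float, repeat_gc: float, model: GcModel) -> tuple[float, bool]:
    """Correct one repeat consensus' coverage; returns (value, unreliable_flag).

    The flag is True when the repeat's GC falls in an unreliable (sparse)
    bin; an empty bin yields NaN.
    """
    idx = int(model.bin_index(repeat_gc))
    expected = model.expected[idx]
    flag = bool(model.unreliable[idx]) or not np.isfinite(expected)
    value = float(repeat_coverage / expected) if np.isfinite(expected) and expected > 0 else float("nan")
    return value, flag


def gc_model_to_frame(model: GcModel):
    """Serialize a GcModel as a (bin_lo, bin_hi, expected, n) table."""
    import pandas as pd

    return pd.DataFrame({
        "bin_lo": model.bin_edges[:-1],
        "bin_hi": model.bin_edges[1:],
        "expected": model.expected,
        "n": model.n_windows,
        "unreliable": model.unreliable,
    })
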