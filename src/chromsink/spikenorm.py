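"""Spike-in normalization of ChIP-seq signal.

A fixed amount of foreign-species chromatin is added to every sample before
immunoprecipitation.  Because the spike contributes the same amount of marked
chromatin to every library, the fraction of reads recovered from the spike
calibrates each sample's global mark abundance: if a sample's true mark level
drops genome-wide, its target reads shrink relative to the constant spike and
the normalization restores the difference that plain depth normalization
erases.

Two estimators of the scaling are provided:

``spike_scaling_ratio``
    From the four library totals.  With target/spike read counts (M, S) and
    spike fractions phi = S / (M + S), the factor is phi_input / phi_chip.
    The per-window signal then reduces algebraically to
    (c_w / i_w) * (S_input / S_chip).

``spike_scaling_regression``
    Through-the-origin least-squares slope of depth-normalized spike ChIP
    coverage on depth-normalized spike input coverage, genome-wide over spike
    windows; the factor is the reciprocal slope.  On noiseless proportional
    data the two estimators coincide exactly.

``relative_recovery``
    (Mc/Sc) / (Mi/Si) -- the recovery of target ChIP signal versus spike ChIP
    signal, each normalized by its input counts.  Unlike the phi-based factor
    this statistic is directly proportional to the sample's genome-wide mark
    abundance, so ratios of it across samples estimate global dilution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import WindowTrack


@dataclass
class LibraryComposition:
    """One sequencing library: target/spike totals plus per-window target coverage.

    ``target_reads`` (M) and ``spike_reads`` (S) are library totals including
    reads in masked windows; ``coverage`` holds per-window target counts
    aligned to the analysis windows.
    """

    target_reads: float
    spike_reads: float
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.target_reads < 0 or self.spike_reads < 0:
            raise ValueError("read totals must be >= 0")

    @property
    def total(self) -> float:
        return self.target_reads + self.spike_reads

    @property
    def spike_fraction(self) -> float:
        return self.spike_reads / self.total


@dataclass
class SignalTrack:
    """Normalized per-window ChIP signal with its method provenance."""

    values: np.ndarray
    method: str  # spike_ratio | spike_regression | unspiked
    factor: float
    pseudocount: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_windowtrack(self, windows: WindowTrack) -> WindowTrack:
        return windows.with_values(
            self.values,
            meta={**self.meta, "method": self.method,
                  "factor": repr(self.factor), "pseudocount": repr(self.pseudocount)},
        )


def spike_scaling_ratio(chip: LibraryComposition, input_: LibraryComposition) -> float:
    """Scaling factor phi_input / phi_chip from the library composition totals."""
    for name, lib in (("chip", chip), ("input", input_)):
        if lib.spike_reads <= 0:
            raise ValueError(f"{name} library has no spike reads (spike failed)")
        if lib.target_reads <= 0:
            raise ValueError(f"{name} library has no target reads")
    return input_.spike_fraction / chip.spike_fraction


def relative_recovery(chip: LibraryComposition, input_: LibraryComposition) -> float:
    """(Mc/Sc) / (Mi/Si): input-normalized recovery of target vs spike ChIP reads.

    Proportional to the sample's abundance-weighted mean mark density, so the
    ratio of this statistic between two samples estimates their global mark
    dilution directly.
    """
    if chip.spike_reads <= 0 or input_.spike_reads <= 0:
        raise ValueError("spike reads must be positive in both libraries")
    if input_.target_reads <= 0:
        raise ValueError("input library has no target reads")
    return (chip.target_reads / chip.spike_reads) / (input_.target_reads / input_.spike_reads)


def window_signal(chip: LibraryComposition, input_: LibraryComposition, factor: float,
                  pseudocount: float = 0.0, mask: np.ndarray | None = None,
                  method: str = "spike_ratio") -> SignalTrack:
    """Per-window normalized signal.

    signal_w = [(c_w / (Mc+Sc)) / (i_w / (Mi+Si))] * factor

    Windows with zero input are missing (NaN) unless a pseudocount is given,
    in which case the pseudocount is added to both ChIP and input coverage.
    ``mask`` marks windows (True = masked) forced to NaN, e.g. cross-mapping
    regions excluded from the analysis.
    """
    c = chip.coverage
    i = input_.coverage
    if c.shape != i.shape:
        raise ValueError(f"window mismatch: chip has {c.shape[0]} windows, input {i.shape[0]}")
    c = c + pseudocount
    i = i + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        signal = (c / chip.total) / (i / input_.total) * factor
    signal = np.where(i > 0, signal, np.nan)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != signal.shape:
            raise ValueError("mask length does not match window count")
        signal = np.where(mask, np.nan, signal)
    return SignalTrack(signal, method=method, factor=factor, pseudocount=pseudocount)


def spike_scaling_regression(spike_chip_cov: np.ndarray, spike_input_cov: np.ndarray,
                             chip_total: float, input_total: float,
                             min_windows: int = 20) -> float:
    """Scaling factor from a through-the-origin regression over spike windows.

    Depth-normalizes both spike coverage vectors by their library totals and
    fits y = a*x by least squares (a = sum(xy)/sum(x^2)); the factor is 1/a.
    """
    x = np.asarray(spike_input_cov, dtype=float) / input_total
    y = np.asarray(spike_chip_cov, dtype=float) / chip_total
    if x.shape != y.shape:
        raise ValueError("spike coverage vectors differ in length")
    ok = x > 0
    if ok.sum() < min_windows:
        raise ValueError(f"need >= {min_windows} spike windows with nonzero input, have {int(ok.sum())}")
    sxx = float(np.sum(x[ok] * x[ok]))
    sxy = float(np.sum(x[ok] * y[ok]))
    if sxx == 0 or sxy == 0:
        raise ValueError("degenerate spike coverage (all zero)")
    slope = sxy / sxx
    return 1.0 / slope


def unspiked_signal(chip: LibraryComposition, input_: LibraryComposition,
                    pseudocount: float = 0.0, mask: np.ndarray | None = None) -> SignalTrack:
    """Depth-normalized ChIP/input ratio with no spike term.

    This is what a spike-free experiment can compute; it preserves the shape
    of the enrichment profile but is blind to global changes in mark
    abundance (a uniform genome-wide dilution cancels out).  Library totals
    are the target reads alone, as in a library with no spike present.
    """
    c = chip.coverage + pseudocount
    i = input_.coverage + pseudocount
    if c.shape != i.shape:
        raise ValueError(f"window mismatch: chip has {c.shape[0]} windows, input {i.shape[0]}")
    with np.errstate(divide="ignore", invalid="ignore"):
        signal = (c / chip.target_reads) / (i / input_.target_reads)
    signal = np.where(i > 0, signal, np.nan)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != signal.shape:
            raise ValueError("mask length does not match window count")
        signal = np.where(mask, np.nan, signal)
    return SignalTrack(signal, method="unspiked", factor=1.0, pseudocount=pseudocount)
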