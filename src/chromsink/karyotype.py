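"""Karyotype definitions and genome-size / heterochromatin-content arithmetic.

Flow cytometry gives each karyotype's diploid genome size relative to an
internal standard of known size (a *D. virilis* head, 1C = 328 Mb).  Under the
assumption that the euchromatic portion of the genome is constant across
karyotypes -- 232 Mb per diploid cell for flies carrying two X chromosomes and
210 Mb for flies with a single X -- the heterochromatin content is simply the
diploid size minus that constant.  Across the five sex-chromosome karyotypes
this yields the repeat-content gradient X0 < XX < XY < XXY < XYY that the rest
of the pipeline conditions on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Known 1C genome size of the D. virilis flow-cytometry standard, in Mb.
VIRILIS_STANDARD_MB = 328.0

#: Diploid euchromatin constants (Mb), keyed by number of X chromosomes.
EUCHROMATIN_MB_TWO_X = 232.0
EUCHROMATIN_MB_ONE_X = 210.0


@dataclass(frozen=True)
class KaryotypeSpec:
    """Sex-chromosome complement identifying a sample.

    Parameters
    ----------
    label : str
        Conventional name (``"X0"``, ``"XX"``, ``"XY"``, ``"XXY"``, ``"XYY"``
        or a custom string).
    n_X, n_Y : int
        Copy numbers of the X and Y chromosome.  At least one X is required;
        the Y count may be zero.
    autosome_ploidy : int
        Copies of each autosome (2 for the diploid flies modeled here).
    """

    label: str
    n_X: int
    n_Y: int
    autosome_ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_X < 1:
            raise ValueError(f"karyotype {self.label!r}: n_X must be >= 1, got {self.n_X}")
        if self.n_Y < 0:
            raise ValueError(f"karyotype {self.label!r}: n_Y must be >= 0, got {self.n_Y}")
        if self.autosome_ploidy < 1:
            raise ValueError("autosome_ploidy must be >= 1")


X0 = KaryotypeSpec("X0", n_X=1, n_Y=0)
XX = KaryotypeSpec("XX", n_X=2, n_Y=0)
XY = KaryotypeSpec("XY", n_X=1, n_Y=1)
XXY = KaryotypeSpec("XXY", n_X=2, n_Y=1)
XYY = KaryotypeSpec("XYY", n_X=1, n_Y=2)

#: The five karyotypes of the study, in increasing repeat-content order.
STANDARD_KARYOTYPES = (X0, XX, XY, XXY, XYY)


def euchromatin_constant_mb(karyotype: KaryotypeSpec) -> float:
    """Diploid euchromatin size (Mb) assumed constant for a given X count.

    Only the one-X and two-X cases are defined; other X ploidies raise rather
    than extrapolate, since the fixed-euchromatin assumption was stated for
    those two configurations only.
    """
    if karyotype.n_X == 1:
        return EUCHROMATIN_MB_ONE_X
    if karyotype.n_X == 2:
        return EUCHROMATIN_MB_TWO_X
    raise ValueError(
        f"no euchromatin constant defined for n_X={karyotype.n_X} "
        "(only 1 or 2 X chromosomes supported)"
    )


def genome_size_from_fluorescence(f_sample, f_standard, standard_size_mb: float = VIRILIS_STANDARD_MB):
    """Diploid genome size (Mb) from propidium-iodide fluorescence ratios.

    ``standard_size_mb * f_sample / f_standard`` -- the sample's fluorescence
    peak relative to the co-prepared standard, scaled by the standard's known
    genome size.  Accepts scalars or arrays (replicate measurements).
    """
    f_sample = np.asarray(f_sample, dtype=float)
    f_standard = np.asarray(f_standard, dtype=float)
    if np.any(f_sample <= 0) or np.any(f_standard <= 0):
        raise ValueError("fluorescence values must be positive")
    if standard_size_mb <= 0:
        raise ValueError("standard genome size must be positive")
    out = standard_size_mb * f_sample / f_standard
    return float(out) if out.ndim == 0 else out


def heterochromatin_content(diploid_size_mb: float, karyotype: KaryotypeSpec) -> float:
    """Heterochromatin content (Mb) under the fixed-euchromatin assumption."""
    const = euchromatin_constant_mb(karyotype)
    het = diploid_size_mb - const
    if het < 0:
        raise ValueError(
            f"diploid size {diploid_size_mb} Mb is below the euchromatin constant "
            f"{const} Mb for karyotype {karyotype.label!r} (negative heterochromatin)"
        )
    return het


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Genome-size estimate for one karyotype, with the constant used."""

    karyotype: KaryotypeSpec
    diploid_size_mb: float
    het_content_mb: float
    euchromatin_constant_mb: float


def estimate_genome_size(f_sample, f_standard, karyotype: KaryotypeSpec,
                         standard_size_mb: float = VIRILIS_STANDARD_MB) -> GenomeSizeEstimate:
    """Combine both steps: fluorescence ratio -> size -> heterochromatin content.

    Replicate fluorescence measurements are averaged before subtraction.
    """
    sizes = np.atleast_1d(genome_size_from_fluorescence(f_sample, f_standard, standard_size_mb))
    size = float(np.mean(sizes))
    return GenomeSizeEstimate(
        karyotype=karyotype,
        diploid_size_mb=size,
        het_content_mb=heterochromatin_content(size, karyotype),
        euchromatin_constant_mb=euchromatin_constant_mb(karyotype),
    )
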