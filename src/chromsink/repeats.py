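"""Repeat-family analysis: Y-linkage classification, ChIP enrichment,
copy-number estimation, and copy-number-corrected expression.

Male-specific (Y-linked) repeats are called from sex-resolved genomic
coverage: high normalized coverage in males together with either zero female
coverage or a female/male share both below a ratio cutoff and significantly
below equality by a binomial test on read counts (Bonferroni-corrected across
families).  Copy number is estimated against the mean input coverage of
annotated single-copy euchromatin, and expression is reported per copy so
that transcriptional derepression can be separated from plain genomic dosage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gcbias import GcModel, gc_correct_repeat


@dataclass
class ClassifierSettings:
    """Thresholds for the male-specific repeat call (all reported in output).

    ``min_male_cov`` is expressed as a multiple of single-copy coverage
    (default 5 -- a sequence must effectively be repetitive in males);
    ``max_female_ratio`` caps the depth-normalized female/male coverage
    ratio; ``alpha`` is the per-family binomial level before Bonferroni
    correction.
    """

    min_male_cov: float = 5.0
    max_female_ratio: float = 0.1
    alpha: float = 0.01
    bonferroni: bool = True


def classify_male_specific(coverage: pd.DataFrame,
                           male_depth: float | None = None,
                           female_depth: float | None = None,
                           settings: ClassifierSettings | None = None) -> pd.DataFrame:
    """Label repeat families as male_specific / shared / female_only.

    ``coverage`` needs columns ``name, male_cov, female_cov`` and, for the
    binomial test, ``male_reads, female_reads``.  ``male_depth`` /
    ``female_depth`` are per-single-copy sequencing depths used to normalize
    (taken from ``coverage.attrs`` when omitted).  A family is male-specific
    iff normalized male coverage >= min_male_cov and the female signal is
    either exactly zero or both below the ratio cutoff and significantly
    below the equal-abundance expectation.
    """
    settings = settings or ClassifierSettings()
    for col in ("male_cov", "female_cov"):
        if col not in coverage.columns:
            raise ValueError(f"missing sex coverage column {col!r}")
    male_depth = male_depth if male_depth is not None else coverage.attrs.get("male_depth")
    female_depth = female_depth if female_depth is not None else coverage.attrs.get("female_depth")
    if male_depth is None or female_depth is None:
        raise ValueError("per-sex sequencing depths are required for normalization")

    m_norm = coverage["male_cov"].to_numpy(float) / male_depth
    f_norm = coverage["female_cov"].to_numpy(float) / female_depth
    n_fam = len(coverage)
    alpha = settings.alpha / n_fam if settings.bonferroni else settings.alpha
    # expected female read share if per-copy abundance were equal in both sexes
    p_equal = female_depth / (male_depth + female_depth)

    labels, pvals = [], []
    have_reads = {"male_reads", "female_reads"} <= set(coverage.columns)
    for i in range(n_fam):
        male_ok = m_norm[i] >= settings.min_male_cov
        if f_norm[i] == 0:
            p = 0.0 if m_norm[i] > 0 else 1.0
            label = "male_specific" if male_ok else "shared"
        else:
            ratio = f_norm[i] / m_norm[i] if m_norm[i] > 0 else np.inf
            if have_reads:
                n_tot = int(coverage["male_reads"].iloc[i] + coverage["female_reads"].iloc[i])
                p = stats.binomtest(int(coverage["female_reads"].iloc[i]), n_tot,
                                    p_equal, alternative="less").pvalue if n_tot > 0 else 1.0
            else:
                p = np.nan
            significant = (p < alpha) if np.isfinite(p) else False
            if male_ok and ratio <= settings.max_female_ratio and significant:
                label = "male_specific"
            elif m_norm[i] == 0 and f_norm[i] > 0:
                label = "female_only"
            else:
                label = "shared"
        if not male_ok and label == "male_specific":
            label = "shared"
        if m_norm[i] == 0 and f_norm[i] > 0:
            label = "female_only"
        labels.append(label)
        pvals.append(p)

    out = coverage.copy()
    out["male_cov_norm"] = m_norm
    out["female_cov_norm"] = f_norm
    out["binom_p"] = pvals
    out["label"] = labels
    out.attrs.update({"min_male_cov": settings.min_male_cov,
                      "max_female_ratio": settings.max_female_ratio,
                      "alpha": settings.alpha, "bonferroni": settings.bonferroni})
    return out


def repeat_enrichment(chip_cov: float, input_cov: float, repeat_gc: float,
                      gc_model_chip: GcModel, gc_model_input: GcModel,
                      spike_factor: float, genomewide_signal: float) -> tuple[float, bool]:
    """GC-corrected, spike-scaled ChIP/input for one repeat, relative to the
    sample's genome-wide signal.

    Returns (relative enrichment, flag); the flag marks zero input or an
    unreliable GC bin.  A value of 1.0 means the repeat carries the mark at
    the genome-wide average level for that sample.
    """
    if input_cov == 0:
        return float("nan"), True
    chip_corr, flag_c = gc_correct_repeat(chip_cov, repeat_gc, gc_model_chip)
    input_corr, flag_i = gc_correct_repeat(input_cov, repeat_gc, gc_model_input)
    if not np.isfinite(chip_corr) or not np.isfinite(input_corr) or input_corr == 0:
        return float("nan"), True
    value = (chip_corr / input_corr) * spike_factor / genomewide_signal
    return float(value), bool(flag_c or flag_i)


def copy_number_estimate(family_input_cov, single_copy_baseline_cov: float):
    """Genomic copies from input coverage relative to single-copy euchromatin."""
    if single_copy_baseline_cov <= 0:
        raise ValueError("single-copy baseline coverage must be positive")
    return np.asarray(family_input_cov, dtype=float) / single_copy_baseline_cov


def cn_corrected_expression(expression_cpm, copies):
    """Per-copy expression: CPM (already length-normalized) divided by copies.

    Families with zero copies but nonzero expression come back NaN with a
    flag (transcript from an unassembled or misestimated source).
    """
    expression_cpm = np.asarray(expression_cpm, dtype=float)
    copies = np.asarray(copies, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_copy = np.where(copies > 0, expression_cpm / copies, np.nan)
    flagged = (copies == 0) & (expression_cpm > 0)
    if per_copy.ndim == 0:
        return float(per_copy), bool(flagged)
    return per_copy, flagged


def expression_cpm_per_kb(counts: pd.DataFrame, lengths: pd.Series,
                          library_size: pd.Series | None = None) -> pd.DataFrame:
    """Counts-per-million over the full (repeat + gene) universe, per kb.

    ``counts`` is features x samples.  ``library_size`` gives the per-sample
    total over the whole universe (genes plus repeats); when omitted the
    column sums of ``counts`` are used, which is only appropriate if
    ``counts`` already spans the universe.  The per-kb division makes
    families of different lengths comparable.
    """
    lib = counts.sum(axis=0) if library_size is None else library_size.reindex(counts.columns)
    cpm = counts / lib * 1e6
    return cpm.div(lengths.reindex(cpm.index).to_numpy() / 1000.0, axis=0)
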