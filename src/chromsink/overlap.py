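"""Gene ranking by expression contrast and top-k overlap statistics.

Genes are ranked within each contrast by absolute log2 fold change of mean
CPM (pseudocount-stabilized); the statistic of interest is the size of the
intersection of the top-k genes across m contrasts.  Under a null in which
each contrast's top-k set is an independent uniform k-subset of the N-gene
universe, the expected intersection is N * (k/N)^m, and a Monte-Carlo
permutation p-value is computed with the add-one estimator.  A stricter null
that permutes sample labels within the count table (preserving inter-contrast
correlation) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import rank_sum_test


@dataclass
class RankedContrast:
    """Per-gene log2 fold changes for one contrast, ranked by |lfc|."""

    label: str
    table: pd.DataFrame = field(repr=False)  # index gene; columns lfc, rank
    n_genes: int = 0

    def top_k(self, k: int) -> set:
        if k > self.n_genes:
            raise ValueError(f"k={k} exceeds universe size {self.n_genes}")
        return set(self.table.index[self.table["rank"] <= k])


def rank_genes_by_contrast(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
                           pseudocount: float = 0.5, label: str | None = None,
                           exclude: list[str] | None = None) -> RankedContrast:
    """Rank genes by |log2 fold change| of mean CPM between two sample groups.

    lfc = log2((mean CPM_A + pc) / (mean CPM_B + pc)); rank 1 is the largest
    |lfc|, ties broken deterministically by gene id.  ``exclude`` removes
    genes (e.g. an rDNA scaffold) before ranking.  All-zero genes are
    retained with lfc 0 and flagged.
    """
    for grp, name in ((group_a, "A"), (group_b, "B")):
        if not grp:
            raise ValueError(f"group {name} needs >= 1 replicate")
        missing = [c for c in grp if c not in counts.columns]
        if missing:
            raise ValueError(f"unknown sample columns: {missing}")
    if exclude:
        counts = counts.drop(index=[g for g in exclude if g in counts.index])
    cpm = counts / counts.sum(axis=0) * 1e6
    mean_a = cpm[group_a].mean(axis=1)
    mean_b = cpm[group_b].mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    all_zero = counts.sum(axis=1) == 0
    lfc[all_zero] = 0.0
    table = pd.DataFrame({"lfc": lfc, "all_zero": all_zero})
    gene_ids = table.index.to_numpy().astype(str)
    order_idx = np.lexsort((gene_ids, -lfc.abs().to_numpy()))
    ranks = np.empty(len(table), dtype=np.int64)
    ranks[order_idx] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return RankedContrast(label or "A_vs_B", table, n_genes=len(table))


def topk_overlap(contrasts: list[RankedContrast], k: int) -> int:
    """Size of the intersection of the top-k gene sets across contrasts."""
    universes = {frozenset(c.table.index) for c in contrasts}
    if len(universes) != 1:
        raise ValueError("contrasts are ranked over different gene universes")
    sets = [c.top_k(k) for c in contrasts]
    return len(set.intersection(*sets))


@dataclass
class OverlapTestResult:
    m: int
    k: int
    n_universe: int
    observed: int
    expected_closed_form: float
    permutation_mean: float
    permutation_sd: float
    p_value: float
    n_perm: int
    seed: int


def expected_overlap(m: int, k: int, n_universe: int) -> float:
    """Closed-form expected intersection of m independent uniform k-subsets."""
    return n_universe * (k / n_universe) ** m


def _permutation_overlaps(m: int, k: int, n: int, n_perm: int,
                          rng: np.random.Generator, chunk: int = 200) -> np.ndarray:
    """Intersection sizes of m independent uniform k-subsets, vectorized."""
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        u = rng.random((b * m, n))
        top = np.argpartition(u, k - 1, axis=1)[:, :k]  # k smallest: uniform k-subset
        offsets = (np.arange(b).repeat(m) * n)[:, None]
        flat = (top + offsets).ravel()
        counts = np.bincount(flat, minlength=b * n).reshape(b, n)
        out[done : done + b] = (counts == m).sum(axis=1)
        done += b
    return out


def overlap_permutation_test(m: int, k: int, n_universe: int, observed: int,
                             n_perm: int = 10_000, seed: int = 0) -> OverlapTestResult:
    """Permutation test of an observed m-way top-k overlap.

    Null: each contrast's top-k set is an independent uniform k-subset of the
    universe (gene labels exchangeable).  p = (1 + #{perm >= observed}) /
    (n_perm + 1), so p is never zero and is bounded below by 1/(n_perm + 1).
    """
    if not (0 < k <= n_universe):
        raise ValueError("need 0 < k <= N")
    if not (0 <= observed <= k):
        raise ValueError(f"observed overlap {observed} outside [0, k={k}]")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    rng = np.random.default_rng(seed)
    if k == n_universe:
        overlaps = np.full(n_perm, n_universe, dtype=np.int64)
    else:
        overlaps = _permutation_overlaps(m, k, n_universe, n_perm, rng)
    p = (1 + int((overlaps >= observed).sum())) / (n_perm + 1)
    return OverlapTestResult(
        m=m, k=k, n_universe=n_universe, observed=observed,
        expected_closed_form=expected_overlap(m, k, n_universe),
        permutation_mean=float(overlaps.mean()),
        permutation_sd=float(overlaps.std(ddof=1)),
        p_value=p, n_perm=n_perm, seed=seed,
    )


def label_permutation_overlap(counts: pd.DataFrame, contrast_groups: list[tuple[list[str], list[str]]],
                              k: int, observed: int, n_perm: int = 1000, seed: int = 0,
                              pseudocount: float = 0.5) -> OverlapTestResult:
    """Stricter null preserving inter-contrast correlation: permute sample
    labels within the count table, re-rank every contrast, and recompute the
    overlap.  Considerably more expensive than the uniform-subset null."""
    rng = np.random.default_rng(seed)
    cols = list(counts.columns)
    overlaps = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        perm = dict(zip(cols, rng.permutation(cols)))
        ranked = [rank_genes_by_contrast(counts, [perm[c] for c in a], [perm[c] for c in b],
                                         pseudocount=pseudocount)
                  for a, b in contrast_groups]
        overlaps[i] = topk_overlap(ranked, k)
    m = len(contrast_groups)
    p = (1 + int((overlaps >= observed).sum())) / (n_perm + 1)
    return OverlapTestResult(m=m, k=k, n_universe=len(counts), observed=observed,
                             expected_closed_form=expected_overlap(m, k, len(counts)),
                             permutation_mean=float(overlaps.mean()),
                             permutation_sd=float(overlaps.std(ddof=1)),
                             p_value=p, n_perm=n_perm, seed=seed)


def geneset_contrast(gene_set, contrasts: list[RankedContrast]) -> pd.DataFrame:
    """Compare |lfc| of a gene set against the background, per contrast.

    Returns one row per contrast with set/background median |lfc| and a
    two-sided rank-sum p; genes in the set missing from the universe are
    counted in ``n_missing`` (reported, not fatal).
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    rows = []
    for c in contrasts:
        universe = set(c.table.index)
        present = gene_set & universe
        missing = len(gene_set) - len(present)
        if not present:
            raise ValueError(f"gene set shares no genes with contrast {c.label!r}")
        abs_lfc = c.table["lfc"].abs()
        in_set = abs_lfc.loc[sorted(present)].to_numpy()
        background = abs_lfc.loc[sorted(universe - present)].to_numpy()
        if background.size:
            stat, p = rank_sum_test(in_set, background)
        else:  # set == universe
            stat, p = float("nan"), 1.0
        rows.append({"contrast": c.label, "n_set": len(present), "n_missing": missing,
                     "set_median_abs_lfc": float(np.median(in_set)),
                     "background_median_abs_lfc": float(np.median(background)) if background.size else float(np.median(in_set)),
                     "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)
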