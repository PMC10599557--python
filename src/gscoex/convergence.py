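"""Genetic-risk convergence statistics on preserved modules.

Three lines of evidence that a module concentrates a trait's polygenic signal:

1. correlation between module eigengenes and the genomic-score columns;
2. permutation gene-set enrichment (e.g. GWAS priority genes, microglial
   markers): the observed overlap between a module and a gene set is compared
   with overlaps of random same-size gene draws from the expressed-gene
   universe, with p = (1 + #{null >= observed}) / (n_iter + 1);
3. module-membership (kME) distribution comparison between preserved and
   removed networks, quantified by a two-sample Kolmogorov-Smirnov statistic
   and a median shift (a quantitative companion to visual histogram overlap).

Cross-run module overlap supports replication-style comparisons between two
cohorts/runs, including the multi-set intersection that identifies a shared core
of risk-concentrating genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, ks_2samp, pearsonr

__all__ = [
    "EnrichmentResult",
    "correlate_me_scores",
    "permutation_gene_set_enrichment",
    "microglia_module_check",
    "compare_kme_distributions",
    "cross_run_module_overlap",
    "shared_core",
]


@dataclass
class EnrichmentResult:
    module: str
    gene_set: str
    overlap: int
    module_size: int
    set_size_in_universe: int
    universe_size: int
    p_value: float
    n_iterations: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def correlate_me_scores(
    mes: pd.DataFrame,
    scores: pd.DataFrame,
    pattern: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r and two-sided p for every (module eigengene, score) pair.

    Constant eigengenes yield missing r/p. If correspondence ``pattern`` labels
    are given they are joined in, supporting Table-1-style summaries (counts of
    score-correlated modules among strong vs weak/none).
    """
    if not mes.index.equals(scores.index):
        scores = scores.loc[mes.index]
    rows = []
    for mod in mes.columns:
        me = mes[mod].to_numpy(dtype=float)
        for sc in scores.columns:
            x = scores[sc].to_numpy(dtype=float)
            if me.std() == 0 or x.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(me, x)
            rows.append(
                {
                    "module": mod,
                    "score": sc,
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "p_value": float(p) if np.isfinite(p) else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    if pattern is not None:
        out["pattern"] = out["module"].map(pattern)
    return out


def _null_overlaps(
    n_universe: int,
    module_size: int,
    member_mask: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlap counts for random same-size gene draws (uniform, no replacement).

    Sampling uses independent random keys per iteration: the ``module_size``
    smallest keys index a uniform draw without replacement. Chunked to bound
    memory at ~32 MB.
    """
    out = np.empty(n_iter, dtype=np.int64)
    chunk = max(1, int(4_000_000 // max(n_universe, 1)))
    done = 0
    while done < n_iter:
        c = min(chunk, n_iter - done)
        keys = rng.random((c, n_universe))
        idx = np.argpartition(keys, module_size - 1, axis=1)[:, :module_size]
        out[done : done + c] = member_mask[idx].sum(axis=1)
        done += c
    return out


def permutation_gene_set_enrichment(
    module_genes: list[str],
    gene_set: set[str] | list[str],
    universe: list[str],
    n_iter: int = 100_000,
    seed: int = 0,
    set_name: str = "gene_set",
    module_name: str = "module",
) -> EnrichmentResult:
    """Permutation over-representation test of a gene set in a module."""
    universe = list(universe)
    uni_set = set(universe)
    gene_set = set(gene_set) & uni_set
    if not gene_set:
        raise ValueError("gene set does not intersect the universe")
    module = [g for g in module_genes if g in uni_set]
    if n_iter < 100:
        warnings.warn("n_iter < 100: permutation p-values will be very coarse")
    observed = len(gene_set & set(module))
    mask = np.fromiter((g in gene_set for g in universe), dtype=bool, count=len(universe))
    rng = np.random.default_rng(seed)
    null = _null_overlaps(len(universe), len(module), mask, n_iter, rng)
    p = (1.0 + int((null >= observed).sum())) / (n_iter + 1.0)
    return EnrichmentResult(
        module=module_name,
        gene_set=set_name,
        overlap=observed,
        module_size=len(module),
        set_size_in_universe=len(gene_set),
        universe_size=len(universe),
        p_value=float(p),
        n_iterations=n_iter,
        seed=seed,
    )


def microglia_module_check(
    module_genes: dict[str, list[str]],
    marker_set: set[str] | list[str],
    universe: list[str],
    n_iter: int = 100_000,
    seed: int = 0,
    set_name: str = "microglial_markers",
    min_overlap_report: int = 0,
) -> list[EnrichmentResult]:
    """Enrichment of every module in a marker gene set (e.g. microglial markers).

    Each module gets its own sub-seed so results are reproducible regardless of
    the module iteration order. Modules below ``min_overlap_report`` overlap can
    be filtered by the caller via the returned counts.
    """
    if not set(marker_set) & set(universe):
        raise ValueError("marker set does not intersect the universe")
    results = []
    for i, (mod, genes) in enumerate(sorted(module_genes.items())):
        res = permutation_gene_set_enrichment(
            genes,
            marker_set,
            universe,
            n_iter=n_iter,
            seed=seed + i,
            set_name=set_name,
            module_name=mod,
        )
        if res.overlap >= min_overlap_report:
            results.append(res)
    return results


def exact_hypergeom_p(
    overlap: int, universe_size: int, set_size: int, module_size: int
) -> float:
    """Closed-form upper-tail counterpart of the permutation test."""
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, module_size))


def compare_kme_distributions(
    kme_preserved: pd.DataFrame, kme_removed: pd.DataFrame
) -> pd.DataFrame:
    """Per-module kME distribution shift between preserved and removed networks.

    For each module present in both kME matrices: two-sample KS statistic with
    p-value, plus the median kME difference (preserved minus removed).
    """
    if not kme_preserved.index.equals(kme_removed.index):
        raise ValueError("kME matrices must share the same gene universe")
    shared = [m for m in kme_preserved.columns if m in kme_removed.columns]
    rows = []
    for mod in shared:
        a = kme_preserved[mod].to_numpy(dtype=float)
        b = kme_removed[mod].to_numpy(dtype=float)
        ks = ks_2samp(a, b, method="asymp")
        rows.append(
            {
                "module": mod,
                "ks_statistic": float(ks.statistic),
                "ks_p_value": float(ks.pvalue),
                "median_shift": float(np.median(a) - np.median(b)),
            }
        )
    return pd.DataFrame(rows)


def cross_run_module_overlap(
    modules_a: dict[str, list[str]],
    modules_b: dict[str, list[str]],
    universe: list[str],
) -> pd.DataFrame:
    """Intersection sizes and Fisher enrichment across two runs' module sets."""
    uni = set(universe)
    N = len(uni)
    rows = []
    for ma, ga in modules_a.items():
        sa = set(ga) & uni
        for mb, gb in modules_b.items():
            sb = set(gb) & uni
            o = len(sa & sb)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(sa),
                    "size_b": len(sb),
                    "overlap": o,
                    "p_value": exact_hypergeom_p(o, N, len(sb), len(sa)),
                }
            )
    return pd.DataFrame(rows)


def shared_core(gene_sets: list[list[str]]) -> set[str]:
    """Genes shared by every set (the multi-set intersection)."""
    if not gene_sets:
        return set()
    core = set(gene_sets[0])
    for s in gene_sets[1:]:
        core &= set(s)
    return core
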