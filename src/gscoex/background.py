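"""Consensus background networks and module-correspondence / fragmentation analysis.

The background network for one genomic score is the consensus of the preserved and
removed networks built from that score's adjusted expression: after quantile
scaling, the consensus TOM is the entrywise minimum, so it retains only
co-expression present in *both* networks — co-expression independent of the score.
Each preserved module is then cross-tabulated against the background modules
(background grey included) and every overlap is tested with a one-sided Fisher
exact test. The per-module correspondence pattern is:

* ``strong`` — significant overlap with exactly one background module;
* ``weak``   — significant overlap with two or more background modules (the
  module is *fragmented* across the background);
* ``none``   — no significant non-grey overlap, or the majority (> 50%) of the
  module's genes fall into background grey.

Fragments (the gene sets a weak module scatters into, above a minimum size) can be
extracted for downstream enrichment analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network import GREY, Network, NetworkParams, detect_modules, module_order

__all__ = [
    "BackgroundParams",
    "BackgroundNetwork",
    "CorrespondenceReport",
    "consensus_background",
    "consensus_tom",
    "module_overlap",
    "classify_correspondence",
    "extract_fragments",
    "correspondence_report",
    "fragmentation_summary",
]


@dataclass
class BackgroundParams:
    quantile: float = 0.95
    alpha: float = 0.05
    method: str = "bonferroni"  # or "fdr_bh"
    fragment_min: int = 20
    grey_majority: float = 0.5


@dataclass
class BackgroundNetwork:
    consensus_tom: np.ndarray
    genes: pd.Index
    samples: pd.Index
    labels: pd.Series
    merged_labels: pd.Series
    mes: pd.DataFrame
    dendrogram: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def grey_count(self) -> int:
        return int((self.merged_labels == GREY).sum())


@dataclass
class CorrespondenceReport:
    contingency: pd.DataFrame  # preserved modules x background modules (+ grey)
    fisher_p: pd.DataFrame
    adjusted_p: pd.DataFrame
    significant: pd.DataFrame  # boolean
    pattern: pd.Series  # per preserved module: strong | weak | none
    fragments: dict[str, list[tuple[str, list[str]]]]
    alpha: float
    method: str

    @property
    def n_fragmented(self) -> int:
        return int((self.pattern != "strong").sum())

    @property
    def n_modules(self) -> int:
        return int(len(self.pattern))


def consensus_tom(
    tom_a: np.ndarray, tom_b: np.ndarray, quantile: float = 0.95
) -> np.ndarray:
    """Quantile-scaled entrywise-minimum consensus of two TOMs.

    Each TOM is scaled multiplicatively so that its upper off-diagonal quantile
    equals the smaller of the two quantiles; this makes the consensus symmetric in
    its inputs. Entries are clipped to [0, 1].
    """
    if tom_a.shape != tom_b.shape:
        raise ValueError("TOM shapes differ")
    iu = np.triu_indices_from(tom_a, k=1)
    q_a = float(np.quantile(tom_a[iu], quantile))
    q_b = float(np.quantile(tom_b[iu], quantile))
    target = min(q_a, q_b)
    scaled = []
    for tom, q in ((tom_a, q_a), (tom_b, q_b)):
        if q > 0 and target > 0:
            scaled.append(np.clip(tom * (target / q), 0.0, 1.0))
        else:
            scaled.append(tom)
    cons = np.minimum(scaled[0], scaled[1])
    np.fill_diagonal(cons, 1.0)
    return cons


def consensus_background(
    preserved: Network,
    removed: Network,
    params: BackgroundParams | None = None,
    network_params: NetworkParams | None = None,
    me_expression: pd.DataFrame | None = None,
) -> BackgroundNetwork:
    """Build the background network from a preserved/removed pair.

    Background module eigengenes need an expression matrix, which the consensus
    itself does not define; pass ``me_expression`` — the pipeline uses the
    elementwise mean of the preserved and removed adjusted expression.
    """
    params = params or BackgroundParams()
    network_params = network_params or NetworkParams()
    if not preserved.genes.equals(removed.genes):
        raise ValueError("preserved and removed networks have different gene sets")
    if preserved.tom.size == 0 or removed.tom.size == 0:
        raise ValueError("both networks must retain their TOM matrices")
    cons = consensus_tom(preserved.tom, removed.tom, params.quantile)
    if me_expression is None:
        raise ValueError("me_expression is required to compute background eigengenes")
    labels, merged, Z, mes = detect_modules(
        cons,
        me_expression,
        min_module_size=network_params.min_module_size,
        deep_split=network_params.deep_split,
        merge_cut_height=network_params.merge_cut_height,
        cut_height=network_params.cut_height,
        min_kme_to_stay=network_params.min_kme_to_stay,
    )
    return BackgroundNetwork(
        consensus_tom=cons,
        genes=preserved.genes,
        samples=preserved.samples,
        labels=labels,
        merged_labels=merged,
        mes=mes,
        dendrogram=Z,
        provenance={
            "preserved": preserved.provenance,
            "removed": removed.provenance,
            "quantile": params.quantile,
        },
    )


def module_overlap(
    preserved_labels: pd.Series,
    background_labels: pd.Series,
    universe: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Contingency table and one-sided Fisher enrichment p-values.

    Rows are preserved modules (grey excluded), columns are background modules
    with background grey as an extra column. The p-value for cell (module, bg) is
    the hypergeometric upper tail of drawing at least the observed overlap when
    sampling |module| genes from the universe.
    """
    if universe is None:
        universe = preserved_labels.index
    pl = preserved_labels.loc[universe]
    bl = background_labels.loc[universe]
    N = len(universe)
    rows = module_order(pl)
    cols = module_order(bl) + [GREY]
    cont = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for m in rows:
        counts = bl[pl == m].value_counts()
        for c in cols:
            cont.loc[m, c] = int(counts.get(c, 0))
    pvals = pd.DataFrame(1.0, index=rows, columns=cols)
    for m in rows:
        n_mod = int((pl == m).sum())
        if n_mod == 0:
            continue
        for c in cols:
            K = int((bl == c).sum())
            o = int(cont.loc[m, c])
            pvals.loc[m, c] = float(hypergeom.sf(o - 1, N, K, n_mod))
    return cont, pvals


def _adjust(pvals: pd.DataFrame, method: str) -> pd.DataFrame:
    flat = pvals.to_numpy().ravel()
    if flat.size == 0:
        return pvals.copy()
    adj = multipletests(flat, method=method)[1]
    return pd.DataFrame(
        adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
    )


def classify_correspondence(
    contingency: pd.DataFrame,
    significant: pd.DataFrame,
    grey_majority: float = 0.5,
) -> pd.Series:
    """Assign strong / weak / none to each preserved module (see module docstring)."""
    patterns = {}
    non_grey = [c for c in contingency.columns if c != GREY]
    for m in contingency.index:
        total = contingency.loc[m].sum()
        grey_frac = contingency.loc[m, GREY] / total if GREY in contingency.columns and total else 0.0
        nsig = int(significant.loc[m, non_grey].sum()) if non_grey else 0
        if grey_frac > grey_majority or nsig == 0:
            patterns[m] = "none"
        elif nsig == 1:
            patterns[m] = "strong"
        else:
            patterns[m] = "weak"
    return pd.Series(patterns, name="pattern", dtype=object)


def extract_fragments(
    preserved_labels: pd.Series,
    background_labels: pd.Series,
    pattern: pd.Series,
    fragment_min: int = 20,
) -> dict[str, list[tuple[str, list[str]]]]:
    """For weak (fragmented) modules, the per-background overlap gene sets.

    Only sets strictly larger than ``fragment_min`` genes are kept (default 20,
    matching the "> 20 genes" fragment filter).
    """
    fragments: dict[str, list[tuple[str, list[str]]]] = {}
    for m in pattern.index[pattern == "weak"]:
        genes = preserved_labels.index[preserved_labels == m]
        by_bg = background_labels.loc[genes]
        sets = []
        for bg in module_order(by_bg):
            members = list(by_bg.index[by_bg == bg])
            if len(members) > fragment_min:
                sets.append((bg, members))
        fragments[m] = sets
    return fragments


def correspondence_report(
    preserved_labels: pd.Series,
    background_labels: pd.Series,
    params: BackgroundParams | None = None,
    universe: pd.Index | None = None,
) -> CorrespondenceReport:
    """Full correspondence analysis of one preserved labelling vs a background."""
    params = params or BackgroundParams()
    cont, pvals = module_overlap(preserved_labels, background_labels, universe)
    adj = _adjust(pvals, params.method)
    sig = adj < params.alpha
    pattern = classify_correspondence(cont, sig, params.grey_majority)
    frags = extract_fragments(
        preserved_labels, background_labels, pattern, params.fragment_min
    )
    return CorrespondenceReport(
        contingency=cont,
        fisher_p=pvals,
        adjusted_p=adj,
        significant=sig,
        pattern=pattern,
        fragments=frags,
        alpha=params.alpha,
        method=params.method,
    )


def fragmentation_summary(
    reports: dict[str, CorrespondenceReport]
) -> pd.DataFrame:
    """Strong/weak/none counts and the fragmented fraction per network.

    The fragmented fraction is (weak + none) / total, i.e. the share of preserved
    modules without a single clean background counterpart.
    """
    if not reports:
        raise ValueError("need at least one correspondence report")
    rows = []
    for name, rep in reports.items():
        counts = rep.pattern.value_counts()
        strong = int(counts.get("strong", 0))
        weak = int(counts.get("weak", 0))
        none = int(counts.get("none", 0))
        total = strong + weak + none
        rows.append(
            {
                "network": name,
                "strong": strong,
                "weak": weak,
                "none": none,
                "total": total,
                "fragmented": weak + none,
                "fraction_fragmented": (weak + none) / total if total else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("network")
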