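"""Weighted gene co-expression network core.

Self-contained WGCNA-style machinery: soft-threshold selection by the scale-free
topology criterion, signed/unsigned adjacency, topological overlap (TOM), module
detection by average-linkage clustering of 1 - TOM with a dynamic tree cut, module
eigengenes (first principal component per module), eigengene-similarity module
merging, and module-membership (kME) correlations.

Conventions
-----------
* adjacency: ``a_ij = |cor|^beta`` (unsigned) or ``((1 + cor)/2)^beta`` (signed,
  the default: anti-correlated genes are never treated as connected);
* topological overlap:
  ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
  ``k_i = sum_{u != i} a_iu`` and a unit diagonal;
* module eigengenes are first principal components of the standardized
  within-module expression, sign-oriented to correlate positively with the
  module's average profile and scaled to unit sample variance;
* "grey" is the reserved label for unassigned genes.

Everything here is deterministic: identical input yields identical modules.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .treecut import cut_tree_dynamic

GREY = "grey"

__all__ = [
    "GREY",
    "NetworkParams",
    "Network",
    "SoftThresholdResult",
    "pick_soft_threshold",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "compute_kme",
    "build_network",
]


@dataclass
class NetworkParams:
    """Network construction parameters (WGCNA conventions as defaults)."""

    power: int | None = None  # None -> pick by scale-free fit
    network_type: str = "signed"
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.8
    min_module_size: int = 30
    deep_split: int = 2
    merge_cut_height: float = 0.25
    cut_height: float | None = None
    #: genes whose own-module membership (kME) falls below this stay grey
    min_kme_to_stay: float = 0.3

    def __post_init__(self) -> None:
        if self.network_type not in ("signed", "unsigned"):
            raise ValueError("network_type must be 'signed' or 'unsigned'")


@dataclass
class SoftThresholdResult:
    power: int
    satisfied: bool
    table: pd.DataFrame  # power, r_squared, slope, mean_connectivity


@dataclass
class Network:
    """A built co-expression network with modules, eigengenes and kME."""

    power: int
    network_type: str
    genes: pd.Index
    samples: pd.Index
    tom: np.ndarray
    dendrogram: np.ndarray  # scipy linkage matrix
    labels: pd.Series  # unmerged gene -> module label
    merged_labels: pd.Series
    mes: pd.DataFrame  # samples x merged modules
    mes_unmerged: pd.DataFrame
    kme: pd.DataFrame  # genes x merged modules
    provenance: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return int((self.merged_labels != GREY).sum() > 0) and self.mes.shape[1]

    def module_genes(self, merged: bool = True) -> dict[str, list[str]]:
        labels = self.merged_labels if merged else self.labels
        return {
            m: list(labels.index[labels == m])
            for m in module_order(labels)
        }


def _corr_matrix(data: pd.DataFrame) -> np.ndarray:
    values = data.to_numpy(dtype=float)
    sds = values.std(axis=1)
    if (sds == 0).any():
        bad = list(data.index[sds == 0])
        raise ValueError(f"zero-variance genes: {bad[:10]}")
    return np.corrcoef(values)


def adjacency(
    expr: pd.DataFrame, power: int, network_type: str = "signed"
) -> np.ndarray:
    """Soft-thresholded adjacency from gene-gene Pearson correlations."""
    if power < 1:
        raise ValueError("power must be >= 1")
    cor = _corr_matrix(expr)
    if network_type == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    elif network_type == "unsigned":
        adj = np.abs(cor) ** power
    else:
        raise ValueError("network_type must be 'signed' or 'unsigned'")
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix."""
    a = np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must be in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) ~ log10 k over binned connectivity."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    freq = np.bincount(which, minlength=n_bins).astype(float)
    means = np.array(
        [k[which == b].mean() if freq[b] else np.nan for b in range(n_bins)]
    )
    ok = (freq > 0) & (means > 0)
    if ok.sum() < 3:
        return 0.0, 0.0
    x = np.log10(means[ok])
    y = np.log10(freq[ok] / freq.sum())
    fit = linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: tuple[int, ...] = tuple(range(1, 21)),
    r2_target: float = 0.8,
    network_type: str = "signed",
) -> SoftThresholdResult:
    """Choose the smallest power whose connectivity distribution fits a power law.

    For each candidate the scale-free topology fit R^2 (with a negative slope
    required) and the mean connectivity are tabulated; the smallest power reaching
    ``r2_target`` wins, otherwise the best-fitting power is returned flagged.
    """
    if len(candidate_powers) < 1:
        raise ValueError("need at least one candidate power")
    cor = _corr_matrix(expr)
    base = (1.0 + cor) / 2.0 if network_type == "signed" else np.abs(cor)
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in candidate_powers:
        adj = base**beta
        k = adj.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        rows.append(
            {
                "power": beta,
                "r_squared": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    # a negative slope is part of the scale-free shape; vacuous targets skip it
    ok = table[(table.r_squared >= r2_target) & ((table.slope < 0) | (r2_target <= 0))]
    if len(ok):
        return SoftThresholdResult(int(ok.power.iloc[0]), True, table)
    best = int(table.r_squared.idxmax())
    if len(candidate_powers) == 1:
        warnings.warn("single candidate power: returned without scale-free check")
    else:
        warnings.warn(
            f"no power reached scale-free R^2 {r2_target}; using best fit "
            f"(power {table.power.iloc[best]})"
        )
    return SoftThresholdResult(int(table.power.iloc[best]), False, table)


def module_order(labels: pd.Series) -> list[str]:
    """Non-grey module names in natural (M1, M2, ...) order."""
    names = [m for m in labels.unique() if m != GREY]

    def key(name: str):
        m = re.match(r"^M(\d+)$", str(name))
        return (0, int(m.group(1))) if m else (1, str(name))

    return sorted(names, key=key)


def module_eigengenes(
    expr: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component per module, sign-oriented and unit-variance.

    Returns the eigengene matrix (samples x modules) and the fraction of
    within-module variance each eigengene explains.
    """
    mes = {}
    varexp = {}
    for mod in module_order(labels):
        genes = labels.index[labels == mod]
        X = expr.loc[genes].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError(f"zero-variance gene in module {mod}")
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd
        if len(genes) == 1:
            warnings.warn(f"module {mod} has a single gene; ME is its profile")
            v = Xs[0]
            varexp[mod] = 1.0
        else:
            _, s, vt = np.linalg.svd(Xs, full_matrices=False)
            v = vt[0]
            varexp[mod] = float(s[0] ** 2 / (s**2).sum())
        mean_profile = Xs.mean(axis=0)
        if np.dot(v, mean_profile) < 0:
            v = -v
        mes[mod] = v / v.std(ddof=1)
    me_df = pd.DataFrame(mes, index=expr.columns)
    return me_df, pd.Series(varexp, name="variance_explained", dtype=float)


def compute_kme(expr: pd.DataFrame, mes: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    X = expr.to_numpy(dtype=float)
    Xs = X - X.mean(axis=1, keepdims=True)
    Xn = Xs / np.linalg.norm(Xs, axis=1, keepdims=True)
    M = mes.to_numpy(dtype=float)
    Ms = M - M.mean(axis=0, keepdims=True)
    Mn = Ms / np.linalg.norm(Ms, axis=0, keepdims=True)
    return pd.DataFrame(
        np.clip(Xn @ Mn, -1.0, 1.0), index=expr.index, columns=mes.columns
    )


def _relabel_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    mapping = {old: f"M{i+1}" for i, old in enumerate(order)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def merge_close_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_cut_height: float = 0.25
) -> pd.Series:
    """Iteratively merge modules whose eigengenes correlate above 1 - cut height."""
    labels = labels.copy()
    if merge_cut_height <= 0:
        return labels
    while True:
        mods = module_order(labels)
        if len(mods) < 2:
            break
        mes, _ = module_eigengenes(expr, labels)
        C = np.corrcoef(mes[mods].to_numpy().T)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < 1.0 - merge_cut_height:
            break
        a, b = sorted((i, j))
        labels[labels == mods[b]] = mods[a]
    return _relabel_by_size(labels)


def _core_correlation(expr: pd.DataFrame, core: pd.Index, genes: pd.Index) -> pd.Series:
    """Correlation of each gene with the first PC of the core genes' expression."""
    X = expr.loc[core].to_numpy(dtype=float)
    Xs = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xs, full_matrices=False)
    me = vt[0]
    if np.dot(me, Xs.mean(axis=0)) < 0:
        me = -me
    G = expr.loc[genes].to_numpy(dtype=float)
    Gs = G - G.mean(axis=1, keepdims=True)
    Gn = Gs / np.linalg.norm(Gs, axis=1, keepdims=True)
    return pd.Series(Gn @ (me - me.mean()) / np.linalg.norm(me - me.mean()), index=genes)


def _refine_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    labels: pd.Series,
    min_module_size: int,
    deep_split: int,
    max_depth: int = 2,
) -> pd.Series:
    """Recursively re-cut each module on its own sub-dendrogram.

    Thresholds re-derived from the sub-tree's height range resolve structure the
    global cut cannot: a small tight block glued to a larger module sits just
    below the global noise floor, but inside the module's sub-tree the junction
    between the two parts is prominent. When the sub-cut splits a module, the
    parts replace it (over-splits of genuinely homogeneous modules are undone
    later by eigengene-similarity merging). When it does not split, genes the
    sub-cut leaves outside the module core are kept only if they correlate with
    the core eigengene beyond the expected maximum chance correlation among G
    genes at n samples, sqrt(2 ln G / n) — peripheral genuine members pass,
    stray genes that accreted onto the branch by selection do not.
    """
    labels = labels.copy()
    positions = pd.Series(np.arange(len(labels)), index=labels.index)
    chance_cor = np.sqrt(2.0 * np.log(max(len(labels), 2)) / expr.shape[1])
    for _ in range(max_depth):
        changed = False
        for mod in module_order(labels):
            genes = labels.index[labels == mod]
            if len(genes) < min_module_size + 3:
                continue
            idx = positions[genes].to_numpy()
            sub = 1.0 - tom[np.ix_(idx, idx)]
            np.fill_diagonal(sub, 0.0)
            sub_z = linkage(squareform(sub, checks=False), method="average")
            raw = cut_tree_dynamic(
                sub_z, min_module_size=min_module_size, deep_split=deep_split
            )
            k = raw.max()
            if k >= 2:
                for j in range(1, k + 1):
                    labels[genes[raw == j]] = f"{mod}.{j}"
                labels[genes[raw == 0]] = GREY
                changed = True
            elif k == 1 and (raw == 0).any():
                periphery = genes[raw == 0]
                cors = _core_correlation(expr, genes[raw == 1], periphery)
                drop = periphery[cors < chance_cor]
                if len(drop):
                    labels[drop] = GREY
                    changed = True
        if not changed:
            break
    return labels


def _strip_low_kme(
    expr: pd.DataFrame, labels: pd.Series, min_kme: float
) -> pd.Series:
    """Send genes with own-module membership below ``min_kme`` to grey."""
    if min_kme <= 0 or not (labels != GREY).any():
        return labels
    mes, _ = module_eigengenes(expr, labels)
    kme = compute_kme(expr, mes)
    labels = labels.copy()
    for mod in list(mes.columns):
        members = labels.index[labels == mod]
        low = members[kme.loc[members, mod] < min_kme]
        labels[low] = GREY
    return labels


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    merge_cut_height: float = 0.25,
    cut_height: float | None = None,
    min_kme_to_stay: float = 0.3,
) -> tuple[pd.Series, pd.Series, np.ndarray, pd.DataFrame]:
    """Average-linkage clustering of 1 - TOM with dynamic tree cut and ME merging.

    After the cut, genes whose membership (kME) to their own module falls below
    ``min_kme_to_stay`` are returned to grey — the usual guard against stray
    genes that accreted onto a branch without co-expressing with its core.
    Returns (labels, merged_labels, linkage matrix, merged-module eigengenes).
    """
    n = tom.shape[0]
    if n != len(expr.index):
        raise ValueError("TOM and expression gene sets differ")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    off_diag_max = float(tom.max(initial=0.0, where=~np.eye(n, dtype=bool)))
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: all genes grey")
        raw = np.zeros(n, dtype=int)
    elif off_diag_max <= 0.0:
        warnings.warn("TOM has no off-diagonal similarity: all genes grey")
        raw = np.zeros(n, dtype=int)
    else:
        raw = cut_tree_dynamic(
            Z,
            min_module_size=min_module_size,
            deep_split=deep_split,
            cut_height=cut_height,
        )
    labels = pd.Series(
        [GREY if r == 0 else f"raw{r}" for r in raw], index=expr.index, name="module"
    )
    labels = _refine_modules(tom, expr, labels, min_module_size, deep_split)
    labels = _strip_low_kme(expr, labels, min_kme_to_stay)
    labels = _relabel_by_size(labels)
    merged = merge_close_modules(expr, labels, merge_cut_height)
    if (merged != GREY).any():
        mes, _ = module_eigengenes(expr, merged)
    else:
        mes = pd.DataFrame(index=expr.columns)
    return labels, merged, Z, mes


def build_network(
    expr: pd.DataFrame,
    params: NetworkParams | None = None,
    keep_tom: bool = True,
    provenance: dict | None = None,
) -> Network:
    """Run the full network stage on one adjusted expression matrix."""
    params = params or NetworkParams()
    if params.power is None:
        st = pick_soft_threshold(
            expr, params.candidate_powers, params.r2_target, params.network_type
        )
        power = st.power
    else:
        power = params.power
    adj = adjacency(expr, power, params.network_type)
    tom = tom_similarity(adj)
    labels, merged, Z, mes = detect_modules(
        tom,
        expr,
        min_module_size=params.min_module_size,
        deep_split=params.deep_split,
        merge_cut_height=params.merge_cut_height,
        cut_height=params.cut_height,
        min_kme_to_stay=params.min_kme_to_stay,
    )
    kme = compute_kme(expr, mes) if mes.shape[1] else pd.DataFrame(index=expr.index)
    mes_unmerged = (
        module_eigengenes(expr, labels)[0]
        if (labels != GREY).any()
        else pd.DataFrame(index=expr.columns)
    )
    return Network(
        power=power,
        network_type=params.network_type,
        genes=expr.index,
        samples=expr.columns,
        tom=tom if keep_tom else np.empty((0, 0)),
        dendrogram=Z,
        labels=labels,
        merged_labels=merged,
        mes=mes,
        mes_unmerged=mes_unmerged,
        kme=kme,
        provenance=provenance or {},
    )
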