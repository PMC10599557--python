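"""Shuffled-score artifact networks and the fragmentation proportion test.

Internal validation of the preserve/remove design: if the fragmentation of
preserved modules against the background were an artifact of the cleaning step
itself, it would be reproduced when the genomic score is shuffled across samples
(destroying any genuine score-expression coupling while keeping the score's
marginal distribution). The procedure:

1. permute the score ``n_shuffles`` times (default 50);
2. for each permutation, re-clean expression in preserve and remove mode and
   build the preserved network;
3. average the per-shuffle adjacency matrices per mode, take the TOM of each
   mean, form their consensus — the *artifact background* — and detect its
   modules with the same parameters;
4. compute each shuffled preserved network's fragmentation against the artifact
   background, and compare the original network's fragmentation proportion with
   the shuffled ones via a k-sample equality-of-proportions chi-squared test
   (Pearson X^2 on the 2 x (1 + n_shuffles) table, df = n_shuffles, no
   continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .adjust import clean_expression, fit_gene_models
from .background import (
    BackgroundNetwork,
    BackgroundParams,
    consensus_tom,
    correspondence_report,
)
from .network import NetworkParams, adjacency, detect_modules, tom_similarity
from .screen import CovariateTable

__all__ = [
    "ShuffleEnsemble",
    "PropTestResult",
    "shuffle_scores",
    "build_shuffled_ensemble",
    "average_adjacency_background",
    "fragmentation_proportion_test",
]


@dataclass
class ShuffleEnsemble:
    score_id: str
    seed: int
    permuted_scores: np.ndarray  # n_shuffles x n_samples
    shuffle_labels: list[pd.Series]  # unmerged preserved labels per shuffle
    fragmentation: list[tuple[int, int]]  # (fragmented, total) per shuffle
    artifact_background: BackgroundNetwork
    reports: list = field(default_factory=list)

    @property
    def n_shuffles(self) -> int:
        return len(self.shuffle_labels)

    @property
    def artifact_grey_count(self) -> int:
        # surfaced, not asserted: backgrounds from shuffled scores may have
        # few or no grey genes compared with real-score backgrounds
        return self.artifact_background.grey_count


@dataclass
class PropTestResult:
    statistic: float
    df: int
    p_value: float
    proportions: list[float]


def shuffle_scores(
    score: np.ndarray | pd.Series, n_shuffles: int, seed: int = 0
) -> np.ndarray:
    """``n_shuffles`` independent uniform permutations of the score vector."""
    values = np.asarray(score, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to shuffle")
    rng = np.random.default_rng(seed)
    return np.stack([rng.permutation(values) for _ in range(n_shuffles)])


def average_adjacency_background(
    preserve_adjacencies: Sequence[np.ndarray] | Iterable[np.ndarray],
    remove_adjacencies: Sequence[np.ndarray] | Iterable[np.ndarray],
    me_expression: pd.DataFrame,
    network_params: NetworkParams | None = None,
    background_params: BackgroundParams | None = None,
) -> BackgroundNetwork:
    """Artifact background from ensembles of adjacency matrices.

    Adjacencies are averaged entrywise per mode (incrementally, so an iterator of
    matrices is fine), each mean is converted to a TOM, and the two TOMs are
    combined with the same quantile-scaled minimum consensus used for real
    backgrounds.
    """
    network_params = network_params or NetworkParams()
    background_params = background_params or BackgroundParams()

    def running_mean(mats: Iterable[np.ndarray]) -> np.ndarray:
        total, count = None, 0
        for m in mats:
            m = np.asarray(m, dtype=float)
            if total is None:
                total = m.copy()
            else:
                if m.shape != total.shape:
                    raise ValueError("adjacency shapes differ within a mode")
                total += m
            count += 1
        if count < 2:
            raise ValueError("need at least 2 adjacency matrices per mode")
        return total / count

    mean_p = running_mean(preserve_adjacencies)
    mean_r = running_mean(remove_adjacencies)
    return _background_from_mean_adjacency(
        mean_p, mean_r, me_expression, network_params, background_params
    )


def _background_from_mean_adjacency(
    mean_preserve: np.ndarray,
    mean_remove: np.ndarray,
    me_expression: pd.DataFrame,
    network_params: NetworkParams,
    background_params: BackgroundParams,
) -> BackgroundNetwork:
    tom_p = tom_similarity(mean_preserve)
    tom_r = tom_similarity(mean_remove)
    cons = consensus_tom(tom_p, tom_r, background_params.quantile)
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
        genes=me_expression.index,
        samples=me_expression.columns,
        labels=labels,
        merged_labels=merged,
        mes=mes,
        dendrogram=Z,
        provenance={"kind": "artifact_background"},
    )


def build_shuffled_ensemble(
    expr: pd.DataFrame,
    cov: CovariateTable,
    score_id: str,
    n_shuffles: int = 50,
    seed: int = 0,
    network_params: NetworkParams | None = None,
    background_params: BackgroundParams | None = None,
    nuisance: list[str] | None = None,
    max_genes: int = 6000,
    allow_large: bool = False,
) -> ShuffleEnsemble:
    """Full shuffled-score ensemble for one genomic score.

    Per-shuffle networks reuse the soft power given in ``network_params`` (pass
    the originally chosen power; recomputing per shuffle would confound score
    shuffling with power re-selection). The per-mode adjacency means are
    accumulated incrementally so memory stays at two gene x gene matrices.
    """
    if len(expr) > max_genes and not allow_large:
        raise ValueError(
            f"{len(expr)} genes exceeds the resource cap ({max_genes}); "
            "pass allow_large=True to override"
        )
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles for the proportion test")
    network_params = network_params or NetworkParams()
    background_params = background_params or BackgroundParams()
    if network_params.power is None:
        raise ValueError("network_params.power must be fixed for the ensemble")
    perms = shuffle_scores(cov.data[score_id].to_numpy(), n_shuffles, seed)

    sum_p = np.zeros((len(expr), len(expr)))
    sum_r = np.zeros_like(sum_p)
    shuffle_labels: list[pd.Series] = []
    me_expr_sum = np.zeros(expr.shape)
    for i in range(n_shuffles):
        data = cov.data.copy()
        data[score_id] = perms[i]
        cov_i = CovariateTable(data, dict(cov.roles))
        fits = fit_gene_models(expr, cov_i, score_id, nuisance=nuisance)
        pres = clean_expression(expr, fits, "preserve")
        rem = clean_expression(expr, fits, "remove")
        adj_p = adjacency(pres.data, network_params.power, network_params.network_type)
        adj_r = adjacency(rem.data, network_params.power, network_params.network_type)
        sum_p += adj_p
        sum_r += adj_r
        me_expr_sum += (pres.data.to_numpy() + rem.data.to_numpy()) / 2.0
        tom_p = tom_similarity(adj_p)
        labels, _, _, _ = detect_modules(
            tom_p,
            pres.data,
            min_module_size=network_params.min_module_size,
            deep_split=network_params.deep_split,
            merge_cut_height=network_params.merge_cut_height,
            cut_height=network_params.cut_height,
            min_kme_to_stay=network_params.min_kme_to_stay,
        )
        shuffle_labels.append(labels)

    me_expression = pd.DataFrame(
        me_expr_sum / n_shuffles, index=expr.index, columns=expr.columns
    )
    artifact = _background_from_mean_adjacency(
        sum_p / n_shuffles,
        sum_r / n_shuffles,
        me_expression,
        network_params,
        background_params,
    )
    fragmentation = []
    reports = []
    for labels in shuffle_labels:
        rep = correspondence_report(
            labels, artifact.merged_labels, background_params
        )
        fragmentation.append((rep.n_fragmented, rep.n_modules))
        reports.append(rep)
    return ShuffleEnsemble(
        score_id=score_id,
        seed=seed,
        permuted_scores=perms,
        shuffle_labels=shuffle_labels,
        fragmentation=fragmentation,
        artifact_background=artifact,
        reports=reports,
    )


def fragmentation_proportion_test(
    original: tuple[int, int],
    shuffled: list[tuple[int, int]],
) -> PropTestResult:
    """k-sample equality-of-proportions test (original vs each shuffle).

    Pearson chi-squared on the 2 x k success/failure table without continuity
    correction, df = k - 1 (e.g. 50 shuffles + the original -> df = 50).
    """
    groups = [original] + list(shuffled)
    if len(groups) < 2:
        raise ValueError("need the original plus at least one shuffled group")
    table = []
    for frag, total in groups:
        if total <= 0:
            raise ValueError("every group must have a positive module total")
        if frag > total:
            raise ValueError("fragmented count exceeds total")
        table.append([frag, total - frag])
    arr = np.array(table).T  # 2 x k
    # degenerate margins (all fragmented or none): X^2 is 0 by definition
    if (arr.sum(axis=1) == 0).any():
        return PropTestResult(0.0, len(groups) - 1, 1.0, [f / t for f, t in groups])
    stat, p, df, _ = chi2_contingency(arr, correction=False)
    return PropTestResult(
        float(stat), int(df), float(p), [f / t for f, t in groups]
    )
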