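"""End-to-end orchestration: screening -> adjustment -> networks -> backgrounds
-> convergence -> optional shuffled-score null, with artifact writing and report
assembly.

All randomness flows from one master seed via named substreams (one per stage),
so re-running a configuration reproduces every table bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import MODES, fit_gene_models, clean_expression
from .background import BackgroundParams, consensus_background, correspondence_report, fragmentation_summary
from .convergence import (
    compare_kme_distributions,
    correlate_me_scores,
    microglia_module_check,
)
from .io import read_covariates, read_expression, read_gmt
from .network import GREY, NetworkParams, build_network, pick_soft_threshold
from .nullmodel import build_shuffled_ensemble, fragmentation_proportion_test
from .screen import (
    CovariateTable,
    SelectionPolicy,
    collinearity_diagnostics,
    partition_variance_two_step,
    select_covariates,
)

logger = logging.getLogger("gscoex")


@dataclass
class EnrichmentParams:
    n_iter: int = 100_000
    seed: int = 0


@dataclass
class NullParams:
    enabled: bool = False
    n_shuffles: int = 50
    score_ids: list[str] = field(default_factory=list)
    max_genes: int = 6000
    allow_large: bool = False


@dataclass
class PipelineConfig:
    expression_path: str = ""
    covariates_path: str = ""
    out_dir: str = "gscoex_run"
    score_ids: list[str] = field(
        default_factory=lambda: ["GS3_SCZ", "GS5_SCZ", "GS3_HT", "GS5_HT"]
    )
    gene_set_paths: dict[str, str] = field(default_factory=dict)
    vif_threshold: float = 10.0
    network: NetworkParams = field(default_factory=NetworkParams)
    background: BackgroundParams = field(default_factory=BackgroundParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    null: NullParams = field(default_factory=NullParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, sub in (
            ("network", NetworkParams),
            ("background", BackgroundParams),
            ("enrichment", EnrichmentParams),
            ("null", NullParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = sub(**raw[key])
        if "network" in raw and isinstance(raw["network"], NetworkParams):
            if raw["network"].candidate_powers is not None:
                raw["network"].candidate_powers = tuple(raw["network"].candidate_powers)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    networks: dict
    backgrounds: dict
    reports: dict
    me_correlations: pd.DataFrame
    fragmentation: pd.DataFrame
    enrichment: pd.DataFrame
    kme_shifts: pd.DataFrame
    null_tests: dict
    out_dir: Path


def _substream(master_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig,
    expr: pd.DataFrame | None = None,
    cov: CovariateTable | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the full analysis for one cohort.

    ``expr``/``cov`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from the configured paths.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    if expr is None:
        expr = read_expression(config.expression_path)
    if cov is None:
        cov = read_covariates(config.covariates_path, interest=config.score_ids)
    missing = [s for s in config.score_ids if s not in cov.data.columns]
    if missing:
        raise ValueError(f"stage screen: score columns missing: {missing}")

    logger.info("screen: variance partition and collinearity on %d genes", len(expr))
    vft = partition_variance_two_step(expr, cov)
    colrep = collinearity_diagnostics(cov, config.vif_threshold)
    traits: dict[str, list[str]] = {}
    for s in config.score_ids:  # group GS3_SCZ/GS5_SCZ etc. by trait suffix
        trait = s.split("_")[-1] if "_" in s else s
        traits.setdefault(trait, []).append(s)
    selection = select_covariates(vft, colrep, SelectionPolicy(candidates=traits))

    logger.info("adjust: eight preserve/remove inputs")
    networks: dict = {}
    backgrounds: dict = {}
    reports: dict = {}
    me_rows = []
    kme_rows = []
    enrich_rows = []
    gene_sets = {
        name: read_gmt(path) for name, path in config.gene_set_paths.items()
    }
    universe = list(expr.index)

    power = config.network.power
    for score_id in config.score_ids:
        fits = fit_gene_models(expr, cov, score_id, nuisance=selection.non_interest)
        adjusted = {m: clean_expression(expr, fits, m) for m in MODES}
        if power is None:
            st = pick_soft_threshold(
                adjusted["preserve"].data,
                config.network.candidate_powers,
                config.network.r2_target,
                config.network.network_type,
            )
            power = st.power
            logger.info("network: soft power %d (picked once, reused)", power)
        net_params = NetworkParams(
            power=power,
            network_type=config.network.network_type,
            min_module_size=config.network.min_module_size,
            deep_split=config.network.deep_split,
            merge_cut_height=config.network.merge_cut_height,
            cut_height=config.network.cut_height,
        )
        pair = {}
        for mode in MODES:
            logger.info("network: %s %s", score_id, mode)
            pair[mode] = build_network(
                adjusted[mode].data,
                net_params,
                provenance={"score": score_id, "mode": mode},
            )
            networks[(mode, score_id)] = pair[mode]
        me_expr = (adjusted["preserve"].data + adjusted["remove"].data) / 2.0
        bg = consensus_background(
            pair["preserve"], pair["remove"], config.background, net_params, me_expr
        )
        backgrounds[score_id] = bg
        for which, labels in (
            ("merged", pair["preserve"].merged_labels),
            ("unmerged", pair["preserve"].labels),
        ):
            reports[(score_id, which)] = correspondence_report(
                labels, bg.merged_labels, config.background
            )
        # free the big matrices once the background exists
        for mode in MODES:
            networks[(mode, score_id)].tom = np.empty((0, 0))
        bg.consensus_tom = np.empty((0, 0))

        scores_df = cov.data[config.score_ids]
        me_tab = correlate_me_scores(
            pair["preserve"].mes, scores_df, reports[(score_id, "merged")].pattern
        )
        me_tab.insert(0, "network", f"{score_id}_preserve")
        me_rows.append(me_tab)

        shift = compare_kme_distributions(pair["preserve"].kme, pair["remove"].kme)
        shift.insert(0, "network", score_id)
        kme_rows.append(shift)

        for set_name, sets in gene_sets.items():
            for gs_name, genes in sets.items():
                results = microglia_module_check(
                    pair["preserve"].module_genes(),
                    genes,
                    universe,
                    n_iter=config.enrichment.n_iter,
                    seed=_substream(config.seed, f"enrich:{score_id}:{gs_name}"),
                    set_name=gs_name,
                )
                for r in results:
                    enrich_rows.append(
                        {
                            "network": f"{score_id}_preserve",
                            "module": r.module,
                            "gene_set": r.gene_set,
                            "overlap": r.overlap,
                            "module_size": r.module_size,
                            "p_value": r.p_value,
                            "n_iterations": r.n_iterations,
                        }
                    )

    frag = fragmentation_summary(
        {f"{sid}_{which}": rep for (sid, which), rep in reports.items()}
    )
    me_correlations = pd.concat(me_rows, ignore_index=True)
    kme_shifts = (
        pd.concat(kme_rows, ignore_index=True) if kme_rows else pd.DataFrame()
    )
    enrichment = pd.DataFrame(enrich_rows)

    null_tests: dict = {}
    if config.null.enabled:
        for score_id in config.null.score_ids or config.score_ids[:1]:
            logger.info("nullmodel: %d shuffles of %s", config.null.n_shuffles, score_id)
            ens = build_shuffled_ensemble(
                expr,
                cov,
                score_id,
                n_shuffles=config.null.n_shuffles,
                seed=_substream(config.seed, f"null:{score_id}"),
                network_params=NetworkParams(
                    power=power,
                    network_type=config.network.network_type,
                    min_module_size=config.network.min_module_size,
                    deep_split=config.network.deep_split,
                    merge_cut_height=config.network.merge_cut_height,
                ),
                background_params=config.background,
                nuisance=selection.non_interest,
                max_genes=config.null.max_genes,
                allow_large=config.null.allow_large,
            )
            rep = reports[(score_id, "unmerged")]
            test = fragmentation_proportion_test(
                (rep.n_fragmented, rep.n_modules), ens.fragmentation
            )
            null_tests[score_id] = {
                "statistic": test.statistic,
                "df": test.df,
                "p_value": test.p_value,
                "original_proportion": test.proportions[0],
                "artifact_background_grey": ens.artifact_grey_count,
            }

    result = PipelineResult(
        config=config,
        networks=networks,
        backgrounds=backgrounds,
        reports=reports,
        me_correlations=me_correlations,
        fragmentation=frag,
        enrichment=enrichment,
        kme_shifts=kme_shifts,
        null_tests=null_tests,
        out_dir=out,
    )
    if write:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    labels = pd.DataFrame(
        {
            f"{mode}_{sid}": net.merged_labels
            for (mode, sid), net in result.networks.items()
        }
    )
    labels.to_csv(out / "module_labels.tsv", sep="\t", index_label="gene_id")
    for sid, bg in result.backgrounds.items():
        bg.merged_labels.to_frame("module").to_csv(
            out / f"background_labels_{sid}.tsv", sep="\t", index_label="gene_id"
        )
    for (sid, which), rep in result.reports.items():
        rep.contingency.to_csv(
            out / f"overlap_contingency_{sid}_{which}.tsv", sep="\t"
        )
        rep.adjusted_p.to_csv(out / f"overlap_fisher_p_{sid}_{which}.tsv", sep="\t")
        rep.pattern.to_frame("pattern").to_csv(
            out / f"correspondence_{sid}_{which}.tsv", sep="\t"
        )
    result.me_correlations.to_csv(out / "me_score_correlations.tsv", sep="\t", index=False)
    result.fragmentation.to_csv(out / "fragmentation_summary.tsv", sep="\t")
    if len(result.enrichment):
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if len(result.kme_shifts):
        result.kme_shifts.to_csv(out / "kme_shifts.tsv", sep="\t", index=False)
    if result.null_tests:
        with open(out / "null_tests.json", "w") as fh:
            json.dump(result.null_tests, fh, indent=1)
    manifest = {
        "gscoex_version": __version__,
        "numpy_version": np.__version__,
        "config": result.config.to_dict(),
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "networks": {
            f"{mode}_{sid}": {
                "power": net.power,
                "n_modules_merged": int(len(set(net.merged_labels)) - (GREY in set(net.merged_labels))),
                "n_modules_unmerged": int(len(set(net.labels)) - (GREY in set(net.labels))),
                "grey_genes": int((net.merged_labels == GREY).sum()),
            }
            for (mode, sid), net in result.networks.items()
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def write_report(run_dir: str | Path, result: PipelineResult | None = None) -> Path:
    """Assemble a human-readable summary (tables + basic plots) for a finished run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import dendrogram

    run = Path(run_dir)
    rep_dir = run / "report"
    rep_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# gscoex run report", ""]
    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        lines.append(f"config digest: `{manifest['config_digest']}`")
        lines.append("")
        lines.append("| network | power | merged modules | unmerged modules | grey |")
        lines.append("|---|---|---|---|---|")
        for name, info in manifest["networks"].items():
            lines.append(
                f"| {name} | {info['power']} | {info['n_modules_merged']} | "
                f"{info['n_modules_unmerged']} | {info['grey_genes']} |"
            )
    else:
        lines.append("(manifest.json missing — partial report)")
    frag_path = run / "fragmentation_summary.tsv"
    if frag_path.exists():
        frag = pd.read_csv(frag_path, sep="\t", index_col=0)
        lines += ["", "## Fragmentation", "", frag.to_markdown()]
    me_path = run / "me_score_correlations.tsv"
    if me_path.exists():
        me = pd.read_csv(me_path, sep="\t")
        sig = me[me.p_value < 0.05]
        if "pattern" in me.columns:
            # Table-1-style cells: correlated modules / total, by pattern
            cells = []
            for (net, pat), grp in me.groupby(["network", "pattern"]):
                mods = grp.module.unique()
                corr_mods = grp[grp.p_value < 0.05].module.unique()
                cells.append(
                    {
                        "network": net,
                        "pattern": pat,
                        "correlated/total": f"{len(corr_mods)}/{len(mods)}",
                    }
                )
            lines += [
                "",
                "## Score-correlated modules by correspondence pattern",
                "",
                pd.DataFrame(cells).to_markdown(index=False),
            ]
        lines += ["", f"{len(sig)} (module, score) correlations with p < 0.05"]
    if result is not None:
        for (sid, which), rep in result.reports.items():
            if which != "merged":
                continue
            fig, ax = plt.subplots(figsize=(6, 4))
            mat = -np.log10(rep.adjusted_p.to_numpy().clip(1e-300))
            im = ax.imshow(mat, aspect="auto", cmap="viridis")
            ax.set_xticks(range(len(rep.adjusted_p.columns)))
            ax.set_xticklabels(rep.adjusted_p.columns, rotation=90, fontsize=6)
            ax.set_yticks(range(len(rep.adjusted_p.index)))
            ax.set_yticklabels(rep.adjusted_p.index, fontsize=6)
            ax.set_title(f"module vs background overlap, {sid}")
            fig.colorbar(im, label="-log10 adjusted p")
            fig.tight_layout()
            fig.savefig(rep_dir / f"overlap_heatmap_{sid}.png", dpi=120)
            plt.close(fig)
        for (mode, sid), net in result.networks.items():
            if mode != "preserve":
                continue
            fig, ax = plt.subplots(figsize=(7, 3))
            dendrogram(net.dendrogram, no_labels=True, ax=ax, color_threshold=0)
            ax.set_title(f"gene dendrogram, {sid} preserved")
            fig.tight_layout()
            fig.savefig(rep_dir / f"dendrogram_{sid}_preserve.png", dpi=120)
            plt.close(fig)
            if net.kme.shape[1]:
                fig, ax = plt.subplots(figsize=(5, 3))
                ax.hist(net.kme.to_numpy().ravel(), bins=40)
                ax.set_xlabel("kME")
                ax.set_title(f"kME distribution, {sid} preserved")
                fig.tight_layout()
                fig.savefig(rep_dir / f"kme_hist_{sid}_preserve.png", dpi=120)
                plt.close(fig)
    null_path = run / "null_tests.json"
    if null_path.exists():
        lines += ["", "## Shuffled-score null tests", "", "```json",
                  null_path.read_text(), "```"]
    report_md = rep_dir / "report.md"
    report_md.write_text("\n".join(lines) + "\n")
    return report_md
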