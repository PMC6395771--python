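"""End-to-end orchestration: simulate -> preprocess -> differential
expression -> coexpression network -> module preservation -> hub
conservation -> enrichment -> report.

Each region is analyzed independently (a region-specific child seed is
derived from the global seed); cross-region DEG overlap and log2FC
concordance run afterwards.  All outputs are text (TSV/GMT/JSON) and a
run is byte-reproducible given its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexp as de
from . import enrichment as enr
from . import hubs as hub_mod
from . import io as sio
from . import network as net
from . import preprocess as pp
from . import preservation as pres
from . import simulate as sim
from .config import PipelineConfig

__all__ = ["run_pipeline", "run_region", "region_seed"]


def region_seed(global_seed: int, region_index: int) -> int:
    """Deterministic per-region child seed, kept below 2**31."""
    ss = np.random.SeedSequence([int(global_seed), int(region_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_region(config: PipelineConfig, region: str, seed: int) -> dict:
    """Run the full single-region analysis; returns an in-memory bundle."""
    sp = config.simulate
    design = sim.SyntheticDesign(
        n_genes=sp.n_genes,
        n_case=sp.n_case,
        n_control=sp.n_control,
        module_sizes=list(sp.module_sizes),
        module_loadings=sp.module_loadings,
        disrupted_module=sp.disrupted_module,
        disruption_mode=sp.disruption_mode,
        n_deg=sp.n_deg,
        deg_log2fc=sp.deg_log2fc,
        dispersion=sp.dispersion,
        batch_levels=sp.batch_levels,
        batch_effect_sd=sp.batch_effect_sd,
        region=region,
        seed=seed,
    )
    counts_case, counts_ctrl, metadata, truth = sim.simulate_dataset(design)
    counts = pd.concat([counts_case, counts_ctrl], axis=1)

    # --- preprocess ---------------------------------------------------
    filtered, kept = pp.filter_expressed(
        counts, metadata, min_cpm=config.preprocess.min_cpm,
        min_frac=config.preprocess.min_frac,
    )
    expr = pp.normalize_log(filtered, pseudocount=config.preprocess.pseudocount)
    adjust = [c for c in ("sex", "batch") if metadata[c].nunique() > 1]
    svs = pp.estimate_surrogate_variables(
        expr, metadata, primary="group", adjust=adjust,
        n_sv=config.preprocess.n_sv, seed=seed + 1,
    )
    base_design = pp.build_design_matrix(metadata, ["group"] + adjust)
    full_design = pd.concat([base_design, svs], axis=1)
    weights_no_sv = pp.estimate_sample_weights(expr, base_design)
    weights_sv = pp.estimate_sample_weights(expr, full_design)
    weight_cmp = pp.compare_weight_distributions(weights_no_sv, weights_sv)

    # --- differential expression --------------------------------------
    contrast = [c for c in base_design.columns if c.startswith("group_")][0]
    de_table = de.fit_nb_glm_wald(filtered, full_design, contrast=contrast)
    # orient log2fc as case/control
    if contrast == "group_control":
        de_table[["log2fc", "wald_z"]] *= -1.0
    degs = de.call_degs(
        de_table, adj_alpha=config.diffexp.adj_alpha,
        raw_alpha=config.diffexp.raw_alpha,
    )

    # --- coexpression network on the control (reference) data ---------
    ctrl_samples = metadata.index[metadata["group"] == "control"]
    case_samples = metadata.index[metadata["group"] == "case"]
    expr_ctrl = expr[ctrl_samples]
    expr_case = expr[case_samples]

    if config.network.beta == "auto":
        beta, sft_table = net.pick_soft_threshold(
            expr_ctrl, r2_min=config.network.r2_min
        )
    else:
        beta, sft_table = int(config.network.beta), None
    cor_ctrl, _, _ = net.correlation_matrix(expr_ctrl, config.network.max_na_frac)
    adj = net.adjacency(cor_ctrl, beta)
    tom_sim = net.tom(adj)
    partition = net.detect_modules(1.0 - tom_sim, config.network.min_module_size)
    mes_ctrl = net.module_eigengenes(expr_ctrl, partition)
    kme_ctrl = net.kme(expr_ctrl, mes_ctrl)

    # --- preservation --------------------------------------------------
    mapped, _ = pres.map_reference_modules(partition, expr_case)
    stats = pres.permutation_null(
        expr_ctrl, expr_case, mapped, beta=beta,
        n_perm=config.preserve.n_perm, seed=seed + 2,
    )
    mes_case = net.module_eigengenes(expr_case, mapped)
    kme_case = net.kme(expr_case, mes_case)
    selected, rationale = pres.select_least_preserved(stats, kme_ctrl, kme_case)

    # --- hubs in the least preserved module ----------------------------
    module_genes = mapped.genes(selected)
    hubs_ctrl = hub_mod.identify_hubs(
        expr_ctrl, module_genes, threshold=config.hubs.threshold
    )
    hubs_case = hub_mod.identify_hubs(
        expr_case, module_genes, threshold=config.hubs.threshold
    )
    hub_report = hub_mod.HubReport.build(selected, hubs_ctrl, hubs_case)
    hub_degs = hub_mod.hub_deg_overlap(hub_report, module_genes, degs)

    # --- enrichment ----------------------------------------------------
    ep = config.enrich
    gene_sets = sim.simulate_gene_sets(
        truth, n_sets=ep.n_sets, set_size=min(ep.set_size, sp.n_genes),
        enriched_fraction=ep.enriched_fraction, seed=seed + 3,
    )
    background = list(expr.index)
    ora_table = (
        enr.ora(degs.relaxed, gene_sets, background)
        if degs.relaxed
        else pd.DataFrame()
    )
    mset_p = None
    if ep.method == "mset" and degs.relaxed:
        mset_p, _ = enr.mset(
            degs.relaxed, gene_sets["enriched_set"], background,
            n_iter=ep.n_iter, seed=seed + 4,
        )

    return {
        "region": region,
        "seed": seed,
        "beta": beta,
        "counts": counts,
        "metadata": metadata,
        "truth": truth,
        "expr": expr,
        "svs": svs,
        "weights_no_sv": weights_no_sv,
        "weights_sv": weights_sv,
        "weight_comparison": weight_cmp,
        "de_table": de_table,
        "degs": degs,
        "soft_threshold_table": sft_table,
        "partition": partition,
        "preservation": stats,
        "least_preserved": selected,
        "selection_rationale": rationale,
        "kme_control": kme_ctrl,
        "kme_case": kme_case,
        "hub_report": hub_report,
        "hub_deg_overlap": hub_degs,
        "gene_sets": gene_sets,
        "ora": ora_table,
        "mset_p": mset_p,
        "n_genes_prefilter": len(counts),
        "n_genes_postfilter": len(filtered),
    }


def _write_region(out: Path, bundle: dict) -> None:
    region = bundle["region"]
    rdir = out / region
    rdir.mkdir(parents=True, exist_ok=True)
    sio.write_counts(bundle["counts"], rdir / "counts.tsv")
    sio.write_metadata(bundle["metadata"], rdir / "metadata.tsv")
    sio.write_table(
        bundle["de_table"].reset_index(), rdir / "differential_expression.tsv"
    )
    sio.write_table(
        bundle["partition"].labels.rename("module").reset_index().rename(
            columns={"index": "gene_id"}
        ),
        rdir / "modules.tsv",
    )
    sio.write_table(
        bundle["preservation"].summary.reset_index(), rdir / "preservation.tsv"
    )
    sio.write_table(
        bundle["preservation"].zscores.reset_index(names="module"),
        rdir / "preservation_zscores.tsv",
    )
    hub_rows = [
        {"gene": g, "status": status}
        for status, genes in [
            ("exclusive_control", bundle["hub_report"].exclusive_control),
            ("shared", bundle["hub_report"].shared),
            ("exclusive_case", bundle["hub_report"].exclusive_case),
        ]
        for g in sorted(genes)
    ]
    sio.write_table(
        pd.DataFrame(hub_rows, columns=["gene", "status"]), rdir / "hubs.tsv"
    )
    sio.write_table(bundle["hub_deg_overlap"], rdir / "hub_deg_overlap.tsv")
    if len(bundle["ora"]):
        sio.write_table(bundle["ora"], rdir / "enrichment_ora.tsv")
    sio.write_gmt(bundle["gene_sets"], rdir / "gene_sets.gmt")
    sio.write_table(
        pd.DataFrame(
            {
                "sample_id": bundle["weights_no_sv"].index,
                "weight_no_sv": bundle["weights_no_sv"].to_numpy(),
                "weight_sv": bundle["weights_sv"].to_numpy(),
            }
        ),
        rdir / "sample_weights.tsv",
    )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every region plus the cross-region comparison; write a report
    bundle under ``out_dir`` and return the summary dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundles = []
    for i, region in enumerate(config.regions):
        seed = region_seed(config.seed, i)
        bundle = run_region(config, region, seed)
        _write_region(out, bundle)
        bundles.append(bundle)

    summary: dict = {"seed": config.seed, "regions": {}}
    for b in bundles:
        wc = b["weight_comparison"]
        summary["regions"][b["region"]] = {
            "n_genes_prefilter": b["n_genes_prefilter"],
            "n_genes_postfilter": b["n_genes_postfilter"],
            "n_surrogate_variables": int(b["svs"].shape[1]),
            "weight_ks_statistic": round(wc.ks_statistic, 4),
            "n_deg_strict": len(b["degs"].strict),
            "n_deg_relaxed": len(b["degs"].relaxed),
            "beta": b["beta"],
            "n_modules": len(b["partition"].module_ids),
            "least_preserved_module": int(b["least_preserved"]),
            "true_disrupted_module": (
                None
                if b["truth"].disrupted_module is None
                else int(b["truth"].disrupted_module)
            ),
            "selection_agreement": b["selection_rationale"].agreement,
            "hub_counts": b["hub_report"].counts(),
            "zsummary": {
                str(m): round(float(z), 3)
                for m, z in b["preservation"].summary["Zsummary"].items()
            },
        }

    if len(bundles) >= 2:
        overlap, fraction, per_gene = de.overlap_and_concordance(
            {b["region"]: b["de_table"] for b in bundles},
            {b["region"]: b["degs"].relaxed for b in bundles},
        )
        sio.write_table(overlap, out / "deg_overlap.tsv")
        if len(per_gene):
            sio.write_table(per_gene, out / "deg_concordance.tsv")
        summary["cross_region"] = {
            "n_multi_region_degs": int(
                overlap.loc[overlap["regions"].str.contains(r"\+"), "n_genes"].sum()
            ),
            "log2fc_sign_concordance": (
                None if np.isnan(fraction) else round(float(fraction), 4)
            ),
        }

    if config.make_plots:
        from . import plotting

        for b in bundles:
            plotting.preservation_plot(
                b["preservation"],
                b["least_preserved"],
                out / b["region"] / "preservation_plot.png",
            )
            plotting.kme_scatter(
                b["kme_control"],
                b["kme_case"],
                b["least_preserved"],
                out / b["region"] / "kme_scatter.png",
            )

    manifest = {
        "config": asdict(config),
        "region_seeds": {
            region: region_seed(config.seed, i)
            for i, region in enumerate(config.regions)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
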