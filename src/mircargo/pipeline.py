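"""End-to-end pipeline: simulate (or load) every input and chain all stages.

Stage order: low-TPM filter -> differential expression -> DRG calling ->
gene collapse -> pre-ranked GSEA; Ct cards -> expression calling -> ddCt
quantification; target predictions -> consensus -> intersection with the
down-regulated list; ORA on the consensus union -> pathway convergence
against the GSEA results; survival scan. A JSON manifest records the
effective configuration, per-stage row counts and a SHA-256 digest of every
output file, so a run is fully re-executable and two runs with the same
seed are byte-identical.

One master seed drives every stochastic stage through independent child
seeds derived with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, simulate
from .config import PipelineConfig
from .diffexpr import (
    classify_drgs,
    collapse_to_genes,
    differential_expression,
    filter_low_tpm,
)
from .enrich import GeneSetCollection, ora, preranked_gsea, select_top_terms
from .pathways import overlap_pathways
from .qpcr import CtCard, call_expressed, call_highly_expressed, normalize_reference, relative_quant
from .survival import scan_cutoff
from .targets import TargetPredictionSet, consensus_targets, intersect_with_down

logger = logging.getLogger(__name__)

FLOAT_FMT = io.FLOAT_FMT


@contextmanager
def _stage(name: str):
    """Re-raise any stage failure tagged with the stage name."""
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _simulate_inputs(config: PipelineConfig, indir: Path) -> dict[str, Path]:
    """Generate every pipeline input into ``indir``; returns path map."""
    seeds = _child_seeds(config.seed)
    paths = {
        "tpm": indir / "tpm.tsv",
        "groups": indir / "groups.tsv",
        "mapping": indir / "mapping.tsv",
        "ct_card_ev": indir / "ct_card_ev.csv",
        "ct_card_medium": indir / "ct_card_medium.csv",
        "targets": indir / "target_predictions.tsv",
        "gmt": indir / "genesets.gmt",
        "survival": indir / "survival.tsv",
        "truth": indir / "truth.json",
    }

    matrix, truth_expr = simulate.gen_expression_matrix(
        config.sim_n_transcripts,
        config.sim_n_per_group,
        config.sim_de_fraction,
        config.sim_effect_log2fc,
        config.sim_dispersion,
        seed=seeds[0],
        low_fraction=config.sim_low_fraction,
    )
    io.write_expression(matrix, paths["tpm"], paths["groups"])
    mapping = simulate.gen_transcript_gene_map(matrix.tpm.index.to_numpy(), seed=seeds[1])
    io.write_mapping(mapping, paths["mapping"])

    mirna_ids = [f"miR-sim-{i + 1:03d}" for i in range(config.sim_n_mirnas)]
    ev_card, md_card, truth_mirna = simulate.gen_ct_card(
        mirna_ids,
        config.sim_n_preps,
        config.sim_expressed_fraction,
        config.sim_spike_ct,
        config.sim_medium_offset_ct,
        config.sim_noise_sd,
        seed=seeds[2],
        high_fraction=config.sim_high_fraction,
    )
    ev_card.to_csv(paths["ct_card_ev"])
    md_card.to_csv(paths["ct_card_medium"])

    gene_universe = sorted(mapping["gene_symbol"].unique())
    # planted consensus targets among truly down-regulated genes
    down_true = sorted(
        mapping.loc[
            mapping["transcript_id"].isin(
                [t for t, d in truth_expr.de_direction.items() if d == "down"]
            ),
            "gene_symbol",
        ].unique()
    )
    table, truth_targets = simulate.gen_target_dbs(
        sorted(truth_mirna.true_high_mirnas),
        gene_universe,
        config.sim_per_db_density,
        config.sim_consensus_overlap,
        n_dbs=config.sim_n_dbs,
        seed=seeds[3],
    )
    table.to_csv(paths["targets"], sep="\t", index=False)

    genesets, truth_sets = simulate.gen_genesets(
        gene_universe,
        config.sim_n_genesets,
        tuple(config.sim_set_size),
        planted_list=down_true,
        n_planted_sets=config.sim_n_planted_sets if down_true else 0,
        seed=seeds[4],
    )
    genesets.to_gmt(paths["gmt"])

    cohort, truth_surv = simulate.gen_survival(
        config.sim_n_patients,
        config.sim_hazard_ratio,
        config.sim_censor_rate,
        seed=seeds[5],
    )
    io.write_survival(cohort, paths["survival"])

    _write_json(
        {
            "de_transcripts": sorted(truth_expr.de_transcripts),
            "de_direction": dict(sorted(truth_expr.de_direction.items())),
            "true_expressed_mirnas": sorted(truth_mirna.true_expressed_mirnas),
            "true_high_mirnas": sorted(truth_mirna.true_high_mirnas),
            "planted_consensus_targets": {
                m: sorted(g) for m, g in sorted(truth_targets.planted_consensus_targets.items())
            },
            "enriched_pathways": sorted(truth_sets.enriched_pathways),
            "hazard_ratio": truth_surv.hazard_ratio,
        },
        paths["truth"],
    )
    return paths


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    inputs: dict[str, str | Path] | None = None,
    simulate_inputs: bool = True,
) -> dict:
    """Run the full analysis; returns (and writes) the run manifest.

    With ``simulate_inputs`` every input is generated under
    ``outdir/inputs`` from the config's synthetic-data parameters;
    otherwise ``inputs`` must map the kinds accepted by
    :func:`mircargo.io.validate_inputs` to existing files.
    """
    outdir = Path(outdir)
    (outdir / "inputs").mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    counts: dict[str, int] = {}

    if simulate_inputs:
        paths = _simulate_inputs(config, outdir / "inputs")
    else:
        if not inputs:
            raise ValueError("either simulate_inputs=True or an inputs mapping is required")
        paths = {k: Path(v) for k, v in inputs.items()}
        missing = [str(p) for p in paths.values() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")

    # --- transcriptomics ---
    with _stage("transcriptomics"):
        matrix = io.read_expression(paths["tpm"], paths["groups"])
        counts["transcripts_input"] = matrix.n_transcripts
        filtered, removed = filter_low_tpm(
            matrix, config.tpm_threshold, config.min_low_samples, config.filter_scope
        )
        counts["transcripts_removed_by_filter"] = len(removed)
        counts["transcripts_retained"] = filtered.n_transcripts

        deg = differential_expression(filtered, config.pseudocount)
        calls = classify_drgs(deg, config.p_cut, config.lfc_cut)
        io.write_deg_table(calls.table, outdir / "deg_table.tsv")
        counts["drg_up"] = len(calls.up)
        counts["drg_down"] = len(calls.down)

        mapping = io.read_mapping(paths["mapping"])
        ranked = collapse_to_genes(deg, mapping)
        io.write_ranked(ranked, outdir / "ranked_genes.tsv")
        counts["ranked_genes"] = len(ranked)

        down_genes = sorted(
            mapping.set_index("transcript_id")["gene_symbol"].reindex(calls.down.index).dropna().unique()
        )
        io.write_gene_list(down_genes, outdir / "down_genes.txt")
        counts["down_genes"] = len(down_genes)

    # --- enrichment (RNA-seq side) ---
    with _stage("enrichment"):
        genesets = GeneSetCollection.from_gmt(paths["gmt"])
        gsea = preranked_gsea(
            ranked,
            genesets,
            n_perm=config.gsea_n_perm,
            weight=config.gsea_weight,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            seed=seeds[6],
        )
        gsea.to_csv(outdir / "gsea_results.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        top_enr, top_dep = select_top_terms(gsea, k=config.top_k, alpha=config.enrich_alpha)
        top = pd.concat([top_enr, top_dep]).reset_index(drop=True)
        top.to_csv(outdir / "gsea_top_terms.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        counts["gsea_sets_tested"] = len(gsea)

    # --- miRNA cards ---
    with _stage("mirna_cards"):
        ev_card = CtCard.from_csv(paths["ct_card_ev"], condition="ev")
        md_card = CtCard.from_csv(paths["ct_card_medium"], condition="medium")
        mirna_calls = call_highly_expressed(
            call_expressed(ev_card, md_card, config.min_delta, config.ntc_ct_floor),
            config.ct_cut,
        )
        mirna_calls.to_csv(outdir / "mirna_calls.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        counts["mirnas_expressed"] = int(mirna_calls["expressed"].sum())
        counts["mirnas_highly_expressed"] = int(mirna_calls["highly_expressed"].sum())

        rq = relative_quant(normalize_reference(ev_card), normalize_reference(md_card))
        rq.to_csv(outdir / "mirna_rq.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # --- target integration ---
    with _stage("target_integration"):
        preds = TargetPredictionSet.from_tsv(paths["targets"])
        consensus = consensus_targets(preds, config.min_db)
        table = intersect_with_down(consensus, set(down_genes)) if down_genes else None
        if table is not None:
            _write_json(
                {
                    **table.summary(),
                    "per_mirna": {m: sorted(g) for m, g in sorted(table.per_mirna.items())},
                    "multiplicity": dict(sorted(table.multiplicity.items())),
                },
                outdir / "target_consensus.json",
            )
            counts["consensus_union"] = len(table.union)

    # --- convergence ---
    with _stage("convergence"):
        universe = sorted(mapping["gene_symbol"].unique())
        mirna_side = ora(sorted(table.union) if table else [], genesets, universe)
        mirna_side.to_csv(outdir / "ora_mirna_side.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        overlap = overlap_pathways(
            gsea.rename(columns={"set_name": "pathway"})[["pathway", "p_value"]],
            mirna_side.rename(columns={"set_name": "pathway"})[["pathway", "p_value"]],
            alpha=config.alpha,
        )
        overlap.common.to_csv(outdir / "convergent_pathways.tsv", sep="\t", index=False,
                              float_format=FLOAT_FMT)
        _write_json({"alpha": config.alpha, **overlap.venn}, outdir / "venn_summary.json")
        counts["convergent_pathways"] = len(overlap.common)

    # --- survival ---
    with _stage("survival"):
        cohort = io.read_survival(paths["survival"])
        scan = scan_cutoff(cohort, min_group=config.min_group, mode=config.scan_mode)
        _write_json(scan.to_dict(), outdir / "survival_scan.json")
        counts["survival_patients"] = len(cohort)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stage_counts": counts,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest
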