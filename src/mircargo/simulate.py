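"""Synthetic inputs with known ground truth for every pipeline stage.

No raw data accompany the study conditions this package emulates, so every
input — TPM matrix, transcript-to-gene map, qPCR cards, per-database target
predictions, pathway gene sets, survival cohort — is generated with planted
effects recorded in a :class:`SimulationTruth`. The truth object is always
sufficient to recompute the expected downstream output with an independent
brute-force oracle, which is how the pipeline is tested.

All randomness flows from an explicit ``seed`` argument (anything accepted
by :func:`numpy.random.default_rng`); a fixed seed reproduces every output
bit for bit. There is no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CONTROL, TREATED, ExpressionMatrix
from .enrich import GeneSetCollection
from .qpcr import CtCard


@dataclass
class SimulationTruth:
    """Planted ground truth behind one generated dataset."""

    seed: int | None = None
    de_transcripts: frozenset[str] = frozenset()
    de_direction: dict[str, str] = field(default_factory=dict)
    true_expressed_mirnas: frozenset[str] = frozenset()
    true_high_mirnas: frozenset[str] = frozenset()
    planted_consensus_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    enriched_pathways: frozenset[str] = frozenset()
    hazard_ratio: float = 1.0


def _check_finite(**params: float) -> None:
    for name, value in params.items():
        if not math.isfinite(value):
            raise ValueError(f"parameter {name} must be finite, got {value!r}")


def gen_expression_matrix(
    n_transcripts: int,
    n_per_group: int,
    de_fraction: float,
    effect_log2fc: float,
    dispersion: float,
    seed: int,
    low_fraction: float = 0.3,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Two-group TPM matrix with planted differential expression.

    Each transcript gets a log-normal TPM baseline: its log2 mean is drawn
    uniformly from a well-expressed range, except for a ``low_fraction`` of
    transcripts drawn below the TPM=10 floor so the low-expression filter
    has something to remove. ``de_fraction`` of transcripts (placed among
    the well-expressed ones, so they survive filtering) are shifted by
    ``effect_log2fc`` in the treated group, in a random direction recorded
    in the truth. Per-sample noise is Normal(0, ``dispersion``) on the log2
    scale, so all TPM values are strictly positive.
    """
    _check_finite(
        de_fraction=de_fraction, effect_log2fc=effect_log2fc,
        dispersion=dispersion, low_fraction=low_fraction,
    )
    if n_transcripts < 1 or n_per_group < 2:
        raise ValueError("need n_transcripts >= 1 and n_per_group >= 2")
    if not 0 <= de_fraction <= 1 or not 0 <= low_fraction <= 1:
        raise ValueError("de_fraction and low_fraction must lie in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)

    ids = np.array([f"ENST{i:08d}" for i in range(n_transcripts)])
    n_low = round(low_fraction * n_transcripts)
    low_idx = rng.choice(n_transcripts, size=n_low, replace=False)
    is_low = np.zeros(n_transcripts, dtype=bool)
    is_low[low_idx] = True

    mu = np.empty(n_transcripts)
    mu[is_low] = rng.uniform(-1.0, 2.3, size=is_low.sum())  # TPM ~ 0.5 .. 5
    mu[~is_low] = rng.uniform(4.5, 11.0, size=(~is_low).sum())  # TPM ~ 23 .. 2048

    high_idx = np.flatnonzero(~is_low)
    n_de = round(de_fraction * n_transcripts)
    if n_de > len(high_idx):
        raise ValueError(
            f"cannot plant {n_de} DE transcripts among {len(high_idx)} well-expressed ones; "
            "lower de_fraction or low_fraction"
        )
    de_idx = rng.choice(high_idx, size=n_de, replace=False) if n_de else np.array([], int)
    direction = rng.choice([-1.0, 1.0], size=n_de)

    shift = np.zeros(n_transcripts)
    shift[de_idx] = direction * effect_log2fc

    samples = [f"{CONTROL}_{i + 1}" for i in range(n_per_group)] + [
        f"{TREATED}_{i + 1}" for i in range(n_per_group)
    ]
    mean_per_sample = np.concatenate(
        [np.tile(mu[:, None], n_per_group), np.tile((mu + shift)[:, None], n_per_group)],
        axis=1,
    )
    log2_tpm = mean_per_sample + rng.normal(0.0, dispersion, size=mean_per_sample.shape)
    tpm = pd.DataFrame(np.exp2(log2_tpm), index=pd.Index(ids, name="transcript_id"),
                       columns=samples)
    groups = pd.Series(
        [CONTROL] * n_per_group + [TREATED] * n_per_group, index=samples, name="group"
    )
    truth = SimulationTruth(
        seed=None if not isinstance(seed, (int, np.integer)) else int(seed),
        de_transcripts=frozenset(ids[de_idx]),
        de_direction={
            ids[i]: ("up" if d > 0 else "down") for i, d in zip(de_idx, direction)
        },
    )
    return ExpressionMatrix(tpm, groups), truth


def gen_transcript_gene_map(
    transcript_ids: list[str] | np.ndarray,
    seed: int,
    mean_transcripts_per_gene: float = 2.0,
    unmapped_fraction: float = 0.05,
) -> pd.DataFrame:
    """Random transcript-to-gene-symbol mapping table.

    A fraction of transcripts is left without a gene (dropped from the
    table, emulating IDs that fail symbol conversion); the rest are
    assigned round-robin to synthetic gene symbols so genes average
    ``mean_transcripts_per_gene`` members.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(transcript_ids)
    mapped_mask = rng.random(len(ids)) >= unmapped_fraction
    mapped = ids[mapped_mask]
    n_genes = max(1, round(len(mapped) / mean_transcripts_per_gene))
    genes = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    assigned = genes[rng.integers(0, n_genes, size=len(mapped))]
    return (
        pd.DataFrame({"transcript_id": mapped, "gene_symbol": assigned})
        .sort_values("transcript_id", kind="mergesort")
        .reset_index(drop=True)
    )


def gen_ct_card(
    mirna_ids: list[str],
    n_preps: int,
    expressed_fraction: float,
    spike_ct: float,
    medium_offset_ct: float,
    noise_sd: float,
    seed: int,
    high_fraction: float = 0.5,
    medium_spike_ct: float | None = None,
    spike_id: str = "spike-in",
) -> tuple[CtCard, CtCard, SimulationTruth]:
    """EV and medium qPCR cards with planted expressed/high-abundance miRNAs.

    Expressed miRNAs get EV Ct ~ Normal(mu, ``noise_sd``) in every
    preparation, with mu in a clearly detectable range (below the 27.5
    high-abundance cutoff for a ``high_fraction`` of them, above it for the
    rest), a clean NTC, and a medium background that is either a non-detect
    or sits ``medium_offset_ct`` cycles above the EV level. Non-expressed
    miRNAs are split between EV non-detects and detected targets whose
    medium separation stays below 4 cycles (with an occasional dirty NTC).
    The spike-in row appears on both cards in every preparation.
    """
    if not mirna_ids:
        raise ValueError("mirna_ids must be non-empty")
    if n_preps < 1:
        raise ValueError("n_preps must be >= 1")
    if not 0 < expressed_fraction <= 1:
        raise ValueError("expressed_fraction must lie in (0, 1]")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    _check_finite(spike_ct=spike_ct, medium_offset_ct=medium_offset_ct, noise_sd=noise_sd)
    rng = np.random.default_rng(seed)
    mirna_ids = [str(m) for m in mirna_ids]
    if spike_id in mirna_ids:
        raise ValueError(f"spike-in ID {spike_id!r} collides with a panel miRNA")

    n = len(mirna_ids)
    n_expr = round(expressed_fraction * n)
    expressed = list(rng.choice(mirna_ids, size=n_expr, replace=False))
    n_high = round(high_fraction * n_expr)
    high = set(expressed[:n_high])

    preps = [f"prep_{i + 1}" for i in range(n_preps)]
    med_spike = spike_ct if medium_spike_ct is None else medium_spike_ct
    ev_rows: list[dict] = []
    md_rows: list[dict] = []

    def add(rows, target, prep, ct, ntc=False, spike=False):
        rows.append({"target_id": target, "prep_id": prep, "ct": ct,
                     "is_ntc": ntc, "is_spike_in": spike})

    for prep in preps:
        add(ev_rows, spike_id, prep, rng.normal(spike_ct, 0.05), spike=True)
        add(md_rows, spike_id, prep, rng.normal(med_spike, 0.05), spike=True)
    add(ev_rows, spike_id, "NTC", np.nan, ntc=True, spike=True)

    for m in mirna_ids:
        if m in expressed:
            mu = rng.uniform(21.5, 26.5) if m in high else rng.uniform(28.5, 33.0)
            ev_ct = rng.normal(mu, noise_sd, size=n_preps)
            # medium: mostly non-detect, otherwise far above the EV level
            if rng.random() < 0.3 and mu + medium_offset_ct + 1 < 40:
                md_ct = np.clip(rng.normal(mu + medium_offset_ct, noise_sd, n_preps), None, 40.0)
            else:
                md_ct = np.full(n_preps, np.nan)
            ntc_ct = np.nan
        else:
            kind = rng.random()
            if kind < 0.5:  # absent from EVs entirely
                ev_ct = np.full(n_preps, np.nan)
                md_ct = np.full(n_preps, np.nan)
                ntc_ct = np.nan
            else:  # detected but indistinguishable from medium background
                mu = rng.uniform(24.0, 30.0)
                ev_ct = rng.normal(mu, noise_sd, size=n_preps)
                md_ct = ev_ct + rng.uniform(-1.0, 2.5, size=n_preps)
                ntc_ct = rng.uniform(28.0, 33.0) if kind > 0.9 else np.nan
        for prep, e, d in zip(preps, ev_ct, md_ct):
            add(ev_rows, m, prep, e)
            add(md_rows, m, prep, d)
        add(ev_rows, m, "NTC", ntc_ct, ntc=True)

    ev_card = CtCard(pd.DataFrame(ev_rows), condition="ev")
    md_card = CtCard(pd.DataFrame(md_rows), condition="medium")
    truth = SimulationTruth(
        seed=int(seed),
        true_expressed_mirnas=frozenset(expressed),
        true_high_mirnas=frozenset(high),
    )
    return ev_card, md_card, truth


def gen_target_dbs(
    mirna_ids: list[str],
    gene_universe: list[str],
    per_db_density: float,
    consensus_overlap: float,
    n_dbs: int = 3,
    seed: int = 0,
) -> tuple["pd.DataFrame", SimulationTruth]:
    """Per-database miRNA-target prediction tables with a planted consensus.

    Each database predicts roughly ``per_db_density * |universe|`` genes
    per miRNA. A ``consensus_overlap`` fraction of that budget is planted
    into at least two databases — these pairs form the truth consensus —
    while all remaining predictions are drawn from database-exclusive gene
    pools, so they can never coincide across databases. Consequently the
    two-of-n consensus over the generated tables equals the planted pairs
    exactly, for any overlap value.

    Returns a long table (mirna_id, db_name, gene_symbol) plus the truth.
    """
    if not gene_universe:
        raise ValueError("gene_universe must be non-empty")
    if n_dbs < 2:
        raise ValueError("need at least 2 databases")
    if not 0 <= consensus_overlap <= 1:
        raise ValueError("consensus_overlap must lie in [0, 1]")
    if per_db_density < 0:
        raise ValueError("per_db_density must be >= 0")
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(set(map(str, gene_universe))))
    dbs = [f"db{i + 1}" for i in range(n_dbs)]

    m_per_db = round(per_db_density * len(universe))
    n_plant = round(consensus_overlap * m_per_db)
    rows: list[dict] = []
    planted_truth: dict[str, frozenset[str]] = {}

    for mirna in map(str, mirna_ids):
        planted = (
            rng.choice(universe, size=min(n_plant, len(universe)), replace=False)
            if n_plant else np.array([], dtype=universe.dtype)
        )
        planted_truth[mirna] = frozenset(planted)
        per_db_planted: dict[str, set[str]] = {db: set() for db in dbs}
        for gene in planted:
            k = int(rng.integers(2, n_dbs + 1))
            for db in rng.choice(dbs, size=k, replace=False):
                per_db_planted[db].add(str(gene))
        remaining = np.setdiff1d(universe, planted, assume_unique=False)
        rng.shuffle(remaining)
        pools = np.array_split(remaining, n_dbs)
        for db, pool in zip(dbs, pools):
            want = max(0, m_per_db - len(per_db_planted[db]))
            private = pool[: min(want, len(pool))]
            genes = per_db_planted[db] | set(map(str, private))
            for g in sorted(genes):
                rows.append({"mirna_id": mirna, "db_name": db, "gene_symbol": g})

    table = pd.DataFrame(rows, columns=["mirna_id", "db_name", "gene_symbol"])
    truth = SimulationTruth(seed=int(seed), planted_consensus_targets=planted_truth)
    return table, truth


def gen_genesets(
    gene_universe: list[str],
    n_sets: int,
    size_range: tuple[int, int],
    planted_list: list[str] | None = None,
    n_planted_sets: int = 0,
    seed: int = 0,
    planted_frac: float = 0.8,
) -> tuple[GeneSetCollection, SimulationTruth]:
    """Random pathway gene sets, optionally enriched for a planted gene list.

    The first ``n_planted_sets`` sets draw ``planted_frac`` of their
    members from ``planted_list`` (for enrichment power tests); the rest
    are uniform over the universe. Set sizes are uniform over
    ``size_range`` (inclusive).
    """
    universe = sorted(set(map(str, gene_universe)))
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError(f"size_range {size_range} must satisfy 1 <= lo <= hi <= |universe|")
    planted_list = [str(g) for g in (planted_list or [])]
    stray = sorted(set(planted_list) - set(universe))
    if stray:
        raise ValueError(f"planted genes outside the universe: {stray[:10]}")
    if n_planted_sets > 0 and not planted_list:
        raise ValueError("n_planted_sets > 0 requires a non-empty planted_list")
    rng = np.random.default_rng(seed)
    universe_arr = np.array(universe)
    planted_arr = np.array(sorted(set(planted_list)))

    sets: dict[str, frozenset[str]] = {}
    for i in range(n_sets):
        name = f"PW{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted_sets:
            k_pl = min(round(planted_frac * size), len(planted_arr))
            members = set(rng.choice(planted_arr, size=k_pl, replace=False))
            rest_pool = np.array(sorted(set(universe) - members))
            extra = rng.choice(rest_pool, size=size - len(members), replace=False)
            members |= set(map(str, extra))
        else:
            members = set(map(str, rng.choice(universe_arr, size=size, replace=False)))
        sets[name] = frozenset(members)
    truth = SimulationTruth(
        seed=int(seed),
        enriched_pathways=frozenset(f"PW{i + 1:04d}" for i in range(n_planted_sets)),
    )
    return GeneSetCollection(sets, {n: "synthetic pathway" for n in sets}), truth


def gen_survival(
    n_patients: int,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    baseline_hazard: float = 1.0 / 60.0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Survival cohort where above-median expression scales the event hazard.

    Expression is standard normal; event times are exponential with rate
    ``baseline_hazard`` (per month; default median survival ~42 months)
    multiplied by ``hazard_ratio`` for patients above the median. Each
    record is independently censored with probability ``censor_rate`` at a
    uniform fraction of its event time.
    """
    if n_patients < 16:
        raise ValueError("need n_patients >= 16 (two groups of >= 8)")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    expression = rng.normal(0.0, 1.0, size=n_patients)
    high = expression > np.median(expression)
    rate = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n_patients) < censor_rate
    time = np.where(censored, t_event * rng.random(n_patients), t_event)
    time = np.maximum(time, 1e-9)
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
            "expression": expression,
            "time": time,
            "event": (~censored).astype(int),
        }
    )
    truth = SimulationTruth(seed=int(seed), hazard_ratio=float(hazard_ratio))
    return cohort, truth
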