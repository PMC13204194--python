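"""Pathway-convergence analysis: terms significant on both evidence sides.

Given pathway-level p-values from the transcriptome enrichment (RNA-seq
side) and from the miRNA-target over-representation (miRNA side), the
overlap — terms with p < alpha in *both* analyses — identifies pathways
most plausibly driven by the EV miRNA cargo. Matching is exact after name
normalisation (case-fold, whitespace collapse); fuzzy matching of pathway
labels is deliberately avoided as a source of silent errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

logger = logging.getLogger(__name__)


def normalize_pathway_name(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def _as_frame(results: pd.DataFrame | Iterable[tuple[str, float]], side: str) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results.rename(columns={"set_name": "pathway"})[["pathway", "p_value"]].copy()
    else:
        df = pd.DataFrame(list(results), columns=["pathway", "p_value"])
    df["pathway"] = df["pathway"].astype(str)
    df["key"] = df["pathway"].map(normalize_pathway_name)
    dupes = df.loc[df["key"].duplicated(), "pathway"].tolist()
    if dupes:
        raise ValueError(f"duplicate pathway names on the {side} side: {dupes[:10]}")
    return df


@dataclass
class PathwayOverlap:
    """Overlap of significant pathways between the two evidence sides.

    ``common`` is a DataFrame (pathway, p_mirna, p_rnaseq) sorted by
    ascending RNA-seq p-value; ``venn`` holds the three Venn counts.
    """

    rnaseq_significant: frozenset[str]
    mirna_significant: frozenset[str]
    common: pd.DataFrame
    alpha: float

    @property
    def venn(self) -> dict[str, int]:
        n_common = len(self.common)
        return {
            "rnaseq_only": len(self.rnaseq_significant) - n_common,
            "mirna_only": len(self.mirna_significant) - n_common,
            "common": n_common,
        }


def overlap_pathways(
    rnaseq_results: pd.DataFrame | Iterable[tuple[str, float]],
    mirna_results: pd.DataFrame | Iterable[tuple[str, float]],
    alpha: float = 0.05,
) -> PathwayOverlap:
    """Pathways with p < ``alpha`` in both result lists.

    Input rows are (pathway, p_value) pairs (or DataFrames with those
    columns; ``set_name`` is accepted as an alias). The RNA-seq side's
    original spelling is reported for common entries.
    """
    rna = _as_frame(rnaseq_results, "RNA-seq")
    mir = _as_frame(mirna_results, "miRNA")
    rna_sig = rna[rna["p_value"] < alpha]
    mir_sig = mir[mir["p_value"] < alpha]
    merged = rna_sig.merge(mir_sig, on="key", suffixes=("_rnaseq", "_mirna"))
    unmatched = set(rna_sig["key"]) ^ set(mir_sig["key"])
    if unmatched:
        logger.info("pathway names significant on one side only: %d", len(unmatched))
    common = (
        merged.rename(
            columns={
                "pathway_rnaseq": "pathway",
                "p_value_mirna": "p_mirna",
                "p_value_rnaseq": "p_rnaseq",
            }
        )[["pathway", "p_mirna", "p_rnaseq"]]
        .sort_values(["p_rnaseq", "pathway"], kind="mergesort")
        .reset_index(drop=True)
    )
    return PathwayOverlap(
        rnaseq_significant=frozenset(rna_sig["pathway"]),
        mirna_significant=frozenset(mir_sig["pathway"]),
        common=common,
        alpha=alpha,
    )
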