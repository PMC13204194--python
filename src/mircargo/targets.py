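"""Consensus miRNA-target integration across prediction databases.

Individual target-prediction databases disagree wildly, so a prediction is
kept only when at least ``min_db`` databases agree on the (miRNA, gene)
pair. Consensus sets are then intersected with an experimentally
down-regulated gene list and summarised: the union of putative targets, its
fraction of the down-regulated list, and per-gene multiplicity (how many
distinct mature miRNAs converge on the gene).

A prediction row may name a combined miRNA family (e.g.
``miR-365a-3p/miR-365b-3p``): it is treated as a single row for consensus
but expands to its mature members for multiplicity counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd


@dataclass
class TargetPredictionSet:
    """Per-(miRNA, database) predicted gene sets.

    ``predictions`` maps miRNA ID -> database name -> gene set; a database
    with no prediction for a miRNA simply lacks the inner key (equivalent
    to the empty set — a database may legitimately return nothing).
    """

    predictions: dict[str, dict[str, frozenset[str]]]
    db_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.db_names)) != len(self.db_names):
            raise ValueError("database names must be unique")
        if len(self.db_names) < 2:
            raise ValueError("at least two prediction databases are required")
        unknown = {
            db for per_db in self.predictions.values() for db in per_db
        } - set(self.db_names)
        if unknown:
            raise ValueError(f"predictions reference unknown databases: {sorted(unknown)}")

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.predictions)

    def genes(self, mirna: str, db: str) -> frozenset[str]:
        return self.predictions.get(mirna, {}).get(db, frozenset())

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, db_names: tuple[str, ...] | None = None
    ) -> "TargetPredictionSet":
        """Build from a long table with columns mirna_id, db_name, gene_symbol."""
        preds: dict[str, dict[str, frozenset[str]]] = {}
        grouped = df.groupby(["mirna_id", "db_name"])["gene_symbol"]
        for (mirna, db), genes in grouped:
            preds.setdefault(str(mirna), {})[str(db)] = frozenset(
                g.strip() for g in genes.astype(str) if g.strip()
            )
        dbs = db_names or tuple(sorted(df["db_name"].astype(str).unique()))
        return cls(preds, tuple(dbs))

    @classmethod
    def from_tsv(cls, path: str | Path, db_names: tuple[str, ...] | None = None):
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str), db_names)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"mirna_id": m, "db_name": db, "gene_symbol": g}
            for m in sorted(self.predictions)
            for db in self.db_names
            for g in sorted(self.genes(m, db))
        ]
        pd.DataFrame(rows, columns=["mirna_id", "db_name", "gene_symbol"]).to_csv(
            path, sep="\t", index=False
        )


def expand_mirna_id(mirna_id: str) -> tuple[str, ...]:
    """Split a combined family row into mature miRNA IDs (on ``/``)."""
    return tuple(part.strip() for part in mirna_id.split("/") if part.strip())


def consensus_targets(
    preds: TargetPredictionSet, min_db: int = 2
) -> dict[str, frozenset[str]]:
    """Genes predicted by at least ``min_db`` databases, per miRNA."""
    if min_db < 1:
        raise ValueError("min_db must be >= 1")
    if min_db > len(preds.db_names):
        raise ValueError(
            f"min_db={min_db} exceeds the {len(preds.db_names)} available databases"
        )
    out: dict[str, frozenset[str]] = {}
    for mirna in preds.mirna_ids:
        counts: Counter[str] = Counter()
        for db in preds.db_names:
            counts.update(preds.genes(mirna, db))
        out[mirna] = frozenset(g for g, c in counts.items() if c >= min_db)
    return out


def target_multiplicity(per_mirna: Mapping[str, frozenset[str]]) -> dict[str, int]:
    """Distinct mature miRNAs converging on each gene.

    Combined family rows contribute one count per mature member, so a gene
    hit by a two-miRNA row plus a single row has multiplicity 3.
    """
    mult: Counter[str] = Counter()
    for mirna, genes in per_mirna.items():
        n_mature = len(expand_mirna_id(mirna))
        for g in genes:
            mult[g] += n_mature
    return dict(mult)


@dataclass
class ConsensusTable:
    """Consensus targets restricted to a down-regulated gene list."""

    per_mirna: dict[str, frozenset[str]]
    union: frozenset[str]
    fraction_of_down: float
    multiplicity: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict:
        hist: Counter[int] = Counter(self.multiplicity.values())
        return {
            "n_mirnas": len(self.per_mirna),
            "union_size": len(self.union),
            "fraction_of_down": round(self.fraction_of_down, 3),
            "multiplicity_histogram": {str(k): hist[k] for k in sorted(hist)},
        }


def intersect_with_down(
    consensus: Mapping[str, frozenset[str]], down_genes: set[str]
) -> ConsensusTable:
    """Restrict consensus sets to the down-regulated list and summarise.

    ``fraction_of_down = |union| / |down_genes|``. Gene symbols are compared
    case-sensitively after whitespace trimming; the two inputs must share a
    symbol namespace.
    """
    down = {g.strip() for g in down_genes if g and g.strip()}
    if not down:
        raise ValueError("down-regulated gene list is empty")
    per_mirna = {m: frozenset(genes) & down for m, genes in consensus.items()}
    union = frozenset().union(*per_mirna.values()) if per_mirna else frozenset()
    return ConsensusTable(
        per_mirna=per_mirna,
        union=union,
        fraction_of_down=len(union) / len(down),
        multiplicity=target_multiplicity(per_mirna),
    )
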