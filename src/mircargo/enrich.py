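"""Gene-set enrichment on a pre-ranked list, and hypergeometric over-representation.

Two complementary engines:

* :func:`preranked_gsea` — weighted Kolmogorov-Smirnov-like running-sum
  enrichment score (ES) over a gene list ranked by score (here: average
  log2 fold change), with a gene-label permutation null, sign-matched NES
  normalisation and add-one-smoothed permutation p-values.
* :func:`ora` — upper-tail hypergeometric test of a gene list against each
  set within a stated universe.

Both are deterministic given a seed and emit BH-adjusted p-values for
information only (selection uses raw p, mirroring the upstream analysis
this package re-implements).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member sets."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        descriptions: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (needs >=3 fields): {line[:80]!r}")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            descriptions[name] = desc
        return cls(sets, descriptions)

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for name in self.names():
            desc = self.descriptions.get(name, "na")
            lines.append("\t".join([name, desc, *sorted(self.sets[name])]))
        Path(path).write_text("\n".join(lines) + "\n")


def _running_sum_es(
    hit_pos: np.ndarray, abs_weights: np.ndarray, n_genes: int
) -> np.ndarray:
    """ES for one or many hit-position sets.

    ``hit_pos``: (..., k) sorted 0-based positions of set members in the
    ranked list. ``abs_weights``: per-gene |score|^weight over the whole
    list. The running sum increments by the normalised hit weight at each
    member and decrements by 1/(N-k) at each non-member; the ES is the
    maximal deviation from zero (positive deviations peak just after a hit,
    negative ones just before). Ties in magnitude resolve to the positive
    deviation.
    """
    hit_pos = np.atleast_2d(hit_pos)
    k = hit_pos.shape[-1]
    w = abs_weights[hit_pos]
    total = w.sum(axis=-1, keepdims=True)
    uniform = total == 0  # all-zero scores: fall back to equal hit increments
    with np.errstate(invalid="ignore", divide="ignore"):
        cum = np.cumsum(w, axis=-1) / total
    cum = np.where(uniform, np.arange(1, k + 1) / k, cum)
    miss_step = 1.0 / (n_genes - k)
    j = np.arange(1, k + 1)
    after = cum - (hit_pos + 1 - j) * miss_step
    before = np.concatenate(
        [np.zeros((*hit_pos.shape[:-1], 1)), cum[..., :-1]], axis=-1
    ) - (hit_pos - (j - 1)) * miss_step
    es_pos = np.maximum(after.max(axis=-1), 0.0)
    es_neg = np.minimum(before.min(axis=-1), 0.0)
    # magnitude ties (possible with rational steps at weight 0) resolve to the
    # positive deviation; the tolerance absorbs floating-point asymmetry
    return np.where(es_pos >= -es_neg - 1e-12, es_pos, es_neg)


def preranked_gsea(
    ranked: pd.DataFrame,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a (gene, score) table.

    The null distribution comes from ``n_perm`` random gene-label
    permutations (equivalently: random position sets of matching size),
    the only null consistent with a pre-ranked input. ``NES = ES /
    mean(|null ES| of matching sign)`` and ``p`` is the add-one-smoothed
    fraction of matching-sign null ES at least as extreme, so
    ``p >= 1/(n_perm+1)``.

    Sets are first intersected with the ranked genes and kept only if the
    overlap size lies in ``[min_size, max_size]``; skipped sets are logged.
    Returns a DataFrame with columns ``set_name, size, es, nes, p_value,
    p_adj, direction`` sorted by set name.
    """
    ranked = ranked.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    genes = ranked["gene"].to_numpy()
    if len(genes) == 0:
        raise ValueError("ranked list is empty")
    if len(set(genes)) != len(genes):
        raise ValueError("ranked list contains duplicate gene symbols")
    scores = ranked["score"].to_numpy(dtype=float)
    abs_w = np.abs(scores) ** weight if weight != 0 else np.ones_like(scores)
    n_genes = len(genes)
    pos_of = {g: i for i, g in enumerate(genes)}

    rng = np.random.default_rng(seed)
    # one shared pool of permutations; a set of size k uses the first k slots
    perms = np.tile(np.arange(n_genes, dtype=np.int64), (n_perm, 1))
    perms = rng.permuted(perms, axis=1)

    rows = []
    for name in sets.names():
        members = sets[name]
        hit = np.array(sorted(pos_of[g] for g in members if g in pos_of))
        k = len(hit)
        if k == 0:
            logger.info("GSEA: set %r has no overlap with the ranked list; skipped", name)
            continue
        if not (min_size <= k <= max_size):
            logger.info("GSEA: set %r overlap size %d outside [%d, %d]; skipped",
                        name, k, min_size, max_size)
            continue
        if k >= n_genes:
            logger.info("GSEA: set %r covers the whole list; skipped", name)
            continue
        es = float(_running_sum_es(hit, abs_w, n_genes)[0])
        null_pos = np.sort(perms[:, :k], axis=1)
        null_es = _running_sum_es(null_pos, abs_w, n_genes)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        p = (1 + int((np.abs(null_es[same_sign]) >= abs(es)).sum())) / (1 + n_same)
        denom = np.abs(null_es[same_sign]).mean() if n_same else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else 0.0
        rows.append(
            {
                "set_name": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p_value": p,
                "direction": "enriched" if es > 0 else "depleted",
            }
        )
    out = pd.DataFrame(
        rows, columns=["set_name", "size", "es", "nes", "p_value", "direction"]
    )
    if not out.empty:
        out.insert(5, "p_adj", stats.false_discovery_control(out["p_value"], method="bh"))
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out.reset_index(drop=True)


def select_top_terms(
    results: pd.DataFrame, k: int = 10, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k enriched and depleted terms among those with ``p < alpha``.

    Enriched terms are sorted by descending NES, depleted by ascending NES;
    each list is truncated to ``k`` rows.
    """
    sig = results[results["p_value"] < alpha]
    enriched = (
        sig[sig["direction"] == "enriched"]
        .sort_values(["nes", "set_name"], ascending=[False, True], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
    )
    depleted = (
        sig[sig["direction"] == "depleted"]
        .sort_values(["nes", "set_name"], ascending=[True, True], kind="mergesort")
        .head(k)
        .reset_index(drop=True)
    )
    return enriched, depleted


def ora(
    gene_list: Iterable[str],
    sets: GeneSetCollection | Mapping[str, frozenset[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    ``p = P(overlap >= observed)`` when drawing ``|gene_list|`` genes
    without replacement from ``|universe|`` of which ``|set & universe|``
    are successes. The gene list must be a subset of the universe.
    """
    gene_list = set(gene_list)
    universe = set(universe)
    offending = sorted(gene_list - universe)
    if offending:
        raise ValueError(f"gene list members outside the universe: {offending[:10]}")
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else dict(sets)
    m_univ = len(universe)
    n_draw = len(gene_list)
    rows = []
    for name in sorted(mapping):
        in_univ = frozenset(mapping[name]) & universe
        k_succ = len(in_univ)
        overlap = len(in_univ & gene_list)
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, k_succ, n_draw))
        rows.append(
            {"set_name": name, "overlap": overlap, "set_size": k_succ,
             "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p_value"])
    if not out.empty:
        out["p_adj"] = stats.false_discovery_control(out["p_value"], method="bh")
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out
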