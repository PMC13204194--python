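"""Transcript-level differential expression between control and EV-treated groups.

The workflow mirrors a small-n (3 vs 3) bulk RNA-seq comparison that starts
from a TPM matrix rather than raw counts: transcripts consistently below a
TPM floor are removed, a Welch two-sample t-test on log2(TPM + 1) provides
per-transcript p-values, genes are called up/down-regulated by strict
fold-change and p-value cutoffs, and transcript scores are collapsed to a
gene-level ranked list for downstream enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
GROUPS = (CONTROL, TREATED)


@dataclass
class ExpressionMatrix:
    """TPM expression matrix (transcripts x samples) with a two-group design.

    Parameters
    ----------
    tpm : pandas.DataFrame
        Non-negative TPM values, indexed by transcript ID with one column per
        sample. Transcript IDs must be unique.
    groups : pandas.Series
        Maps every sample ID (index) to ``"control"`` or ``"treated"``.
    """

    tpm: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.tpm.index.has_duplicates:
            dupes = self.tpm.index[self.tpm.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript IDs: {dupes[:5]}")
        vals = self.tpm.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("TPM matrix contains non-finite values")
        if (vals < 0).any():
            raise ValueError("TPM values must be >= 0")
        self.groups = self.groups.reindex(self.tpm.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples without a group assignment: {missing}")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def n_transcripts(self) -> int:
        return self.tpm.shape[0]


class FilterResult(NamedTuple):
    matrix: ExpressionMatrix
    removed: pd.Index


def filter_low_tpm(
    matrix: ExpressionMatrix,
    threshold: float = 10.0,
    min_low_samples: int = 2,
    scope: Literal["either_group", "both_groups"] = "either_group",
) -> FilterResult:
    """Remove transcripts that sit below a TPM floor in too many samples.

    A transcript is excluded when, within a group, at least
    ``min_low_samples`` samples have TPM strictly below ``threshold``.
    With ``scope="either_group"`` one offending group suffices (the stricter
    reading of "in either one or both groups"); with ``scope="both_groups"``
    every group must offend.

    Returns the filtered matrix together with the index of removed
    transcripts; sample order is preserved. The operation is idempotent.
    """
    if scope not in ("either_group", "both_groups"):
        raise ValueError(f"unknown scope {scope!r}")
    per_group_low = []
    for group in GROUPS:
        cols = matrix.samples_in(group)
        if len(cols) < min_low_samples:
            raise ValueError(
                f"group {group!r} has {len(cols)} samples, fewer than "
                f"min_low_samples={min_low_samples}"
            )
        low_counts = (matrix.tpm[cols] < threshold).sum(axis=1)
        per_group_low.append(low_counts >= min_low_samples)
    flagged = pd.concat(per_group_low, axis=1)
    remove = flagged.any(axis=1) if scope == "either_group" else flagged.all(axis=1)
    removed = matrix.tpm.index[remove]
    kept = ExpressionMatrix(matrix.tpm.loc[~remove].copy(), matrix.groups.copy())
    logger.info(
        "low-TPM filter removed %d of %d transcripts (threshold=%g, "
        "min_low_samples=%d, scope=%s)",
        len(removed), matrix.n_transcripts, threshold, min_low_samples, scope,
    )
    return FilterResult(kept, removed)


def differential_expression(
    matrix: ExpressionMatrix, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-transcript two-group differential expression.

    Fold change is ``(mean treated TPM + pc) / (mean control TPM + pc)``;
    the p-value comes from a two-sided Welch t-test on ``log2(TPM + pc)``.
    Transcripts with zero variance in both groups get ``p = 1`` by
    convention rather than raising. A Benjamini-Hochberg adjusted column is
    included for information (calling uses raw p).

    Returns a DataFrame indexed by transcript ID with columns
    ``fold_change``, ``log_fc``, ``p_value``, ``p_adj``.
    """
    if pseudocount <= 0 or not np.isfinite(pseudocount):
        raise ValueError("pseudocount must be a positive finite number")
    ctrl_cols = matrix.samples_in(CONTROL)
    trt_cols = matrix.samples_in(TREATED)
    if len(ctrl_cols) < 2 or len(trt_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    ctrl = matrix.tpm[ctrl_cols].to_numpy(dtype=float)
    trt = matrix.tpm[trt_cols].to_numpy(dtype=float)

    fold_change = (trt.mean(axis=1) + pseudocount) / (ctrl.mean(axis=1) + pseudocount)
    log_fc = np.log2(fold_change)

    log_ctrl = np.log2(ctrl + pseudocount)
    log_trt = np.log2(trt + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
        p_value = np.asarray(res.pvalue, dtype=float)
    # Zero variance in both groups: the location test is undefined; report 1.
    degenerate = (log_ctrl.var(axis=1) == 0) & (log_trt.var(axis=1) == 0)
    p_value[degenerate] = 1.0
    p_value = np.clip(np.nan_to_num(p_value, nan=1.0), 0.0, 1.0)

    out = pd.DataFrame(
        {
            "fold_change": fold_change,
            "log_fc": log_fc,
            "p_value": p_value,
            "p_adj": stats.false_discovery_control(p_value, method="bh"),
        },
        index=matrix.tpm.index.copy(),
    )
    out.index.name = "transcript_id"
    return out


class DrgCalls(NamedTuple):
    table: pd.DataFrame  # input table plus a "call" column
    up: pd.DataFrame  # sorted by ascending p
    down: pd.DataFrame  # sorted by ascending p


def classify_drgs(
    records: pd.DataFrame, p_cut: float = 0.01, lfc_cut: float = 0.5
) -> DrgCalls:
    """Partition transcripts into up / down / ns by strict cutoffs.

    ``up`` requires ``log_fc > lfc_cut`` and ``p_value < p_cut``; ``down``
    requires ``log_fc < -lfc_cut`` and ``p_value < p_cut``. Both
    inequalities are strict, so boundary records (e.g. log_fc exactly
    -0.5) stay ``ns``.
    """
    if records.empty:
        raise ValueError("no records to classify")
    table = records.copy()
    sig = table["p_value"] < p_cut
    call = np.where(
        sig & (table["log_fc"] > lfc_cut),
        "up",
        np.where(sig & (table["log_fc"] < -lfc_cut), "down", "ns"),
    )
    table["call"] = call
    up = table[table["call"] == "up"].sort_values(["p_value", "log_fc"]).copy()
    down = table[table["call"] == "down"].sort_values(["p_value", "log_fc"]).copy()
    logger.info(
        "DRG calling: %d up, %d down, %d ns (p<%g, |logFC|>%g)",
        len(up), len(down), len(table) - len(up) - len(down), p_cut, lfc_cut,
    )
    return DrgCalls(table, up, down)


def collapse_to_genes(
    records: pd.DataFrame, mapping: pd.DataFrame | Mapping[str, str]
) -> pd.DataFrame:
    """Average transcript log-fold-changes into a gene-level ranked list.

    Transcripts without a gene mapping are dropped; the per-gene score is
    the arithmetic mean of its member transcripts' ``log_fc``. The output
    (columns ``gene``, ``score``) is sorted by descending score with ties
    broken lexicographically by gene symbol so the ranking is deterministic.
    """
    if isinstance(mapping, pd.DataFrame):
        gene_of = mapping.set_index("transcript_id")["gene_symbol"]
    else:
        gene_of = pd.Series(dict(mapping))
    genes = records.index.map(gene_of)
    keep = genes.notna()
    if not keep.any():
        raise ValueError("no transcript in the records is covered by the mapping")
    scores = (
        records.loc[keep, "log_fc"]
        .groupby(genes[keep])
        .mean()
        .rename("score")
        .rename_axis("gene")
        .reset_index()
    )
    scores = scores.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return scores
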