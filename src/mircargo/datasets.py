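"""Published worked-example datasets shipped with the package.

These small plain-text tables come from a published profiling of
osteoblast-derived extracellular vesicles and the osteosarcoma cells they
were applied to: the top down-/up-regulated transcripts with fold changes
and p-values, the mean Ct summary of the highly expressed EV miRNAs (with
the ath-miR159a spike-in), the three-database miRNA-target prediction
table restricted to the down-regulated genes (together with the published
at-least-two-databases consensus column), and the pathway terms significant
in both the transcriptome enrichment and the miRNA-target analysis. They
exercise every analytical rule in this package on real printed numbers.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .targets import TargetPredictionSet

DB_NAMES = ("targetscan", "diana", "mirdb")


def _path(name: str):
    return resources.files("mircargo") / "data" / name


def load_top_regulated() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(down, up) tables of the top regulated transcripts.

    Columns: ``gene_symbol``, ``entrez_id``, ``fold_change`` (treated /
    control ratio; < 1 means down-regulated), ``p_value``. A ``log_fc``
    column (log2 of the fold change) is added on load.
    """
    frames = []
    for name in ("ev_top_downregulated.tsv", "ev_top_upregulated.tsv"):
        df = pd.read_csv(_path(name), sep="\t")
        df["log_fc"] = np.log2(df["fold_change"])
        frames.append(df)
    return frames[0], frames[1]


def load_mirna_ct_means() -> pd.DataFrame:
    """Mean/SE Ct summary of EV-expressed miRNAs plus the spike-in row.

    Columns: ``target_id``, ``ev_ct_mean``, ``ev_ct_se``,
    ``medium_ct_mean``, ``medium_ct_se`` (NaN = non-detect in medium),
    ``is_spike_in``.
    """
    df = pd.read_csv(_path("ev_mirna_ct_means.csv"))
    for col in ("ev_ct_mean", "ev_ct_se", "medium_ct_mean", "medium_ct_se"):
        df[col] = pd.to_numeric(df[col].replace("Undetermined", np.nan))
    df["is_spike_in"] = df["is_spike_in"].astype(bool)
    return df


def load_mirna_call_table() -> pd.DataFrame:
    """Mean-mode expression-call table built from the published Ct summary.

    The published rows are the miRNAs already called expressed in every EV
    preparation, so ``expressed`` is True throughout; only means are
    available (no per-preparation replicates), which puts
    :func:`mircargo.qpcr.call_highly_expressed` into mean mode. The
    spike-in row is excluded (reference rows are exempt from calling).
    """
    df = load_mirna_ct_means()
    df = df[~df["is_spike_in"]].reset_index(drop=True)
    return pd.DataFrame(
        {
            "target_id": df["target_id"],
            "mean_ct_ev": df["ev_ct_mean"],
            "se_ct_ev": df["ev_ct_se"],
            "mean_ct_medium": df["medium_ct_mean"],
            "expressed": True,
        }
    )


def load_target_predictions() -> TargetPredictionSet:
    """Three-database miRNA-target predictions among down-regulated genes."""
    with resources.as_file(_path("ev_mirna_target_predictions.tsv")) as p:
        return TargetPredictionSet.from_tsv(p, DB_NAMES)


def load_expected_consensus() -> dict[str, frozenset[str]]:
    """Published at-least-two-databases consensus column, per miRNA row."""
    df = pd.read_csv(_path("ev_mirna_target_consensus_expected.tsv"), sep="\t")
    return {
        str(m): frozenset(g["gene_symbol"])
        for m, g in df.groupby("mirna_id", sort=False)
    }


def load_convergent_pathways() -> pd.DataFrame:
    """Pathways significant in both the transcriptome and miRNA-target analyses.

    Columns: ``pathway``, ``p_mirna_targets``, ``p_rnaseq``.
    """
    return pd.read_csv(_path("ev_convergent_pathways.csv"))
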