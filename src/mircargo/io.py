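"""Readers, writers and schema validation for the pipeline's file formats.

All formats are plain text: TPM matrix TSV plus a group-assignment sidecar
TSV, transcript-to-gene mapping TSV, Ct card CSV (non-detects spelled
"Undetermined"), long-format target-prediction TSV, GMT gene sets, and a
survival TSV. Writers sort deterministically so repeated runs are
byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .diffexpr import GROUPS, ExpressionMatrix
from .enrich import GeneSetCollection
from .qpcr import CARD_COLUMNS, NON_DETECT, CtCard
from .survival import COHORT_COLUMNS, validate_cohort
from .targets import TargetPredictionSet

# pandas' default float formatting (shortest round-trippable repr) keeps
# writer/reader round-trips lossless and runs byte-reproducible
FLOAT_FMT = None


# --- expression -------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, tpm_path: str | Path,
                     groups_path: str | Path) -> None:
    matrix.tpm.to_csv(tpm_path, sep="\t", float_format=FLOAT_FMT)
    matrix.groups.rename("group").rename_axis("sample_id").reset_index().to_csv(
        groups_path, sep="\t", index=False
    )


def read_expression(tpm_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t").set_index("sample_id")["group"]
    return ExpressionMatrix(tpm, groups)


def write_mapping(mapping: pd.DataFrame, path: str | Path) -> None:
    mapping[["transcript_id", "gene_symbol"]].to_csv(path, sep="\t", index=False)


def read_mapping(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"transcript_id", "gene_symbol"} - set(df.columns)
    if missing:
        raise ValueError(f"mapping table missing columns: {sorted(missing)}")
    return df


def write_deg_table(deg: pd.DataFrame, path: str | Path) -> None:
    deg.sort_index().to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_ranked(ranked: pd.DataFrame, path: str | Path) -> None:
    ranked.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_ranked(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"ranked list missing columns: {sorted(missing)}")
    return df


# --- targets / gene lists ---------------------------------------------------

def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines ignored."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_targets(path: str | Path, db_names: tuple[str, ...] | None = None) -> TargetPredictionSet:
    return TargetPredictionSet.from_tsv(path, db_names)


# --- survival ---------------------------------------------------------------

def write_survival(cohort: pd.DataFrame, path: str | Path) -> None:
    cols = ["patient_id", *COHORT_COLUMNS] if "patient_id" in cohort.columns else COHORT_COLUMNS
    cohort[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_survival(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, sep="\t"))


# --- validation -------------------------------------------------------------

def _violations_tpm(tpm_path: Path, groups_path: Path | None) -> list[str]:
    out = []
    tpm = pd.read_csv(tpm_path, sep="\t", index_col=0)
    if tpm.index.has_duplicates:
        out.append(f"{tpm_path}: duplicate transcript IDs")
    vals = tpm.apply(pd.to_numeric, errors="coerce").to_numpy()
    if np.isnan(vals).any():
        out.append(f"{tpm_path}: non-numeric TPM values")
    elif (vals < 0).any():
        out.append(f"{tpm_path}: negative TPM values")
    if groups_path is not None:
        g = pd.read_csv(groups_path, sep="\t")
        if not {"sample_id", "group"} <= set(g.columns):
            out.append(f"{groups_path}: needs columns sample_id, group")
        else:
            if set(g["sample_id"]) != set(tpm.columns):
                out.append(f"{groups_path}: sample IDs do not match the TPM columns")
            bad = set(g["group"]) - set(GROUPS)
            if bad:
                out.append(f"{groups_path}: unknown group labels {sorted(bad)}")
    return out


def _violations_ct_card(path: Path) -> list[str]:
    out = []
    df = pd.read_csv(path, dtype={"target_id": str, "prep_id": str})
    missing = [c for c in CARD_COLUMNS if c not in df.columns]
    if missing:
        return [f"{path}: missing columns {missing}"]
    ct = df["ct"].replace(NON_DETECT, np.nan)
    if pd.to_numeric(ct, errors="coerce").isna().sum() != ct.isna().sum():
        out.append(f"{path}: Ct values must be numeric or {NON_DETECT!r}")
    n_spike = df.loc[df["is_spike_in"].astype(bool), "target_id"].nunique()
    if n_spike != 1:
        out.append(f"{path}: expected exactly one spike-in target, found {n_spike}")
    return out


def _violations_targets(path: Path, db_names: tuple[str, ...] | None) -> list[str]:
    out = []
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna_id", "db_name", "gene_symbol"} - set(df.columns)
    if missing:
        return [f"{path}: missing columns {sorted(missing)}"]
    if db_names is not None:
        unknown = set(df["db_name"]) - set(db_names)
        if unknown:
            out.append(f"{path}: unknown database names {sorted(unknown)}")
    return out


def _violations_gmt(path: Path) -> list[str]:
    out = []
    seen = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            out.append(f"{path}:{ln}: GMT line has fewer than 3 tab-separated fields")
            continue
        if fields[0] in seen:
            out.append(f"{path}:{ln}: duplicate set name {fields[0]!r}")
        seen.add(fields[0])
    return out


def _violations_survival(path: Path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        return [f"{path}: missing columns {sorted(missing)}"]
    out = []
    if (pd.to_numeric(df["time"], errors="coerce") <= 0).any():
        out.append(f"{path}: follow-up times must be > 0")
    if not df["event"].isin([0, 1]).all():
        out.append(f"{path}: event must be 0 or 1")
    return out


def validate_inputs(
    paths: Mapping[str, str | Path],
    db_names: tuple[str, ...] | None = None,
) -> list[str]:
    """Schema-check input files without mutating them; returns violations.

    ``paths`` maps a kind — ``tpm``, ``groups``, ``mapping``, ``ct_card_ev``,
    ``ct_card_medium``, ``targets``, ``gmt``, ``survival`` — to a file path.
    Unreadable files raise; malformed content is reported as messages.
    """
    violations: list[str] = []
    paths = {k: Path(v) for k, v in paths.items()}
    for kind, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"{kind}: {path}")
    if "tpm" in paths:
        violations += _violations_tpm(paths["tpm"], paths.get("groups"))
    if "mapping" in paths:
        try:
            read_mapping(paths["mapping"])
        except ValueError as exc:
            violations.append(str(exc))
    for kind in ("ct_card_ev", "ct_card_medium", "ct_card"):
        if kind in paths:
            violations += _violations_ct_card(paths[kind])
    if "targets" in paths:
        violations += _violations_targets(paths["targets"], db_names)
    if "gmt" in paths:
        violations += _violations_gmt(paths["gmt"])
    if "survival" in paths:
        violations += _violations_survival(paths["survival"])
    return violations
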