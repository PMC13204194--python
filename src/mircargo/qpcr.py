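"""Relative quantification and expression calling for qPCR miRNA cards.

A card holds threshold-cycle (Ct) values per target and preparation, with a
single designated spike-in/reference row (an exogenous control added during
RNA extraction, or a housekeeping gene) and optional no-template-control
(NTC) wells. Non-detects are "Undetermined" on disk and NaN in memory.

Quantification follows the standard ddCt scheme: dCt = Ct(target) -
Ct(reference) per preparation, ddCt = mean dCt(treated) - mean dCt(control),
RQ = 2^-ddCt. Expression calling implements a conservative EV-versus-medium
rule: a miRNA counts as expressed only with a clean NTC and, in every EV
preparation, a detected Ct that sits at least ``min_delta`` cycles below the
medium background (a medium non-detect counts as infinite separation).
Highly expressed additionally requires Ct < ``ct_cut`` in every preparation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NON_DETECT = "Undetermined"
CARD_COLUMNS = ["target_id", "prep_id", "ct", "is_ntc", "is_spike_in"]


@dataclass
class CtCard:
    """Long-format qPCR card: one row per (target, well).

    ``data`` columns: ``target_id``, ``prep_id``, ``ct`` (float; NaN =
    non-detect), ``is_ntc``, ``is_spike_in``. Exactly one target must be
    flagged as the spike-in/reference, and every non-NTC preparation must
    appear for every target.
    """

    data: pd.DataFrame
    condition: str = "ev"
    max_cycles: int = 40

    def __post_init__(self) -> None:
        missing = [c for c in CARD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct card missing columns: {missing}")
        self.data = self.data[CARD_COLUMNS].copy()
        self.data["ct"] = pd.to_numeric(self.data["ct"], errors="raise")
        for col in ("is_ntc", "is_spike_in"):
            self.data[col] = self.data[col].astype(bool)
        spikes = set(self.data.loc[self.data["is_spike_in"], "target_id"])
        if len(spikes) != 1:
            raise ValueError(
                f"card must have exactly one spike-in/reference target, found {sorted(spikes)}"
            )
        detected = self.data["ct"].dropna()
        if ((detected <= 0) | (detected > self.max_cycles)).any():
            raise ValueError(f"detected Ct values must lie in (0, {self.max_cycles}]")
        wells = self.data[~self.data["is_ntc"]]
        panel = wells.groupby("target_id")["prep_id"].apply(frozenset)
        if panel.nunique() > 1:
            raise ValueError("preparation IDs are not consistent across targets")

    @property
    def spike_target(self) -> str:
        return str(self.data.loc[self.data["is_spike_in"], "target_id"].iloc[0])

    @property
    def preps(self) -> list[str]:
        return sorted(self.data.loc[~self.data["is_ntc"], "prep_id"].unique())

    def targets(self, include_spike: bool = False) -> list[str]:
        sub = self.data[~self.data["is_ntc"]]
        if not include_spike:
            sub = sub[~sub["is_spike_in"]]
        return sorted(sub["target_id"].unique())

    @classmethod
    def from_csv(cls, path: str | Path, condition: str = "ev", max_cycles: int = 40) -> "CtCard":
        df = pd.read_csv(path, dtype={"target_id": str, "prep_id": str})
        df["ct"] = pd.to_numeric(df["ct"].replace(NON_DETECT, np.nan), errors="raise")
        return cls(df, condition=condition, max_cycles=max_cycles)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["ct"] = out["ct"].map(lambda v: NON_DETECT if pd.isna(v) else repr(float(v)))
        out.to_csv(path, index=False)


def normalize_reference(card: CtCard) -> pd.DataFrame:
    """Per-preparation dCt = Ct(target) - Ct(reference).

    The reference (spike-in) must be detected in every preparation;
    otherwise the offending preparations are named in the error. Non-detect
    targets propagate NaN. The reference row itself is not returned.
    """
    wells = card.data[~card.data["is_ntc"]]
    ref = wells[wells["is_spike_in"]].set_index("prep_id")["ct"]
    ref = ref.groupby(level=0).mean()
    bad = sorted(set(card.preps) - set(ref.dropna().index))
    if bad:
        raise ValueError(
            f"reference {card.spike_target!r} not detected in preparations: {bad}"
        )
    targets = wells[~wells["is_spike_in"]].copy()
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.reindex(targets["prep_id"]).to_numpy()
    return targets[["target_id", "prep_id", "delta_ct"]].reset_index(drop=True)


def relative_quant(treated_dct: pd.DataFrame, control_dct: pd.DataFrame) -> pd.DataFrame:
    """ddCt and RQ per target from two dCt tables.

    ``ddCt = mean dCt(treated) - mean dCt(control)`` over detected wells;
    ``RQ = 2^-ddCt``. Targets must intersect across conditions (after
    dropping all-non-detect targets), otherwise an error is raised.
    """
    mean_t = treated_dct.groupby("target_id")["delta_ct"].mean().dropna()
    mean_c = control_dct.groupby("target_id")["delta_ct"].mean().dropna()
    common = mean_t.index.intersection(mean_c.index)
    if common.empty:
        raise ValueError("no common detected targets between conditions")
    ddct = mean_t.loc[common] - mean_c.loc[common]
    out = pd.DataFrame(
        {"target_id": common, "delta_delta_ct": ddct.to_numpy(),
         "rq": np.exp2(-ddct.to_numpy())}
    )
    return out.sort_values("target_id", kind="mergesort").reset_index(drop=True)


def _medium_background(medium_card: CtCard) -> pd.Series:
    """Per-target medium Ct: mean over detected wells, NaN if never detected."""
    wells = medium_card.data[~medium_card.data["is_ntc"] & ~medium_card.data["is_spike_in"]]
    return wells.groupby("target_id")["ct"].mean()


def call_expressed(
    ev_card: CtCard,
    medium_card: CtCard,
    min_delta: float = 4.0,
    ntc_ct_floor: float = 35.0,
) -> pd.DataFrame:
    """Call miRNAs expressed in EVs over the medium background.

    Expressed requires all of, per target:

    * clean NTC — every NTC well is a non-detect or has Ct > ``ntc_ct_floor``
      (targets without NTC wells are treated as clean);
    * detection in **every** EV preparation;
    * separation from background in every EV preparation — the medium is
      either a non-detect for that target, or its mean detected Ct exceeds
      the preparation's EV Ct by at least ``min_delta`` cycles.

    The spike-in/reference row is exempt and not returned. Output columns:
    ``target_id, mean_ct_ev, se_ct_ev, max_ct_ev, mean_ct_medium,
    expressed``; the standard error is NaN with fewer than 2 preparations.
    """
    ev_targets = set(ev_card.targets())
    md_targets = set(medium_card.targets())
    if ev_targets != md_targets:
        only_ev = sorted(ev_targets - md_targets)
        only_md = sorted(md_targets - ev_targets)
        raise ValueError(
            f"EV and medium cards cover different panels; EV-only: {only_ev[:10]}, "
            f"medium-only: {only_md[:10]}"
        )
    wells = ev_card.data[~ev_card.data["is_ntc"] & ~ev_card.data["is_spike_in"]]
    ntc = ev_card.data[ev_card.data["is_ntc"] & ~ev_card.data["is_spike_in"]]
    ntc_clean = (
        ntc.groupby("target_id")["ct"]
        .apply(lambda s: bool((s.isna() | (s > ntc_ct_floor)).all()))
    )
    medium = _medium_background(medium_card)

    rows = []
    for target, grp in wells.groupby("target_id", sort=True):
        ct = grp["ct"]
        detected_all = ct.notna().all()
        med_ct = medium.get(target, np.nan)
        if pd.isna(med_ct):
            separated = True  # medium non-detect: infinite separation
        else:
            separated = bool(((med_ct - ct) >= min_delta).all()) and detected_all
        clean = bool(ntc_clean.get(target, True))
        expressed = clean and detected_all and separated
        n = int(ct.notna().sum())
        rows.append(
            {
                "target_id": target,
                "mean_ct_ev": ct.mean(),
                "se_ct_ev": ct.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                "max_ct_ev": ct.max(),
                "mean_ct_medium": med_ct,
                "ntc_clean": clean,
                "expressed": expressed,
            }
        )
    return pd.DataFrame(rows).reset_index(drop=True)


def call_highly_expressed(calls: pd.DataFrame, ct_cut: float = 27.5) -> pd.DataFrame:
    """Flag highly expressed miRNAs: expressed with Ct strictly below ``ct_cut``.

    With replicate-level data (``max_ct_ev`` present and non-NaN) the rule
    is applied per preparation, i.e. the worst (largest) EV Ct must beat the
    cutoff. When only summary means are available, ``mean_ct_ev`` is used.
    Always implies ``expressed``.
    """
    out = calls.copy()
    if "max_ct_ev" in out.columns:
        worst = out["max_ct_ev"].fillna(out["mean_ct_ev"])
    else:
        worst = out["mean_ct_ev"]
    out["highly_expressed"] = out["expressed"].astype(bool) & (worst < ct_cut)
    return out
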