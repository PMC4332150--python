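"""Dual-filter HCIP calling with bait-self masking and re-addition.

High-confident candidate interacting proteins (HCIPs) are the
interactions that survive two independent filtrations:

1. the mixture-model probability filter (probability > 0.80, strict);
2. the contaminant filter: any prey with mu_i >= 0 — i.e. as abundant
   in the control pool as the common-contaminant baseline — is removed
   from *every* bait and fraction.

Because the bait protein is overexpressed, its self-identification
distorts the abundance estimates; self counts are therefore zeroed
before scoring (kept in a ledger) and re-added to the final table,
flagged, bypassing both filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExperimentDesign
from .scoring import BackgroundModel

HCIP_COLUMNS = ["bait", "prey", "fraction", "probability", "mu",
                "total_count", "is_bait_self"]


def mask_bait_self(cm: CountMatrix, design: ExperimentDesign
                   ) -> tuple[CountMatrix, pd.DataFrame]:
    """Zero each bait's own prey row within its own purifications.

    Applies to every purification whose bait matches a prey row,
    including unrelated-bait controls (they are real TAP experiments
    with self counts).  Returns the masked matrix and a self ledger
    recording the removed cells (purification, bait, prey, fraction,
    pool, count) so they can be re-added after filtration.
    """
    counts = cm.counts.copy()
    rows = []
    for p in design.purifications:
        if p.bait in counts.index:
            c = int(counts.loc[p.bait, p.id])
            rows.append({
                "purification_id": p.id, "bait": p.bait, "prey": p.bait,
                "fraction": p.fraction, "pool": p.pool, "count": c,
            })
            counts.loc[p.bait, p.id] = 0
    ledger = pd.DataFrame(
        rows, columns=["purification_id", "bait", "prey", "fraction",
                       "pool", "count"],
    )
    return CountMatrix(counts, cm.lengths.copy()), ledger


def call_hcips(scores: pd.DataFrame, bg: BackgroundModel,
               ledger: pd.DataFrame | None = None,
               p_threshold: float = 0.80,
               mu_threshold: float = 0.0) -> pd.DataFrame:
    """Apply the dual filtration and re-add bait-self rows.

    Keeps (bait, prey, fraction) iff probability > p_threshold (strict)
    AND mu < mu_threshold (mu_threshold itself fails, matching
    "mu_i >= 0 is removed").  Self-ledger rows from sample purifications
    are re-added, flagged ``is_bait_self``, in the fractions where the
    bait was actually detected (count > 0), and are never filtered.
    """
    if not 0.0 <= p_threshold <= 1.0:
        raise ValueError("p_threshold must be in [0, 1]")
    cols = HCIP_COLUMNS
    if len(scores):
        keep = (scores["probability"] > p_threshold) & \
               (scores["mu"] < mu_threshold)
        table = scores.loc[keep, ["bait", "prey", "fraction",
                                  "probability", "mu", "total_count"]].copy()
    else:
        table = pd.DataFrame(columns=cols[:-1])
    table["is_bait_self"] = False

    if ledger is not None and len(ledger):
        self_rows = (
            ledger[(ledger["pool"] == "sample") & (ledger["count"] > 0)]
            .groupby(["bait", "prey", "fraction"], as_index=False)["count"]
            .sum()
        )
        if len(self_rows):
            self_rows = self_rows.rename(columns={"count": "total_count"})
            self_rows["probability"] = np.nan
            self_rows["mu"] = [
                float(bg.mu.get(p, np.nan)) for p in self_rows["prey"]
            ]
            self_rows["is_bait_self"] = True
            table = pd.concat([table, self_rows[cols]], ignore_index=True)

    table = table.reset_index(drop=True)
    dup = table.duplicated(subset=["bait", "prey", "fraction"])
    if dup.any():
        raise ValueError("duplicate (bait, prey, fraction) rows in HCIP table")
    return table[cols]


def hcip_summary(scores: pd.DataFrame, hcips: pd.DataFrame,
                 p_threshold: float = 0.80,
                 mu_threshold: float = 0.0) -> pd.DataFrame:
    """Step-by-step filtration counts, total and per fraction.

    Rows: scored interactions, passed the probability filter, passed
    the contaminant filter, HCIP (both, incl. re-added self rows).
    """
    def strata(mask_frame: pd.DataFrame) -> dict:
        return {
            "total": len(mask_frame),
            "chromatin": int((mask_frame["fraction"] == "chromatin").sum()),
            "soluble": int((mask_frame["fraction"] == "soluble").sum()),
        }

    pass_p = scores[scores["probability"] > p_threshold] if len(scores) \
        else scores
    pass_mu = scores[scores["mu"] < mu_threshold] if len(scores) else scores
    rows = [
        {"step": "scored", **strata(scores)},
        {"step": "passed_probability", **strata(pass_p)},
        {"step": "passed_mu", **strata(pass_mu)},
        {"step": "hcip", **strata(hcips)},
    ]
    return pd.DataFrame(rows, columns=["step", "total", "chromatin", "soluble"])
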