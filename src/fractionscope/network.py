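"""Comparative analyses downstream of HCIP calling.

Fraction overlap (how many bait-prey pairs are HCIP both on and off
chromatin), per-bait total spectral counts of HCIPs, replicate
reproducibility as a function of count depth, reciprocal-purification
validation, and overlap with a reference interaction set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, DesignMismatchError, ExperimentDesign


@dataclass
class OverlapSummary:
    """Chromatin / soluble HCIP overlap bookkeeping.

    ``pct_both`` uses distinct (bait, prey) pairs as the denominator;
    ``pct_both_of_rows`` (rows = fraction-stratified interactions) and
    ``pct_both_of_min_fraction`` are the two other natural conventions,
    emitted for transparency since the choice changes the number.
    """

    n_total: int
    n_chromatin: int
    n_soluble: int
    n_both: int
    n_both_self: int
    pct_both: float
    pct_both_of_rows: float
    pct_both_of_min_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def fraction_overlap(hcips: pd.DataFrame) -> OverlapSummary:
    """Count bait-prey pairs called HCIP in both fractions.

    A pair counts in ``n_both`` iff it appears with both the chromatin
    and the soluble label; ``n_both_self`` is the subset of those that
    are bait self-identifications.
    """
    chrom = hcips[hcips["fraction"] == "chromatin"]
    sol = hcips[hcips["fraction"] == "soluble"]
    chr_pairs = set(zip(chrom["bait"], chrom["prey"]))
    sol_pairs = set(zip(sol["bait"], sol["prey"]))
    both = chr_pairs & sol_pairs
    self_pairs = set(zip(hcips.loc[hcips["is_bait_self"], "bait"],
                         hcips.loc[hcips["is_bait_self"], "prey"]))
    n_pairs = len(chr_pairs | sol_pairs)
    n_chr, n_sol = len(chrom), len(sol)
    n_total = len(hcips)
    return OverlapSummary(
        n_total=n_total,
        n_chromatin=n_chr,
        n_soluble=n_sol,
        n_both=len(both),
        n_both_self=len(both & self_pairs),
        pct_both=100.0 * len(both) / n_pairs if n_pairs else 0.0,
        pct_both_of_rows=100.0 * len(both) / n_total if n_total else 0.0,
        pct_both_of_min_fraction=(
            100.0 * len(both) / min(len(chr_pairs), len(sol_pairs))
            if min(len(chr_pairs), len(sol_pairs)) else 0.0
        ),
    )


def tsc_per_bait(hcips: pd.DataFrame, cm: CountMatrix,
                 design: ExperimentDesign) -> pd.DataFrame:
    """Total spectral counts of each bait's non-self HCIPs, per fraction.

    Sums the count matrix over the bait's own purifications of each
    fraction, restricted to its HCIP preys in that fraction; bait-self
    rows are excluded.  The result mirrors the on/off-chromatin binding
    load comparison of the study.
    """
    unknown = set(hcips["bait"]) - set(design.sample_baits())
    if unknown:
        raise DesignMismatchError(f"baits absent from design: {sorted(unknown)}")
    rows = []
    fractions = [f for f in design.sample_fractions()]
    for bait in design.sample_baits():
        for frac in fractions:
            sub = hcips[(hcips["bait"] == bait)
                        & (hcips["fraction"] == frac)
                        & (~hcips["is_bait_self"])]
            purs = [p.id for p in design.purifications_of(bait, frac)]
            preys = [p for p in sub["prey"] if p in cm.counts.index]
            tsc = int(cm.counts.loc[preys, purs].to_numpy().sum()) \
                if preys and purs else 0
            rows.append({"bait": bait, "fraction": frac, "tsc": tsc,
                         "n_hcips": len(sub)})
    return pd.DataFrame(rows, columns=["bait", "fraction", "tsc", "n_hcips"])


def replicate_reproducibility(hcips_rep1: pd.DataFrame,
                              hcips_rep2: pd.DataFrame,
                              thresholds=(2, 5, 10)) -> pd.DataFrame:
    """HCIP overlap ratio between biological replicates vs count depth.

    At threshold t the directed ratio is |pairs HCIP in both replicates
    with total_count >= t in the reference| / |pairs HCIP in the
    reference with total_count >= t|; the reported ratio averages the
    two directions.  Pairs are (bait, prey, fraction) triples.
    """
    b1 = set(hcips_rep1["bait"])
    b2 = set(hcips_rep2["bait"])
    if not (b1 & b2):
        raise DesignMismatchError("replicate tables share no baits")

    def keyed(df: pd.DataFrame) -> dict:
        return {
            (r.bait, r.prey, r.fraction): int(r.total_count)
            for r in df.itertuples(index=False)
        }

    k1, k2 = keyed(hcips_rep1), keyed(hcips_rep2)
    rows = []
    for t in thresholds:
        def directed(ref: dict, other: dict) -> float | None:
            denom = [k for k, c in ref.items() if c >= t]
            if not denom:
                return None
            hits = sum(1 for k in denom if k in other)
            return hits / len(denom)

        d1 = directed(k1, k2)
        d2 = directed(k2, k1)
        vals = [d for d in (d1, d2) if d is not None]
        ratio = float(np.mean(vals)) if vals else np.nan
        n_pairs = sum(1 for k, c in k1.items() if c >= t) + \
            sum(1 for k, c in k2.items() if c >= t)
        rows.append({"threshold": t, "overlap_ratio": ratio,
                     "n_pairs": n_pairs})
    return pd.DataFrame(rows, columns=["threshold", "overlap_ratio", "n_pairs"])


def reproducibility_trend(curve: pd.DataFrame) -> float:
    """Spearman rho between threshold and overlap ratio (>= 0 means the
    reproducibility rises with count depth)."""
    sub = curve.dropna(subset=["overlap_ratio"])
    if len(sub) < 2 or sub["overlap_ratio"].nunique() == 1:
        return 0.0
    rho, _ = stats.spearmanr(sub["threshold"], sub["overlap_ratio"])
    return float(rho)


def reciprocal_validation(forward: pd.DataFrame,
                          reverse_tables: dict[str, pd.DataFrame],
                          pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Check whether preys re-capture their baits in reverse purifications.

    For each (forward_bait, prey) pair, the pair is *recovered* iff the
    forward bait appears (any fraction) among the prey's reverse HCIPs,
    and *fraction-matched* iff the reverse detection fractions intersect
    the forward detection fractions.  Pairs without a reverse table are
    flagged (``has_reverse_table`` False) and excluded from the counts.
    """
    rows = []
    for bait, prey in pairs:
        fwd = forward[(forward["bait"] == bait) & (forward["prey"] == prey)]
        fwd_fracs = sorted(set(fwd["fraction"]))
        rev = reverse_tables.get(prey)
        if rev is None:
            rows.append({
                "forward_bait": bait, "prey": prey,
                "forward_fractions": "/".join(fwd_fracs),
                "reverse_fractions": "", "has_reverse_table": False,
                "recovered": False, "fraction_matched": False,
            })
            continue
        hit = rev[rev["prey"] == bait]
        rev_fracs = sorted(set(hit["fraction"]))
        recovered = len(hit) > 0
        matched = bool(set(rev_fracs) & set(fwd_fracs))
        rows.append({
            "forward_bait": bait, "prey": prey,
            "forward_fractions": "/".join(fwd_fracs),
            "reverse_fractions": "/".join(rev_fracs) if recovered else "N",
            "has_reverse_table": True,
            "recovered": recovered, "fraction_matched": matched,
        })
    return pd.DataFrame(rows, columns=[
        "forward_bait", "prey", "forward_fractions", "reverse_fractions",
        "has_reverse_table", "recovered", "fraction_matched",
    ])


def reciprocal_counts(result: pd.DataFrame) -> tuple[int, int]:
    """(n_recovered, n_fraction_matched) over pairs with a reverse table."""
    sub = result[result["has_reverse_table"]]
    return int(sub["recovered"].sum()), int(sub["fraction_matched"].sum())


def reference_overlap(hcips: pd.DataFrame,
                      reference_edges) -> tuple[int, int, float]:
    """Overlap of non-self HCIP pairs with a reference edge set.

    ``reference_edges`` is an iterable of (protein, protein) pairs,
    treated as undirected.  Returns (n_known, n_total_nonself,
    fraction_known).
    """
    ref = {frozenset(e) for e in reference_edges}
    nonself = hcips[~hcips["is_bait_self"]]
    pairs = {frozenset((b, p)) for b, p in zip(nonself["bait"],
                                               nonself["prey"])}
    n_total = len(pairs)
    n_known = sum(1 for p in pairs if p in ref)
    return n_known, n_total, (n_known / n_total if n_total else 0.0)
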