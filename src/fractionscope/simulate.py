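"""Synthetic fractionated AP-MS datasets with known ground truth.

The generator emulates the statistical structure of a two-fraction TF
interactome screen: ~56 baits purified from chromatin and soluble
fractions (a few with biological replicates), a negative-control pool of
unrelated-bait and vector-only purifications, several thousand preys
with log-normally heterogeneous Poisson background rates, a minority of
ubiquitous contaminant preys with boosted background, planted
fraction-specific true interactions, and bait self-identifications in
every purification of a tagged protein (controls included — the
unrelated-bait controls are real TAP experiments).

Counts are independent Poisson draws:

    X_ij ~ Poisson( background_i * [boost if contaminant]
                    + lambda_true * [(bait_j, i, fraction_j) is an edge]
                    + bait_self_mean * [i is bait_j's own protein] )

so every downstream estimate can be checked against the generating
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import (
    CONTROL,
    CountMatrix,
    ExperimentDesign,
    PreyInfo,
    Purification,
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-shaped conditions.

    n_baits / n_preys / n_unrelated_controls / vector_controls:
        56 baits, 3,700 preys, 61 unrelated-bait controls and 9
        vector-only controls (4 chromatin, 4 soluble, 1 combined) match
        the screen's design of 190 purifications.
    replicated_baits_per_fraction:
        how many baits get a second biological replicate per fraction
        (4 + 4 extra runs bring 112 bait purifications to 60 + 60).
    lambda_false:
        background Poisson mean for a typical prey; each prey's
        background is additionally scaled by a log-normal factor
        (sigma = background_sigma) so the contaminant-score spectrum is
        non-degenerate.
    lambda_true:
        mean spectral count contributed by a planted true interaction.
    contaminant_fraction / contaminant_boost:
        proportion of preys that are ubiquitous contaminants and the
        multiplicative boost on their background rate.
    edge_density:
        expected planted true edges per bait per fraction;
        fraction_shared_edges is the proportion of a bait's edges
        present in both fractions.
    bait_self_mean:
        Poisson mean added on the bait's own prey row in its own
        purifications.
    """

    n_baits: int = 56
    n_preys: int = 3700
    n_unrelated_controls: int = 61
    vector_controls: int = 9
    replicates_per_bait_fraction: int = 1
    replicated_baits_per_fraction: int = 4
    lambda_false: float = 0.035
    lambda_true: float = 25.0
    background_sigma: float = 0.5
    contaminant_fraction: float = 0.05
    contaminant_boost: float = 20.0
    edge_density: float = 18.0
    fraction_shared_edges: float = 0.05
    bait_self_mean: float = 30.0
    mean_prey_length: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lambda_false, self.lambda_true, self.bait_self_mean) <= 0:
            raise ValueError("all rates must be positive")
        for name in ("contaminant_fraction", "fraction_shared_edges"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contaminant_boost <= 1.0:
            raise ValueError("contaminant_boost must be > 1")
        if self.n_preys < self.n_baits + self.n_unrelated_controls:
            raise ValueError(
                "n_preys must cover the bait and unrelated-control "
                "self proteins"
            )
        if self.replicates_per_bait_fraction < 1:
            raise ValueError("replicates_per_bait_fraction must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study-shaped configuration (190 purifications)."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Generating truth of a simulated dataset."""

    true_edges: set  # of (bait, prey, fraction)
    contaminant_preys: set
    background_rates: pd.Series  # per-prey background (before boost)
    config: SimulationConfig

    def edges_frame(self) -> pd.DataFrame:
        rows = sorted(self.true_edges)
        return pd.DataFrame(rows, columns=["bait", "prey", "fraction"])


FRACS = ("chromatin", "soluble")


def _build_design(cfg: SimulationConfig, control_baits: list[str]
                  ) -> ExperimentDesign:
    purs: list[Purification] = []
    n_rep = cfg.replicates_per_bait_fraction
    extra = cfg.replicated_baits_per_fraction
    for f, frac in enumerate(FRACS):
        for b in range(cfg.n_baits):
            bait = f"BAIT{b + 1:03d}"
            reps = n_rep + (1 if n_rep == 1 and b < extra else 0)
            for r in range(1, reps + 1):
                purs.append(Purification(
                    id=f"{bait}_{frac[:3]}_r{r}", bait=bait,
                    fraction=frac, pool="sample", replicate=r,
                ))
    # unrelated-bait controls alternate fractions (odd count allowed)
    for k, bait in enumerate(control_baits):
        frac = FRACS[k % 2]
        purs.append(Purification(
            id=f"{bait}_{frac[:3]}_ctl", bait=bait, fraction=frac,
            pool="control", replicate=1,
        ))
    # vector-only controls: alternate chromatin/soluble, odd one combined
    nv = cfg.vector_controls
    for k in range(nv):
        if k == nv - 1 and nv % 2 == 1:
            frac = "combined"
        else:
            frac = FRACS[k % 2]
        purs.append(Purification(
            id=f"VEC_{frac[:3]}_{k + 1}", bait=CONTROL, fraction=frac,
            pool="control", replicate=1,
        ))
    return ExperimentDesign(purs)


def simulate_dataset(cfg: SimulationConfig
                     ) -> tuple[CountMatrix, ExperimentDesign, GroundTruth]:
    """Draw a dataset; identical config (incl. seed) gives identical data."""
    rng = np.random.default_rng(cfg.seed)

    bait_ids = [f"BAIT{b + 1:03d}" for b in range(cfg.n_baits)]
    control_baits = [f"CTRL{b + 1:03d}" for b in range(cfg.n_unrelated_controls)]
    n_named = cfg.n_baits + cfg.n_unrelated_controls
    prey_ids = bait_ids + control_baits + [
        f"PREY{k + 1:04d}" for k in range(cfg.n_preys - n_named)
    ]
    lengths = rng.integers(max(2, cfg.mean_prey_length // 5),
                           cfg.mean_prey_length * 2, size=cfg.n_preys)
    preys = [PreyInfo(pid, int(ln)) for pid, ln in zip(prey_ids, lengths)]

    design = _build_design(cfg, control_baits)

    # per-prey heterogeneous background; contaminants boosted
    background = cfg.lambda_false * rng.lognormal(
        mean=0.0, sigma=cfg.background_sigma, size=cfg.n_preys
    )
    n_contam = int(round(cfg.contaminant_fraction * cfg.n_preys))
    contam_idx = rng.choice(cfg.n_preys, size=n_contam, replace=False)
    is_contam = np.zeros(cfg.n_preys, dtype=bool)
    is_contam[contam_idx] = True
    effective_bg = background * np.where(is_contam, cfg.contaminant_boost, 1.0)

    # planted edges: preys drawn from non-contaminant, non-self preys
    # (the contaminant filter presumes true partners are not themselves
    # ubiquitous contaminants)
    prey_index = {pid: k for k, pid in enumerate(prey_ids)}
    candidates = np.array([
        k for k in range(cfg.n_preys) if not is_contam[k]
    ])
    true_edges: set[tuple[str, str, str]] = set()
    for bait in bait_ids:
        b_idx = prey_index[bait]
        pool = candidates[candidates != b_idx]
        n_shared = rng.poisson(cfg.edge_density * cfg.fraction_shared_edges)
        n_shared = min(n_shared, len(pool))
        shared = rng.choice(pool, size=n_shared, replace=False)
        for frac in FRACS:
            n_spec = rng.poisson(
                cfg.edge_density * (1.0 - cfg.fraction_shared_edges))
            rest = np.setdiff1d(pool, shared, assume_unique=False)
            n_spec = min(n_spec, len(rest))
            spec = rng.choice(rest, size=n_spec, replace=False) \
                if n_spec else np.array([], dtype=int)
            for k in np.concatenate([shared, spec]):
                true_edges.add((bait, prey_ids[int(k)], frac))

    # rate matrix: background everywhere, plus edge and self signal
    n_purs = len(design)
    rates = np.tile(effective_bg[:, None], (1, n_purs))
    pur_list = design.purifications
    edge_by_bait_frac: dict[tuple[str, str], list[int]] = {}
    for (bait, prey, frac) in true_edges:
        edge_by_bait_frac.setdefault((bait, frac), []).append(prey_index[prey])
    for j, p in enumerate(pur_list):
        if p.pool == "sample":
            idxs = edge_by_bait_frac.get((p.bait, p.fraction))
            if idxs:
                rates[idxs, j] += cfg.lambda_true
        if p.bait in prey_index:  # self counts, samples and controls alike
            rates[prey_index[p.bait], j] += cfg.bait_self_mean

    counts = rng.poisson(rates)
    cm = CountMatrix.from_preys(preys, design.ids, counts)
    truth = GroundTruth(
        true_edges=true_edges,
        contaminant_preys={prey_ids[k] for k in np.flatnonzero(is_contam)},
        background_rates=pd.Series(background, index=prey_ids,
                                   name="background_rate"),
        config=cfg,
    )
    return cm, design, truth


# ---------------------------------------------------------------------------
# hard-coded worked fixtures
# ---------------------------------------------------------------------------

def make_worked_fixture(name: str):
    """Small deterministic fixtures with documented expected outputs.

    ``tiny_two_prey`` and ``fraction_skew`` return (CountMatrix,
    ExperimentDesign, GroundTruth); ``reciprocal_table2`` returns
    (forward HCIP table, {prey: reverse HCIP table}, pairs) encoding a
    published 16-pair reciprocal-purification panel in which 14 preys
    re-captured their bait, 2 did not, and the detections sit in the
    fractions shown.
    """
    if name == "tiny_two_prey":
        return _tiny_two_prey()
    if name == "fraction_skew":
        return _fraction_skew()
    if name == "reciprocal_table2":
        return _reciprocal_table2()
    raise ValueError(f"unknown fixture {name!r}")


def _tiny_two_prey():
    """2 preys x (2 sample + 4 control) purifications with hand-set counts.

    P1 is a planted partner of BAIT001 (high counts in the bait's
    purifications, absent from controls); P2 is a contaminant-like prey
    seen everywhere.
    """
    preys = [PreyInfo("P1", 300), PreyInfo("P2", 500)]
    purs = [
        Purification("s_chr", "BAIT001", "chromatin", "sample"),
        Purification("s_sol", "BAIT001", "soluble", "sample"),
        Purification("c1", CONTROL, "chromatin", "control"),
        Purification("c2", CONTROL, "chromatin", "control"),
        Purification("c3", CONTROL, "soluble", "control"),
        Purification("c4", CONTROL, "soluble", "control"),
    ]
    counts = np.array([
        [12, 9, 0, 0, 0, 0],   # P1
        [3, 4, 5, 4, 6, 5],    # P2
    ])
    design = ExperimentDesign(purs)
    cm = CountMatrix.from_preys(preys, design.ids, counts)
    truth = GroundTruth(
        true_edges={("BAIT001", "P1", "chromatin"),
                    ("BAIT001", "P1", "soluble")},
        contaminant_preys={"P2"},
        background_rates=pd.Series([0.05, 5.0], index=["P1", "P2"]),
        config=None,
    )
    return cm, design, truth


def _fraction_skew():
    """A bait detected 59:402 chromatin:soluble in its own self row,
    mimicking a strongly soluble-skewed bait protein."""
    preys = [PreyInfo("BAITX", 441), PreyInfo("P1", 200)]
    purs = [
        Purification("x_chr", "BAITX", "chromatin", "sample"),
        Purification("x_sol", "BAITX", "soluble", "sample"),
        Purification("c1", CONTROL, "chromatin", "control"),
        Purification("c2", CONTROL, "soluble", "control"),
    ]
    counts = np.array([
        [59, 402, 0, 0],   # bait self row
        [6, 1, 0, 0],      # a chromatin partner
    ])
    design = ExperimentDesign(purs)
    cm = CountMatrix.from_preys(preys, design.ids, counts)
    truth = GroundTruth(
        true_edges={("BAITX", "P1", "chromatin")},
        contaminant_preys=set(),
        background_rates=pd.Series([0.0, 0.05], index=["BAITX", "P1"]),
        config=None,
    )
    return cm, design, truth


_TABLE2_ROWS = [
    # (forward bait, prey, forward fractions, reverse fractions or None)
    ("MAX", "L3MBTL2", ("chromatin",), ("soluble",)),
    ("MAX", "E2F6", ("chromatin",), ("chromatin",)),
    ("MAX", "FOXK2", ("chromatin",), ("chromatin",)),
    ("NFATC1", "JUN", ("chromatin",), ("chromatin",)),
    ("NFATC1", "HOXD13", ("chromatin",), ("chromatin",)),
    ("NFATC1", "CREB1", ("chromatin",), ("chromatin",)),
    ("NFATC1", "ATF3", ("chromatin",), ("chromatin",)),
    ("NFATC1", "ATF1", ("chromatin",), ("chromatin",)),
    ("RBPJ", "L3MBTL2", ("chromatin",), ("soluble",)),
    ("RBPJ", "KDM1", ("chromatin",), ("chromatin",)),
    ("RBPJ", "FBXO42", ("chromatin", "soluble"), ("chromatin", "soluble")),
    ("CREB1", "ATF1", ("chromatin", "soluble"), ("chromatin", "soluble")),
    ("CREB1", "HMGA1", ("chromatin",), None),
    ("CREB1", "ZNF131", ("chromatin",), None),
    ("CREB1", "NFIX", ("chromatin",), ("chromatin",)),
    ("CREB1", "NFATC2", ("chromatin",), ("chromatin",)),
]


def _hcip_stub(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["bait", "prey", "fraction", "probability", "mu",
                 "total_count", "is_bait_self"],
    )


def _reciprocal_table2():
    fwd_rows = []
    for bait, prey, fwd_fracs, _ in _TABLE2_ROWS:
        for f in fwd_fracs:
            fwd_rows.append((bait, prey, f, 0.99, -2.0, 20, False))
    forward = _hcip_stub(fwd_rows)
    reverse_tables: dict[str, pd.DataFrame] = {}
    for bait, prey, _, rev_fracs in _TABLE2_ROWS:
        rows = reverse_tables.get(prey)
        existing = [] if rows is None else list(
            rows.itertuples(index=False, name=None))
        if rev_fracs is not None:
            for f in rev_fracs:
                row = (prey, bait, f, 0.99, -2.0, 15, False)
                if row not in existing:
                    existing.append(row)
        reverse_tables[prey] = _hcip_stub(existing)
    pairs = [(bait, prey) for bait, prey, _, _ in _TABLE2_ROWS]
    return forward, reverse_tables, pairs
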