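"""One-shot orchestration: mask self -> background -> score -> atlas ->
HCIP -> comparative analyses, with provenance.

Every run writes a directory of TSV tables, each carrying the package
version and a hash of the full configuration, plus a ``summary.tsv``
with the step-by-step filtration counts (experiments, identifications,
probability-filter survivors, contaminant-filter survivors, HCIPs;
columns total / chromatin / soluble)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .atlas import AtlasThresholds, build_atlas, categorize_preys, plot_atlas
from .datamodel import CountMatrix, ExperimentDesign
from .hcip import call_hcips, hcip_summary, mask_bait_self
from .network import (
    fraction_overlap,
    reference_overlap,
    tsc_per_bait,
)
from .scoring import ScoringConfig, estimate_background, score_interactions

log = logging.getLogger("fractionscope")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    matrix: str | None = None
    design: str | None = None
    reference_edges: str | None = None
    out_dir: str = "fractionscope_run"
    matrix_dialect: str = "matrix_tsv"
    lengths: str | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    atlas: AtlasThresholds = field(default_factory=AtlasThresholds)
    p_threshold: float = 0.80
    mu_threshold: float = 0.0
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("scoring", "atlas")}
        d["scoring"] = self.scoring.to_dict()
        d["atlas"] = self.atlas.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        scoring = ScoringConfig(**d.pop("scoring", {}))
        atlas = AtlasThresholds(**d.pop("atlas", {}))
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(scoring=scoring, atlas=atlas, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        # hash of the analysis parameters; the output location is not
        # part of a run's identity
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self) -> None:
        if self.matrix is None or self.design is None:
            raise ConfigError("config must set both 'matrix' and 'design'")
        for label, p in (("matrix", self.matrix), ("design", self.design)):
            if not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
        if self.reference_edges and not Path(self.reference_edges).exists():
            raise ConfigError(
                f"reference_edges path does not exist: {self.reference_edges}"
            )
        if not 0.0 <= self.p_threshold <= 1.0:
            raise ConfigError("p_threshold must be in [0, 1]")


def _design_summary(design: ExperimentDesign, cm: CountMatrix,
                    scores, hsum: pd.DataFrame) -> pd.DataFrame:
    """Table-1-style layout: step counts, total / strata columns."""
    def n_purs(pred) -> int:
        return sum(1 for p in design.purifications if pred(p))

    identified = {
        "total": int((cm.counts > 0).to_numpy().sum()),
        "tfs": int((cm.counts[[p.id for p in design.samples]] > 0
                    ).to_numpy().sum()),
        "chromatin": int((cm.counts[[p.id for p in design.samples
                                     if p.fraction == "chromatin"]] > 0
                          ).to_numpy().sum()),
        "soluble": int((cm.counts[[p.id for p in design.samples
                                   if p.fraction == "soluble"]] > 0
                        ).to_numpy().sum()),
        "controls": int((cm.counts[[p.id for p in design.controls]] > 0
                         ).to_numpy().sum()),
    }
    peptides = {
        "total": cm.total(),
        "tfs": int(cm.counts[[p.id for p in design.samples]]
                   .to_numpy().sum()),
        "chromatin": int(cm.counts[[p.id for p in design.samples
                                    if p.fraction == "chromatin"]]
                         .to_numpy().sum()),
        "soluble": int(cm.counts[[p.id for p in design.samples
                                  if p.fraction == "soluble"]]
                       .to_numpy().sum()),
        "controls": int(cm.counts[[p.id for p in design.controls]]
                        .to_numpy().sum()),
    }
    rows = [
        {"step": "experiments",
         "total": len(design),
         "tfs": design.sample_count,
         "chromatin": n_purs(lambda p: p.pool == "sample"
                             and p.fraction == "chromatin"),
         "soluble": n_purs(lambda p: p.pool == "sample"
                           and p.fraction == "soluble"),
         "controls": design.control_count},
        {"step": "spectra", **peptides},
        {"step": "identifications", **identified},
    ]
    for r in hsum.itertuples(index=False):
        rows.append({"step": r.step, "total": r.total, "tfs": r.total,
                     "chromatin": r.chromatin, "soluble": r.soluble,
                     "controls": ""})
    return pd.DataFrame(rows, columns=["step", "total", "tfs", "chromatin",
                                       "soluble", "controls"])


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with the stage name in the exception and a
    FAILED marker file; partial outputs are retained.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    comments = [f"config_hash {chash}"]
    cfg.to_yaml(out / "config.yaml")
    stage = "load"
    t0 = time.time()
    try:
        design = fio.read_design(cfg.design)
        cm = fio.read_count_matrix(
            cfg.matrix, cfg.matrix_dialect,
            lengths_path=cfg.lengths, design=design,
        )
        cm.validate_against(design)
        log.info("loaded %d preys x %d purifications",
                 *cm.shape)

        stage = "mask_bait_self"
        masked, ledger = mask_bait_self(cm, design)
        fio.write_table(ledger, out / "self_ledger.tsv", comments=comments)

        stage = "estimate_background"
        bg = estimate_background(masked, design, cfg.scoring)

        stage = "score_interactions"
        scores = score_interactions(masked, design, bg, cfg.scoring)
        fio.write_table(scores, out / "scores.tsv", comments=comments)
        log.info("scored %d candidate interactions", len(scores))

        stage = "atlas"
        atlas = categorize_preys(
            build_atlas(masked, design, bg, cfg.scoring), cfg.atlas)
        fio.write_table(atlas, out / "atlas.tsv", comments=comments + [
            "tf_specificity = log rate(entire group) - log rate(controls); "
            "fraction_specificity = log rate(chromatin) - log rate(soluble)"
        ])
        if cfg.make_plots:
            plot_atlas(atlas, out / "atlas.png")

        stage = "call_hcips"
        hcips = call_hcips(scores, bg, ledger,
                           p_threshold=cfg.p_threshold,
                           mu_threshold=cfg.mu_threshold)
        fio.write_table(hcips, out / "hcips.tsv", comments=comments)
        hsum = hcip_summary(scores, hcips, cfg.p_threshold, cfg.mu_threshold)

        stage = "network_analysis"
        overlap = fraction_overlap(hcips)
        fio.write_table(overlap.to_frame(), out / "overlap.tsv",
                        comments=comments)
        tsc = tsc_per_bait(hcips, cm, design)
        fio.write_table(tsc, out / "tsc.tsv", comments=comments)
        if cfg.reference_edges:
            ref = fio.read_table(cfg.reference_edges)
            edges = list(zip(ref.iloc[:, 0], ref.iloc[:, 1]))
            n_known, n_tot, frac = reference_overlap(hcips, edges)
            fio.write_table(
                pd.DataFrame([{"n_known": n_known, "n_total_nonself": n_tot,
                               "fraction_known": frac}]),
                out / "reference_overlap.tsv", comments=comments)

        stage = "summary"
        summary = _design_summary(design, cm, scores, hsum)
        fio.write_table(summary, out / "summary.tsv", comments=comments)
        log.info("pipeline finished in %.1fs", time.time() - t0)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    return out
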