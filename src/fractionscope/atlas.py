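"""Per-prey abundance / specificity atlas and colour categorization.

Every prey detected in at least one TF (sample) purification gets three
log-scale summary scores:

* ``abundance`` — log depth-normalized mean rate over *all* purifications
  (the bubble size of the specificity map);
* ``tf_specificity`` — log rate over the entire group (samples +
  controls) minus log rate over the control group; positive means the
  prey is enriched in TF purifications rather than background;
* ``fraction_specificity`` — log rate among chromatin purifications
  minus log rate among soluble purifications; positive means
  chromatin-enriched.

Categories partition the atlas by position on the (fraction_specificity,
tf_specificity) map: red = TF-specific and chromatin-enriched, blue =
TF-specific and soluble-enriched, purple = TF-specific with no
fractional preference, green = weakly specific, grey = non-specific
(the abundant-contaminant tail).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, ExperimentDesign
from .scoring import BackgroundModel, ScoringConfig

CATEGORIES = ("red", "purple", "blue", "green", "grey")


@dataclass
class AtlasThresholds:
    """Category boundaries on the log-rate scores (log units).

    The source map draws these boundaries visually, so they are plain
    configuration: ``specificity_min`` separates TF-specific preys from
    the rest, ``green_band`` is the weakly-specific band below it, and
    ``fraction_margin`` is the |fraction_specificity| above which a
    fraction preference is declared.
    """

    specificity_min: float = 1.0
    fraction_margin: float = 1.0
    green_band: float = 0.3

    def __post_init__(self) -> None:
        if not self.specificity_min > self.green_band >= 0:
            raise ValueError("need specificity_min > green_band >= 0")
        if self.fraction_margin <= 0:
            raise ValueError("fraction_margin must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_rate(cm: CountMatrix, ids: list[str], offsets: pd.Series) -> pd.Series:
    """Depth-normalized mean count rate over a purification set."""
    scales = np.exp(offsets[ids].to_numpy(dtype=float))
    return (cm.counts[ids] / scales).mean(axis=1)


def build_atlas(cm: CountMatrix, design: ExperimentDesign,
                bg: BackgroundModel,
                cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Compute the per-prey score atlas.

    Only preys appearing in >= 1 sample (TF-group) purification are
    emitted.  Returns a DataFrame with columns prey, abundance,
    tf_specificity, fraction_specificity, mu and an empty category
    column (filled by :func:`categorize_preys`).
    """
    cfg = cfg or ScoringConfig()
    cm.validate_against(design)
    sample_ids = [p.id for p in design.samples]
    control_ids = [p.id for p in design.controls]
    if not sample_ids:
        raise ValueError("no sample purifications; atlas is empty")
    in_tf_group = cm.counts[sample_ids].sum(axis=1) > 0
    preys = cm.counts.index[in_tf_group]
    if len(preys) == 0:
        raise ValueError("no prey observed in any TF-group purification")
    eps = cfg.pseudo_count
    off = bg.experiment_offsets

    all_ids = cm.purification_ids
    rate_all = _mean_rate(cm, all_ids, off).loc[preys]
    rate_ctrl = _mean_rate(cm, control_ids, off).loc[preys] if control_ids \
        else pd.Series(0.0, index=preys)

    chr_ids = [p.id for p in design.purifications if p.fraction == "chromatin"]
    sol_ids = [p.id for p in design.purifications if p.fraction == "soluble"]
    rate_chr = _mean_rate(cm, chr_ids, off).loc[preys] if chr_ids \
        else pd.Series(0.0, index=preys)
    rate_sol = _mean_rate(cm, sol_ids, off).loc[preys] if sol_ids \
        else pd.Series(0.0, index=preys)

    atlas = pd.DataFrame({
        "prey": preys,
        "abundance": np.log(rate_all + eps).to_numpy(),
        "tf_specificity": (np.log(rate_all + eps)
                           - np.log(rate_ctrl + eps)).to_numpy(),
        "fraction_specificity": (np.log(rate_chr + eps)
                                 - np.log(rate_sol + eps)).to_numpy(),
        "mu": bg.mu.loc[preys].to_numpy(),
        "category": "",
    })
    return atlas.reset_index(drop=True)


def categorize_preys(atlas: pd.DataFrame,
                     thr: AtlasThresholds | None = None) -> pd.DataFrame:
    """Assign every atlas entry exactly one colour category.

    Rule table (ts = tf_specificity, fs = fraction_specificity):
    ts < green_band -> grey; green_band <= ts < specificity_min ->
    green; ts >= specificity_min: fs >= fraction_margin -> red,
    fs <= -fraction_margin -> blue, otherwise purple.  Total and
    deterministic.
    """
    thr = thr or AtlasThresholds()
    ts = atlas["tf_specificity"].to_numpy(dtype=float)
    fs = atlas["fraction_specificity"].to_numpy(dtype=float)
    cat = np.full(len(atlas), "purple", dtype=object)
    cat[fs >= thr.fraction_margin] = "red"
    cat[fs <= -thr.fraction_margin] = "blue"
    cat[ts < thr.specificity_min] = "green"
    cat[ts < thr.green_band] = "grey"
    out = atlas.copy()
    out["category"] = cat
    return out


def plot_atlas(atlas: pd.DataFrame, path=None):
    """Bubble plot of the atlas: x = fraction specificity, y = TF
    specificity, bubble size = abundance, colour = category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    palette = {"red": "#d62728", "purple": "#9467bd", "blue": "#1f77b4",
               "green": "#2ca02c", "grey": "#aaaaaa"}
    size = 10 + 20 * (atlas["abundance"] - atlas["abundance"].min())
    for cat, grp in atlas.groupby("category"):
        ax.scatter(grp["fraction_specificity"], grp["tf_specificity"],
                   s=size[grp.index], c=palette.get(cat, "black"),
                   alpha=0.5, label=cat, edgecolors="none")
    ax.axhline(0, lw=0.5, color="black")
    ax.axvline(0, lw=0.5, color="black")
    ax.set_xlabel("fraction specificity (chromatin > 0 > soluble)")
    ax.set_ylabel("TF-group specificity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
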