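"""Two-pool Poisson-mixture interaction scoring.

The model treats the spectral count X_ij of prey i in purification j as a
draw from a two-component Poisson mixture: a *false* (background)
component whose rate lambda_F,i is estimated from the negative-control
pool, and a *true* (interaction) component whose rate lambda_T is fitted
per bait-prey-fraction by maximum likelihood over the bait's replicates.
The interaction probability ("SAINT score") is the posterior weight of
the true component under a fixed prior pi:

    p_ij = pi * Pois(X_ij; lam_T e^{c_j})
           / [pi * Pois(X_ij; lam_T e^{c_j}) + (1-pi) * Pois(X_ij; lam_F,i e^{c_j})]

where c_j is an optional per-purification depth offset.  Replicate
probabilities are combined by mean (default) or max.

The control pool also yields the per-prey contaminant score mu_i: the log
of the prey's control-pool abundance relative to a baseline abundance.
Preys with mu_i >= 0 — as abundant in the controls as the most common
background binders — are treated as contaminants downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CountMatrix, DesignMismatchError, ExperimentDesign


@dataclass
class ScoringConfig:
    """Hyper-parameters of the mixture model.

    prior_true
        Mixing weight pi of the true-interaction component; 0.1 reflects
        that only a small minority of detected preys interact with any
        given bait.
    pseudo_count
        Added to control-count sums so background rates are strictly
        positive even for preys never seen in a control.
    normalize_by_total
        When on, per-purification depth offsets c_j = log(TSC_j / median
        TSC) put all purifications on a common depth scale; off by
        default (raw counts are modelled directly).
    length_normalize
        Optionally divide rates by prey length (off by default; spectral
        counts are only weakly length-dependent at this scale).
    fraction_stratified
        Fit separate chromatin and soluble backgrounds from
        fraction-matched controls (combined-fraction controls count in
        both pools); fractions with no matched control fall back to the
        pooled background.
    mu_baseline_quantile
        Quantile of control abundance defining the contaminant baseline:
        mu_i >= 0 flags preys in the top (1 - q) of the control-abundance
        spectrum.  Default 0.90 (top decile = common contaminants).
    replicate_combination
        How per-replicate posteriors are merged: "mean" or "max".
    """

    prior_true: float = 0.1
    pseudo_count: float = 0.1
    normalize_by_total: bool = False
    length_normalize: bool = False
    fraction_stratified: bool = True
    mu_baseline_quantile: float = 0.90
    max_em_iterations: int = 200
    convergence_tolerance: float = 1e-8
    replicate_combination: Literal["mean", "max"] = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_true < 1.0:
            raise ValueError("prior_true must be in (0, 1)")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")
        if not 0.0 < self.mu_baseline_quantile < 1.0:
            raise ValueError("mu_baseline_quantile must be in (0, 1)")
        if self.replicate_combination not in ("mean", "max"):
            raise ValueError("replicate_combination must be 'mean' or 'max'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BackgroundModel:
    """Control-pool background: per-prey false rates, offsets, mu scores.

    lambda_false: DataFrame preys x fraction labels (single column
    "pooled" when unstratified).  mu: per-prey contaminant score computed
    from the pooled control set.  experiment_offsets: c_j per
    purification (zeros unless depth normalization is on).
    """

    lambda_false: pd.DataFrame
    mu: pd.Series
    experiment_offsets: pd.Series
    baseline: float
    pooled_lambda_false: pd.Series
    prey_lengths: pd.Series = field(repr=False, default=None)

    def lambda_for(self, fraction: str) -> pd.Series:
        if fraction in self.lambda_false.columns:
            return self.lambda_false[fraction]
        return self.pooled_lambda_false


def _depth_offsets(cm: CountMatrix, cfg: ScoringConfig) -> pd.Series:
    if not cfg.normalize_by_total:
        return pd.Series(0.0, index=cm.purification_ids)
    tsc = cm.tsc().astype(float)
    if (tsc <= 0).all():
        raise ValueError("all purifications have zero total counts")
    med = float(np.median(tsc[tsc > 0]))
    off = np.log(tsc.where(tsc > 0, med) / med)
    return off.astype(float)


def _control_rates(cm: CountMatrix, controls: list, offsets: pd.Series,
                   cfg: ScoringConfig) -> pd.Series:
    ids = [p.id for p in controls]
    num = cm.counts[ids].sum(axis=1).astype(float) + cfg.pseudo_count
    den = float(np.exp(offsets[ids]).sum())
    lam = num / den
    if cfg.length_normalize:
        lam = lam / cm.lengths * float(cm.lengths.median())
    return lam


def estimate_background(cm: CountMatrix, design: ExperimentDesign,
                        cfg: ScoringConfig | None = None) -> BackgroundModel:
    """Fit the false-interaction background from the control pool.

    Raises if the design has no control purifications (the two-pool
    layout requires a control pool) or the control pool is all zeros.
    """
    cfg = cfg or ScoringConfig()
    cm.validate_against(design)
    controls = design.controls
    if not controls:
        raise DesignMismatchError(
            "no control purifications: two-pool scoring requires a "
            "control pool to estimate the background"
        )
    ctrl_ids = [p.id for p in controls]
    if cm.counts[ctrl_ids].to_numpy().sum() == 0:
        raise ValueError("control pool contains no counts; cannot "
                         "estimate a background")
    offsets = _depth_offsets(cm, cfg)

    pooled = _control_rates(cm, controls, offsets, cfg)

    lam_cols: dict[str, pd.Series] = {}
    if cfg.fraction_stratified:
        for frac in design.sample_fractions():
            fc = design.controls_for_fraction(frac)
            lam_cols[frac] = (
                _control_rates(cm, fc, offsets, cfg) if fc else pooled
            )
    if not lam_cols:
        lam_cols["pooled"] = pooled
    lambda_false = pd.DataFrame(lam_cols)

    # contaminant score: pooled control abundance vs an upper-quantile
    # baseline, restricted to preys actually observed in >= 1 control
    observed = cm.counts[ctrl_ids].sum(axis=1) > 0
    if not observed.any():
        raise ValueError("no prey observed in any control purification")
    baseline = float(np.quantile(pooled[observed], cfg.mu_baseline_quantile))
    mu = np.log(pooled) - np.log(baseline)

    return BackgroundModel(
        lambda_false=lambda_false,
        mu=mu.rename("mu"),
        experiment_offsets=offsets.rename("offset"),
        baseline=baseline,
        pooled_lambda_false=pooled.rename("lambda_false"),
        prey_lengths=cm.lengths,
    )


# ---------------------------------------------------------------------------
# mixture posterior
# ---------------------------------------------------------------------------

def mixture_posterior(x, lam_true, lam_false, prior_true: float,
                      offset=0.0) -> np.ndarray:
    """Posterior P(true | X=x) under the two-component Poisson mixture.

    Evaluated in log space for numerical stability; broadcasting follows
    numpy rules.  This closed form is the scoring primitive — the EM fit
    only supplies lam_true.
    """
    x = np.asarray(x, dtype=float)
    scale = np.exp(np.asarray(offset, dtype=float))
    lt = np.maximum(np.asarray(lam_true, dtype=float) * scale, 1e-300)
    lf = np.maximum(np.asarray(lam_false, dtype=float) * scale, 1e-300)
    log_t = np.log(prior_true) + stats.poisson.logpmf(x, lt)
    log_f = np.log1p(-prior_true) + stats.poisson.logpmf(x, lf)
    m = np.maximum(log_t, log_f)
    post = np.exp(log_t - m) / (np.exp(log_t - m) + np.exp(log_f - m))
    return post


def _fit_lambda_true(counts: np.ndarray, scales: np.ndarray,
                     lam_false: np.ndarray, cfg: ScoringConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """EM for the true-component rate, vectorized over preys.

    counts: (n_preys, n_reps); scales: (n_reps,) = e^{c_j};
    lam_false: (n_preys,).  The fitted rate is floored at 2 * lam_false
    so the true component stays the larger one.  Returns (lam_true,
    converged flags).  Deterministic: initialization is the depth-scaled
    replicate mean (at least the floor), no randomness.
    """
    floor = 2.0 * lam_false
    mean_rate = counts.sum(axis=1) / scales.sum()
    lam = np.maximum(mean_rate, floor)
    pi = cfg.prior_true
    converged = np.zeros(lam.shape, dtype=bool)
    for _ in range(cfg.max_em_iterations):
        z = mixture_posterior(counts, lam[:, None], lam_false[:, None],
                              pi, np.log(scales)[None, :])
        denom = (z * scales[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(denom > 0, (z * counts).sum(axis=1) / denom,
                           lam)
        new = np.maximum(new, floor)
        delta = np.abs(new - lam)
        lam = new
        converged = delta < cfg.convergence_tolerance
        if converged.all():
            break
    return lam, converged


def score_interactions(cm: CountMatrix, design: ExperimentDesign,
                       bg: BackgroundModel,
                       cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every candidate bait-prey-fraction interaction.

    For each sample bait b and fraction f, every prey with a non-zero
    count in at least one of the bait's replicate purifications is
    scored; all replicates (including zero-count ones) contribute to the
    combined probability.  Bait-self rows are expected to be masked
    beforehand (see :func:`fractionscope.hcip.mask_bait_self`).

    Returns a DataFrame with one row per (bait, prey, fraction):
    columns bait, prey, fraction, n_replicates, total_count,
    replicate_probabilities (comma-joined), probability, mu,
    lambda_true, lambda_false, converged.
    """
    cfg = cfg or ScoringConfig()
    cm.validate_against(design)
    missing = set(cm.prey_ids) - set(bg.mu.index)
    if missing:
        raise DesignMismatchError(
            f"preys absent from background model: {sorted(missing)[:5]}"
        )
    rows: list[dict] = []
    for bait in design.sample_baits():
        for frac in design.sample_fractions():
            purs = design.purifications_of(bait, frac)
            if not purs:
                continue
            ids = [p.id for p in purs]
            sub = cm.counts[ids]
            nz = sub.to_numpy().sum(axis=1) > 0
            if not nz.any():
                continue
            preys = sub.index[nz]
            counts = sub.loc[preys].to_numpy(dtype=float)
            scales = np.exp(bg.experiment_offsets[ids].to_numpy(dtype=float))
            lam_f = bg.lambda_for(frac).loc[preys].to_numpy(dtype=float)
            lam_t, conv = _fit_lambda_true(counts, scales, lam_f, cfg)
            degenerate = lam_t <= lam_f * (1 + 1e-12)
            probs = mixture_posterior(
                counts, lam_t[:, None], lam_f[:, None], cfg.prior_true,
                np.log(scales)[None, :],
            )
            probs = np.where(degenerate[:, None], cfg.prior_true, probs)
            if cfg.replicate_combination == "mean":
                combined = probs.mean(axis=1)
            else:
                combined = probs.max(axis=1)
            mu = bg.mu.loc[preys].to_numpy(dtype=float)
            tot = counts.sum(axis=1).astype(np.int64)
            for k, prey in enumerate(preys):
                rows.append({
                    "bait": bait,
                    "prey": prey,
                    "fraction": frac,
                    "n_replicates": len(ids),
                    "total_count": int(tot[k]),
                    "replicate_probabilities": ",".join(
                        f"{p:.12g}" for p in probs[k]
                    ),
                    "probability": float(combined[k]),
                    "mu": float(mu[k]),
                    "lambda_true": float(lam_t[k]),
                    "lambda_false": float(lam_f[k]),
                    "converged": bool(conv[k]) and not bool(degenerate[k]),
                })
    columns = ["bait", "prey", "fraction", "n_replicates", "total_count",
               "replicate_probabilities", "probability", "mu",
               "lambda_true", "lambda_false", "converged"]
    return pd.DataFrame(rows, columns=columns)
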