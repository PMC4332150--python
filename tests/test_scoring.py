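"""Background estimation and mixture scoring against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fractionscope as fs
from fractionscope.scoring import mixture_posterior


def brute_posterior(x, lam_t, lam_f, pi):
    """Independent Bayes evaluation with pure-python Poisson densities."""
    def pois(k, lam):
        return math.exp(-lam) * lam ** k / math.factorial(int(k))

    num = pi * pois(x, lam_t)
    den = num + (1 - pi) * pois(x, lam_f)
    return num / den


# ---------------------------------------------------------------------------
# background / contaminant score
# ---------------------------------------------------------------------------

class TestBackground:
    def test_mu_formula_matches_hand_calculation(self, tiny_design):
        """3-prey/4-control toy: counts {P1: 8s, P2: 1s, P3: 0s}.

        With pseudo-count 0.1 and unit offsets the control rates are
        (32.1, 4.1, 0.1) / 4; the baseline is the configured quantile
        of the rates of control-observed preys (P1, P2), and mu is the
        log-ratio to it.  Recomputed here from scratch.
        """
        preys = [fs.PreyInfo(p, 100) for p in ("P1", "P2", "P3")]
        counts = np.array([
            [0, 0, 8, 8, 8, 8],
            [0, 0, 1, 1, 1, 1],
            [0, 0, 0, 0, 0, 0],
        ])
        cm = fs.CountMatrix.from_preys(preys, tiny_design.ids, counts)
        cfg = fs.ScoringConfig(fraction_stratified=False)
        bg = fs.estimate_background(cm, tiny_design, cfg)
        lam = np.array([32.1, 4.1, 0.1]) / 4.0
        baseline = np.quantile(lam[:2], cfg.mu_baseline_quantile)
        expected = np.log(lam) - np.log(baseline)
        np.testing.assert_allclose(
            bg.mu[["P1", "P2", "P3"]].to_numpy(), expected, rtol=1e-12)
        assert bg.mu["P1"] > bg.mu["P2"] > bg.mu["P3"]

    def test_unseen_prey_has_negative_mu(self, tiny_matrix, tiny_design):
        bg = fs.estimate_background(tiny_matrix, tiny_design)
        assert bg.mu["P3"] < 0  # P3 appears in no control

    def test_no_controls_is_an_error(self):
        design = fs.ExperimentDesign([
            fs.Purification("s1", "A", "chromatin", "sample")])
        cm = fs.CountMatrix.from_preys(
            [fs.PreyInfo("P1", 100)], ["s1"], np.array([[3]]))
        with pytest.raises(fs.DesignMismatchError, match="two-pool"):
            fs.estimate_background(cm, design)

    def test_all_zero_control_pool_is_an_error(self, tiny_design):
        cm = fs.CountMatrix.from_preys(
            [fs.PreyInfo("P1", 100)], tiny_design.ids,
            np.array([[5, 5, 0, 0, 0, 0]]))
        with pytest.raises(ValueError, match="control pool"):
            fs.estimate_background(cm, tiny_design)

    def test_fraction_stratified_uses_matched_controls(self, tiny_design):
        """A prey abundant only in chromatin controls gets a higher
        chromatin background than soluble background."""
        cm = fs.CountMatrix.from_preys(
            [fs.PreyInfo("P1", 100)], tiny_design.ids,
            np.array([[0, 0, 9, 9, 1, 1]]))
        bg = fs.estimate_background(cm, tiny_design, fs.ScoringConfig())
        assert bg.lambda_for("chromatin")["P1"] > bg.lambda_for("soluble")["P1"]

    def test_combined_control_counts_in_both_fraction_pools(self):
        purs = [
            fs.Purification("s1", "A", "chromatin", "sample"),
            fs.Purification("s2", "A", "soluble", "sample"),
            fs.Purification("c1", fs.CONTROL, "chromatin", "control"),
            fs.Purification("c2", fs.CONTROL, "soluble", "control"),
            fs.Purification("c3", fs.CONTROL, "combined", "control"),
        ]
        design = fs.ExperimentDesign(purs)
        assert {p.id for p in design.controls_for_fraction("chromatin")} \
            == {"c1", "c3"}
        assert {p.id for p in design.controls_for_fraction("soluble")} \
            == {"c2", "c3"}

    def test_depth_invariance_of_mu(self):
        """Doubling every count of one control (and its TSC) leaves mu
        essentially unchanged when depth offsets are on."""
        rng = np.random.default_rng(5)
        n_ctrl = 24
        purs = [fs.Purification("s1", "A", "chromatin", "sample")] + [
            fs.Purification(f"c{k}", fs.CONTROL, "chromatin", "control")
            for k in range(n_ctrl)
        ]
        design = fs.ExperimentDesign(purs)
        preys = [fs.PreyInfo(f"P{i}", 100) for i in range(30)]
        base = rng.poisson(3.0, size=(30, n_ctrl + 1))
        cm1 = fs.CountMatrix.from_preys(preys, design.ids, base)
        doubled = base.copy()
        doubled[:, 1] *= 2  # first control purification
        cm2 = fs.CountMatrix.from_preys(preys, design.ids, doubled)
        cfg = fs.ScoringConfig(normalize_by_total=True,
                               fraction_stratified=False)
        mu1 = fs.estimate_background(cm1, design, cfg).mu
        mu2 = fs.estimate_background(cm2, design, cfg).mu
        assert np.abs(mu1 - mu2).max() < 0.1


# ---------------------------------------------------------------------------
# mixture posterior
# ---------------------------------------------------------------------------

class TestPosterior:
    def test_single_point_against_bayes(self):
        got = mixture_posterior(6, 10.0, 1.0, 0.5)
        assert abs(got - brute_posterior(6, 10.0, 1.0, 0.5)) < 1e-9

    @pytest.mark.parametrize("pi", [0.05, 0.1, 0.5, 0.9])
    @pytest.mark.parametrize("lam_t,lam_f", [
        (10.0, 1.0), (2.0, 0.1), (25.0, 0.035), (5.0, 4.0)])
    def test_grid_against_bayes(self, pi, lam_t, lam_f):
        for x in range(0, 40, 3):
            got = float(mixture_posterior(x, lam_t, lam_f, pi))
            want = brute_posterior(x, lam_t, lam_f, pi)
            assert abs(got - want) < 1e-9

    def test_offsets_scale_both_components(self):
        got = float(mixture_posterior(6, 10.0, 1.0, 0.5, offset=math.log(2)))
        want = brute_posterior(6, 20.0, 2.0, 0.5)
        assert abs(got - want) < 1e-9

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        lam_f=st.floats(1e-3, 5.0), ratio=st.floats(1.5, 50.0),
        pi=st.floats(0.01, 0.99),
    )
    def test_monotone_in_count(self, lam_f, ratio, pi):
        """With lam_true > lam_false the posterior never decreases in X."""
        xs = np.arange(0, 60)
        p = mixture_posterior(xs, lam_f * ratio, lam_f, pi)
        assert np.all(np.diff(p) >= -1e-12)


# ---------------------------------------------------------------------------
# score_interactions
# ---------------------------------------------------------------------------

class TestScoreInteractions:
    def test_zero_count_preys_not_emitted(self, tiny_matrix, tiny_design):
        bg = fs.estimate_background(tiny_matrix, tiny_design)
        scores = fs.score_interactions(tiny_matrix, tiny_design, bg)
        sol = scores[scores["fraction"] == "soluble"]
        assert "P3" not in set(sol["prey"])  # P3 only seen in chromatin
        chrom = scores[scores["fraction"] == "chromatin"]
        assert "P3" in set(chrom["prey"])

    def test_probability_consistent_with_reported_parameters(
            self, tiny_matrix, tiny_design):
        """The combined probability equals the mean of closed-form
        posteriors recomputed from the row's own fitted rates."""
        cfg = fs.ScoringConfig()
        bg = fs.estimate_background(tiny_matrix, tiny_design, cfg)
        scores = fs.score_interactions(tiny_matrix, tiny_design, bg, cfg)
        for r in scores.itertuples(index=False):
            ids = [p.id for p in
                   tiny_design.purifications_of(r.bait, r.fraction)]
            xs = tiny_matrix.counts.loc[r.prey, ids].to_numpy()
            ps = [brute_posterior(int(x), r.lambda_true, r.lambda_false,
                                  cfg.prior_true) for x in xs]
            assert abs(r.probability - np.mean(ps)) < 1e-9

    def test_cutoff_is_strict(self):
        """Of scores {0.95, 0.80, 0.50} only 0.95 clears the 0.80 cut."""
        passing = [s for s in (0.95, 0.80, 0.50) if s > 0.80]
        assert passing == [0.95]

    def test_max_replicate_combination(self, tiny_matrix, tiny_design):
        cfg_mean = fs.ScoringConfig(replicate_combination="mean")
        cfg_max = fs.ScoringConfig(replicate_combination="max")
        bg = fs.estimate_background(tiny_matrix, tiny_design, cfg_mean)
        s_mean = fs.score_interactions(tiny_matrix, tiny_design, bg, cfg_mean)
        s_max = fs.score_interactions(tiny_matrix, tiny_design, bg, cfg_max)
        merged = s_mean.merge(s_max, on=["bait", "prey", "fraction"],
                              suffixes=("_mean", "_max"))
        assert (merged["probability_max"]
                >= merged["probability_mean"] - 1e-12).all()

    def test_prey_missing_from_background_is_error(self, tiny_matrix,
                                                   tiny_design):
        bg = fs.estimate_background(tiny_matrix, tiny_design)
        bg.mu = bg.mu.drop("P1")
        with pytest.raises(fs.DesignMismatchError, match="P1"):
            fs.score_interactions(tiny_matrix, tiny_design, bg)

    def test_planted_edges_score_high(self, small_run, small_sim):
        """Edges with a 25-count true rate get probability > 0.8;
        emitted non-edges mostly do not."""
        _, _, truth = small_sim
        scores = small_run["scores"]
        keys = list(zip(scores["bait"], scores["prey"], scores["fraction"]))
        is_edge = np.array([k in truth.true_edges for k in keys])
        edge_probs = scores.loc[is_edge, "probability"]
        assert (edge_probs > 0.8).mean() > 0.95
        nonedge_probs = scores.loc[~is_edge, "probability"]
        assert (nonedge_probs > 0.8).mean() < 0.05
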