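"""Downstream comparative analyses: overlap, TSC, reproducibility,
reciprocal validation, reference overlap."""

import numpy as np
import pandas as pd
import pytest

import fractionscope as fs


def _hcips(rows):
    return pd.DataFrame(rows, columns=["bait", "prey", "fraction",
                                       "probability", "mu", "total_count",
                                       "is_bait_self"])


class TestFractionOverlap:
    def test_hand_enumeration(self):
        """chr = {(A,x),(A,y)}, sol = {(A,y),(A,z)} -> 1 pair in both."""
        t = _hcips([
            ("A", "x", "chromatin", 0.9, -1, 5, False),
            ("A", "y", "chromatin", 0.9, -1, 5, False),
            ("A", "y", "soluble", 0.9, -1, 5, False),
            ("A", "z", "soluble", 0.9, -1, 5, False),
        ])
        s = fs.fraction_overlap(t)
        assert (s.n_total, s.n_chromatin, s.n_soluble, s.n_both) \
            == (4, 2, 2, 1)
        assert s.pct_both == pytest.approx(100.0 / 3)
        assert s.n_chromatin + s.n_soluble == s.n_total

    def test_disjoint_fractions(self):
        t = _hcips([
            ("A", "x", "chromatin", 0.9, -1, 5, False),
            ("A", "y", "soluble", 0.9, -1, 5, False),
        ])
        assert fs.fraction_overlap(t).n_both == 0

    def test_self_rows_counted_in_both_self(self):
        t = _hcips([
            ("A", "A", "chromatin", np.nan, -1, 30, True),
            ("A", "A", "soluble", np.nan, -1, 20, True),
            ("A", "x", "chromatin", 0.9, -1, 5, False),
            ("A", "x", "soluble", 0.9, -1, 5, False),
        ])
        s = fs.fraction_overlap(t)
        assert s.n_both == 2 and s.n_both_self == 1

    def test_bounds_on_simulation(self, small_run):
        s = fs.fraction_overlap(small_run["hcips"])
        assert s.n_both <= min(s.n_chromatin, s.n_soluble)
        assert s.n_both_self <= s.n_both
        assert s.n_chromatin + s.n_soluble == s.n_total


class TestTscPerBait:
    def test_hand_sum(self):
        purs = [
            fs.Purification("a_chr", "A", "chromatin", "sample"),
            fs.Purification("a_sol", "A", "soluble", "sample"),
            fs.Purification("c1", fs.CONTROL, "combined", "control"),
        ]
        design = fs.ExperimentDesign(purs)
        preys = [fs.PreyInfo(p, 100) for p in ("x", "y", "z")]
        counts = np.array([[5, 0, 0], [7, 0, 0], [0, 3, 0]])
        cm = fs.CountMatrix.from_preys(preys, design.ids, counts)
        hcips = _hcips([
            ("A", "x", "chromatin", 0.9, -1, 5, False),
            ("A", "y", "chromatin", 0.9, -1, 7, False),
            ("A", "z", "soluble", 0.9, -1, 3, False),
        ])
        tsc = fs.tsc_per_bait(hcips, cm, design).set_index("fraction")
        assert tsc.loc["chromatin", "tsc"] == 12
        assert tsc.loc["soluble", "tsc"] == 3

    def test_bait_with_no_hcips_has_zero_tsc(self, small_run):
        design, cm = small_run["design"], small_run["cm"]
        empty = _hcips([])
        tsc = fs.tsc_per_bait(empty, cm, design)
        assert (tsc["tsc"] == 0).all()

    def test_unknown_bait_is_error(self, small_run):
        bad = _hcips([("NOBODY", "x", "chromatin", 0.9, -1, 5, False)])
        with pytest.raises(fs.DesignMismatchError, match="NOBODY"):
            fs.tsc_per_bait(bad, small_run["cm"], small_run["design"])

    def test_self_rows_excluded(self, small_run):
        hcips, cm, design = (small_run["hcips"], small_run["cm"],
                             small_run["design"])
        tsc_all = fs.tsc_per_bait(hcips, cm, design)
        noself = hcips[~hcips["is_bait_self"]]
        tsc_ns = fs.tsc_per_bait(noself, cm, design)
        pd.testing.assert_frame_equal(tsc_all, tsc_ns)


class TestReproducibility:
    def test_identical_tables_give_ratio_one(self):
        t = _hcips([("A", "x", "chromatin", 0.9, -1, 10, False),
                    ("A", "y", "chromatin", 0.9, -1, 3, False)])
        curve = fs.replicate_reproducibility(t, t.copy())
        assert (curve["overlap_ratio"].dropna() == 1.0).all()

    def test_disjoint_tables_give_zero(self):
        t1 = _hcips([("A", "x", "chromatin", 0.9, -1, 10, False)])
        t2 = _hcips([("A", "y", "chromatin", 0.9, -1, 10, False)])
        curve = fs.replicate_reproducibility(t1, t2)
        assert (curve["overlap_ratio"].dropna() == 0.0).all()

    def test_hand_enumerated_curve(self):
        """rep1 = {x:10, y:2}, rep2 = {x:12, z:2}: ratio 0.5 at t=2 and
        1.0 at t=10 (both directions averaged)."""
        t1 = _hcips([("A", "x", "chromatin", 0.9, -1, 10, False),
                     ("A", "y", "chromatin", 0.9, -1, 2, False)])
        t2 = _hcips([("A", "x", "chromatin", 0.9, -1, 12, False),
                     ("A", "z", "chromatin", 0.9, -1, 2, False)])
        curve = fs.replicate_reproducibility(t1, t2, thresholds=(2, 10))
        c = curve.set_index("threshold")["overlap_ratio"]
        assert c[2] == pytest.approx(0.5)
        assert c[10] == pytest.approx(1.0)

    def test_no_shared_baits_is_error(self):
        t1 = _hcips([("A", "x", "chromatin", 0.9, -1, 10, False)])
        t2 = _hcips([("B", "x", "chromatin", 0.9, -1, 10, False)])
        with pytest.raises(fs.DesignMismatchError):
            fs.replicate_reproducibility(t1, t2)

    def test_trend_statistic(self):
        curve = pd.DataFrame({"threshold": [2, 5, 10],
                              "overlap_ratio": [0.44, 0.67, 0.90],
                              "n_pairs": [10, 5, 2]})
        assert fs.reproducibility_trend(curve) == pytest.approx(1.0)


class TestReciprocal:
    def test_published_panel_recovers_14_of_16(self):
        """The 16-pair reciprocal-purification panel: 14 preys captured
        their bait; strict fraction-set intersection matches 12."""
        forward, reverse_tables, pairs = fs.make_worked_fixture(
            "reciprocal_table2")
        result = fs.reciprocal_validation(forward, reverse_tables, pairs)
        n_rec, n_matched = fs.reciprocal_counts(result)
        assert len(result) == 16
        assert n_rec == 14
        assert n_matched == 12

    def test_missing_reverse_table_flagged_not_counted(self):
        forward = _hcips([("A", "x", "chromatin", 0.9, -1, 5, False)])
        result = fs.reciprocal_validation(forward, {}, [("A", "x")])
        assert not result.loc[0, "has_reverse_table"]
        assert fs.reciprocal_counts(result) == (0, 0)

    def test_cross_fraction_recovery_not_fraction_matched(self):
        forward = _hcips([("A", "x", "chromatin", 0.9, -1, 5, False)])
        reverse = {"x": _hcips([("x", "A", "soluble", 0.9, -1, 5, False)])}
        result = fs.reciprocal_validation(forward, reverse, [("A", "x")])
        assert result.loc[0, "recovered"]
        assert not result.loc[0, "fraction_matched"]


class TestReferenceOverlap:
    hcips = _hcips([
        ("A", "x", "chromatin", 0.9, -1, 5, False),
        ("A", "y", "soluble", 0.9, -1, 5, False),
        ("B", "z", "chromatin", 0.9, -1, 5, False),
        ("B", "w", "chromatin", 0.9, -1, 5, False),
        ("B", "B", "chromatin", np.nan, -1, 30, True),
    ])

    def test_empty_reference(self):
        n_known, n_total, frac = fs.reference_overlap(self.hcips, [])
        assert (n_known, frac) == (0, 0.0)
        assert n_total == 4  # self row excluded

    def test_full_reference(self):
        ref = [("A", "x"), ("A", "y"), ("B", "z"), ("B", "w")]
        n_known, n_total, frac = fs.reference_overlap(self.hcips, ref)
        assert n_known == n_total == 4 and frac == 1.0

    def test_order_insensitive(self):
        """An edge listed prey-first still matches (undirected)."""
        n_known, _, _ = fs.reference_overlap(self.hcips, [("x", "A")])
        assert n_known == 1


def test_reproducibility_rises_with_counts_on_replicates(small_sim):
    """Splitting the replicated simulation into its two replicate halves
    and calling HCIPs per half, the overlap ratio is non-decreasing in
    the count threshold (Spearman rho >= 0)."""
    cm, design, _ = small_sim
    curves = _replicate_curve(cm, design)
    assert fs.reproducibility_trend(curves) >= 0.0


def _replicate_curve(cm, design):
    tables = []
    for rep in (1, 2):
        purs = [p for p in design.purifications
                if p.pool == "control" or p.replicate == rep]
        sub = fs.ExperimentDesign(purs)
        subcm = fs.CountMatrix(cm.counts[sub.ids], cm.lengths)
        masked, ledger = fs.mask_bait_self(subcm, sub)
        bg = fs.estimate_background(masked, sub)
        scores = fs.score_interactions(masked, sub, bg)
        tables.append(fs.call_hcips(scores, bg, ledger))
    return fs.replicate_reproducibility(tables[0], tables[1],
                                        thresholds=(2, 5, 10, 20))
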