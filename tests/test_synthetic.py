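"""Generators: determinism, planted structure, and calibration."""

import numpy as np
import pandas as pd
import pytest

from dosepath import synthetic
from dosepath.synthetic import DoseDesign, PlantedTruth


def make_truth(n_up=1, n_down=0, n_null=0, **kw):
    genes = [f"G{i}" for i in range(n_up + n_down + n_null)]
    return PlantedTruth(
        frozenset(genes[:n_up]),
        frozenset(genes[n_up : n_up + n_down]),
        frozenset(genes[n_up + n_down :]),
        **kw,
    )


class TestDoseExpression:
    def test_noise_free_profile_is_linear_in_rank(self):
        truth = make_truth(effect_size=4.0, noise_sd=0.0)
        expr = synthetic.generate_dose_expression(DoseDesign(), truth, seed=0)
        np.testing.assert_allclose(
            expr.loc["G0"].to_numpy(), [4 / 3, 8 / 3, 4.0]
        )

    def test_down_genes_mirror_up_genes(self):
        truth = make_truth(n_up=1, n_down=1, effect_size=3.0, noise_sd=0.0)
        expr = synthetic.generate_dose_expression(DoseDesign(), truth, seed=0)
        np.testing.assert_allclose(
            expr.loc["G1"].to_numpy(), -expr.loc["G0"].to_numpy()
        )

    def test_deterministic_given_seed(self):
        truth = make_truth(n_up=5, n_down=5, n_null=20)
        a = synthetic.generate_dose_expression(DoseDesign(), truth, seed=7)
        b = synthetic.generate_dose_expression(DoseDesign(), truth, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = synthetic.generate_dose_expression(DoseDesign(), truth, seed=8)
        assert not a.equals(c)

    def test_null_genes_centred_at_zero(self):
        truth = make_truth(n_up=0, n_down=0, n_null=2000, noise_sd=0.5)
        expr = synthetic.generate_dose_expression(DoseDesign(), truth, seed=1)
        assert abs(expr.to_numpy().mean()) < 0.05

    @pytest.mark.parametrize(
        "levels", [(0.0, 1.25), (0.0, 5.0, 1.25, 20.0), (1.0, 2.0, 3.0)]
    )
    def test_invalid_designs_rejected(self, levels):
        with pytest.raises(ValueError):
            DoseDesign(dose_levels=levels)

    def test_overlapping_truth_sets_rejected(self):
        with pytest.raises(ValueError):
            PlantedTruth(frozenset("a"), frozenset("a"), frozenset())

    def test_replicates_expand_columns(self):
        design = DoseDesign(replicate_count=2)
        truth = make_truth(noise_sd=0.0)
        expr = synthetic.generate_dose_expression(design, truth, seed=0)
        assert list(expr.columns) == [
            "1.25_r1", "1.25_r2", "5_r1", "5_r2", "20_r1", "20_r2",
        ]


class TestGeneSets:
    UNIVERSE = [f"G{i}" for i in range(5000)]

    def test_zero_overlap_gives_disjoint_sets(self):
        coll = synthetic.generate_gene_sets(
            self.UNIVERSE, 20, (10, 30), 0.0, 0.0, seed=1
        )
        seen = set()
        for members in coll.values():
            assert not (set(members) & seen)
            seen |= set(members)

    def test_zero_repressor_fraction_gives_all_activators(self):
        coll = synthetic.generate_gene_sets(
            self.UNIVERSE, 10, (10, 30), 0.2, 0.0, seed=2
        )
        assert all(s == 1 for m in coll.values() for s in m.values())
        coll = synthetic.generate_gene_sets(
            self.UNIVERSE, 10, (10, 30), 0.2, 1.0, seed=2
        )
        assert all(s == -1 for m in coll.values() for s in m.values())

    def test_mean_pairwise_jaccard_tracks_overlap_fraction(self):
        from dosepath.similarity import jaccard_matrix

        coll = synthetic.generate_gene_sets(
            self.UNIVERSE, 50, (20, 80), 0.2, 0.0, seed=11
        )
        j = jaccard_matrix(coll).to_numpy()
        off = j[~np.eye(len(j), dtype=bool)]
        assert abs(off.mean() - 0.2) < 0.1

    def test_sizes_respect_range_and_determinism(self):
        a = synthetic.generate_gene_sets(self.UNIVERSE, 9, (5, 9), 0.3, 0.5, seed=3)
        b = synthetic.generate_gene_sets(self.UNIVERSE, 9, (5, 9), 0.3, 0.5, seed=3)
        assert a == b
        assert all(5 <= len(m) <= 9 for m in a.values())

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_gene_sets(self.UNIVERSE, 0, (5, 9), 0.0, 0.0, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_gene_sets(self.UNIVERSE, 5, (9, 5), 0.0, 0.0, seed=1)


class TestTopology:
    def test_zero_density_gives_zero_matrix(self):
        topo = synthetic.generate_topology(list("abcde"), 0.0, 0.5, seed=1)
        assert not topo.b_matrix.any()
        assert topo.spectral_radius == 0.0

    def test_single_edge_normalization(self):
        topo = synthetic.PathwayTopology(
            genes=["g1", "g2"], beta=np.array([[0.0, 0.0], [1.0, 0.0]])
        )
        expected = np.array([[0.0, 0.0], [1.0, 0.0]])
        np.testing.assert_array_equal(topo.b_matrix, expected)

    def test_columns_normalized_by_out_degree(self):
        topo = synthetic.generate_topology(
            [f"g{i}" for i in range(30)], 0.3, 0.6, seed=5
        )
        col_abs = np.abs(topo.b_matrix).sum(axis=0)
        has_out = np.count_nonzero(topo.beta, axis=0) > 0
        np.testing.assert_allclose(col_abs[has_out], 1.0)
        np.testing.assert_allclose(col_abs[~has_out], 0.0)

    def test_i_minus_b_invertible_at_moderate_density(self):
        topo = synthetic.generate_topology(
            [f"g{i}" for i in range(30)], 0.1, 0.5, seed=3
        )
        n = len(topo.genes)
        rng = np.random.default_rng(0)
        de = rng.normal(size=n)
        pf = np.linalg.solve(np.eye(n) - topo.b_matrix, de)
        resid = np.max(np.abs((np.eye(n) - topo.b_matrix) @ pf - de))
        assert resid < 1e-8


class TestSurvival:
    def test_null_median_matches_exponential_closed_form(self):
        cohort = synthetic.generate_survival(
            None, {}, 0.5, 0.0, 4000, seed=9, extra_genes=["X"]
        )
        expected = np.log(2) / 0.5
        assert abs(np.median(cohort["time"]) - expected) / expected < 0.1

    def test_zero_censor_rate_gives_all_events(self):
        cohort = synthetic.generate_survival(
            None, {"G1": 0.5}, 0.2, 0.0, 100, seed=1
        )
        assert (cohort["event"] == 1).all()

    def test_censor_rate_calibrated_under_null(self):
        cohort = synthetic.generate_survival(
            None, {}, 0.2, 0.4, 4000, seed=2, extra_genes=["X"]
        )
        assert abs((1 - cohort["event"].mean()) - 0.4) < 0.05

    def test_risk_coefficient_recovered_by_cox(self):
        from dosepath.survival import cox_univariate

        cohort = synthetic.generate_survival(
            None, {"G1": np.log(2)}, 0.1, 0.0, 1000, seed=3
        )
        _, hr, _ = cox_univariate(
            cohort["G1"], cohort["time"], cohort["event"], p_method="wald"
        )
        assert 1.8 <= hr <= 2.2

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_survival(None, {}, -1.0, 0.0, 100, seed=1)
        with pytest.raises(ValueError):
            synthetic.generate_survival(None, {}, 1.0, 0.0, 10, seed=1)


def test_reciprocal_study_is_deterministic_and_consistent():
    a = synthetic.generate_reciprocal_study(seed=5, n_genes=500)
    b = synthetic.generate_reciprocal_study(seed=5, n_genes=500)
    pd.testing.assert_frame_equal(a["expr"], b["expr"])
    assert a["collection"] == b["collection"]
    truth = a["truth"]
    for name, members in a["collection"].items():
        fam = a["set_family"][name]
        pool = {
            "metabolic": truth.down_genes,
            "signaling": truth.up_genes,
            "null": truth.null_genes,
        }[fam]
        assert set(members) <= pool
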