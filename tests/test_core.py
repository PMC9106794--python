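"""Network construction core: partial correlations, residuals, Z-scores, strength."""

import numpy as np
import pytest

from petnet import (
    CohortTable,
    CorrelationNetwork,
    RegionSet,
    ResidualNetwork,
    SubjectRecord,
    ZScoreNetwork,
    default_region_set,
    edge_significance,
    node_strength,
    partial_corr_network,
    perturbed_network,
    residual_network,
    score_subject,
    zscore_network,
)
from petnet.networks import from_upper_triangle, upper_triangle
from scipy import stats

from _oracles import partial_corr_oracle, zcc_oracle
from conftest import make_cohort


def _corrnet(matrix, region_set, n=24):
    return CorrelationNetwork(matrix=matrix, region_set=region_set, n_subjects=n)


class TestPartialCorrNetwork:
    def test_duplicated_region_gives_perfect_edge(self, abc_regions):
        """A region duplicating another survives residualisation with r = 1."""
        rng = np.random.default_rng(3)
        base = rng.uniform(1, 5, size=8)
        subjects = tuple(
            SubjectRecord(
                subject_id=f"S{i}",
                age=30.0 + i,
                sex=i % 2,
                suv={"A": base[i], "B": base[i], "C": float(rng.uniform(1, 5))},
            )
            for i in range(8)
        )
        net = partial_corr_network(CohortTable(subjects, abc_regions))
        assert net.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_fixed_integer_table_matches_oracle(self, abc_regions):
        """Fixed 6x3 integer table, ages 40..45, alternating sex: long-hand oracle."""
        suv = np.array(
            [[4, 7, 2], [5, 6, 3], [6, 8, 2], [4, 9, 5], [7, 5, 4], [5, 7, 6]],
            dtype=float,
        )
        subjects = tuple(
            SubjectRecord(
                subject_id=f"S{i}",
                age=40.0 + i,
                sex=i % 2,
                suv=dict(zip("ABC", suv[i])),
            )
            for i in range(6)
        )
        cohort = CohortTable(subjects, abc_regions)
        net = partial_corr_network(cohort)
        expected = partial_corr_oracle(cohort.suv_matrix, cohort.covariates)
        np.testing.assert_allclose(net.matrix, expected, atol=1e-12, rtol=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_cohorts_match_oracle(self, seed):
        """Vectorised construction equals pairwise residualize-then-Pearson."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 31))
        m = int(rng.integers(3, 11))
        regions = RegionSet(tuple(f"R{k}" for k in range(m)))
        cohort = make_cohort(n, regions, seed=seed + 100)
        net = partial_corr_network(cohort)
        expected = partial_corr_oracle(cohort.suv_matrix, cohort.covariates)
        np.testing.assert_allclose(net.matrix, expected, atol=1e-12, rtol=0)
        assert np.allclose(net.matrix, net.matrix.T, atol=1e-12)

    def test_default_parcellation_bookkeeping(self):
        """24 controls x 18 regions: symmetric matrix with 153 unique edges."""
        cohort = make_cohort(24, default_region_set(), seed=5)
        net = partial_corr_network(cohort)
        assert net.matrix.shape == (18, 18)
        assert net.n_subjects == 24
        assert upper_triangle(net.matrix).size == 153

    def test_too_few_subjects_rejected(self, abc_regions):
        with pytest.raises(ValueError, match="at least 5 subjects"):
            partial_corr_network(make_cohort(4, abc_regions))

    def test_collinear_covariates_rejected(self, abc_regions):
        subjects = tuple(
            SubjectRecord(
                subject_id=f"S{i}", age=50.0, sex=1, suv={"A": i + 1.0, "B": 2.0 * i + 1, "C": 7.0 - i}
            )
            for i in range(8)
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_corr_network(CohortTable(subjects, abc_regions))

    def test_covariate_coding_invariance(self, abc_regions):
        """Flipping the sex code or affinely rescaling age leaves the network unchanged."""
        cohort = make_cohort(10, abc_regions, seed=2)
        net = partial_corr_network(cohort)
        flipped = CohortTable(
            tuple(
                SubjectRecord(s.subject_id, s.age * 2.5 + 7.0, 1 - s.sex, s.suv)
                for s in cohort.subjects
            ),
            abc_regions,
        )
        net2 = partial_corr_network(flipped)
        np.testing.assert_allclose(net.matrix, net2.matrix, atol=1e-10, rtol=0)

    def test_subject_order_invariance(self, abc_regions):
        cohort = make_cohort(12, abc_regions, seed=4)
        rng = np.random.default_rng(0)
        permuted = cohort.subset(rng.permutation(12))
        np.testing.assert_allclose(
            partial_corr_network(cohort).matrix,
            partial_corr_network(permuted).matrix,
            atol=1e-12,
            rtol=0,
        )


class TestPerturbedNetwork:
    def test_equals_network_on_augmented_cohort(self, small_cohort):
        subject = SubjectRecord(
            "NEW", 55.0, 1, {r: 2.0 + i for i, r in enumerate(small_cohort.region_set)}
        )
        ptb = perturbed_network(small_cohort, subject)
        direct = partial_corr_network(small_cohort.with_subject(subject))
        np.testing.assert_array_equal(ptb.matrix, direct.matrix)
        assert ptb.n_subjects == small_cohort.n_subjects + 1

    def test_duplicate_row_distinct_id_is_valid(self, small_cohort):
        twin = small_cohort.subjects[0]
        clone = SubjectRecord("CLONE", twin.age, twin.sex, twin.suv)
        ptb = perturbed_network(small_cohort, clone)
        assert np.all(np.isfinite(ptb.matrix))

    def test_duplicate_id_rejected(self, small_cohort):
        dup = small_cohort.subjects[0]
        with pytest.raises(ValueError, match="already in cohort"):
            perturbed_network(small_cohort, dup)


class TestResidualNetwork:
    def test_identical_networks_give_zero(self, abc_regions):
        net = _corrnet(from_upper_triangle([0.5, 0.2, -0.1], 3), abc_regions)
        for frac in (0.0, 0.3, 1.0):
            res = residual_network(net, net, frac)
            assert np.all(res.matrix == 0.0)

    def test_zero_threshold_is_identity(self, abc_regions):
        ptb = _corrnet(from_upper_triangle([0.5, 0.2, 0.1], 3), abc_regions)
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = residual_network(ptb, ref, 0.0)
        np.testing.assert_array_equal(res.matrix, ptb.matrix)

    def test_relative_threshold_hand_case(self, abc_regions):
        """Entries {0.5, 0.2, 0.1} at 30%: cut is 0.15, so 0.1 dies, 0.2 survives."""
        ptb = _corrnet(from_upper_triangle([0.5, 0.2, 0.1], 3), abc_regions)
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = residual_network(ptb, ref, 0.3)
        np.testing.assert_array_equal(
            upper_triangle(res.matrix), np.array([0.5, 0.2, 0.0])
        )

    def test_boundary_tie_is_retained(self, abc_regions):
        """|raw| exactly at the cut survives (strict < for elimination)."""
        ptb = _corrnet(from_upper_triangle([1.0, 0.3, 0.1], 3), abc_regions)
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = residual_network(ptb, ref, 0.3)
        np.testing.assert_array_equal(
            upper_triangle(res.matrix), np.array([1.0, 0.3, 0.0])
        )

    def test_absolute_mode(self, abc_regions):
        ptb = _corrnet(from_upper_triangle([0.5, 0.2, 0.1], 3), abc_regions)
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = residual_network(ptb, ref, 0.3, mode="absolute")
        np.testing.assert_array_equal(
            upper_triangle(res.matrix), np.array([0.5, 0.0, 0.0])
        )

    def test_threshold_monotonicity(self, abc_regions):
        """Raising the threshold never increases any |resNET| entry or any STR."""
        rng = np.random.default_rng(11)
        edges = rng.uniform(-0.5, 0.5, size=3)
        ptb = _corrnet(from_upper_triangle(edges, 3), abc_regions)
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        prev_abs = None
        prev_str = None
        for frac in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            res = residual_network(ptb, ref, frac)
            cur_abs = np.abs(upper_triangle(res.matrix))
            zcc = zscore_network(res, ref, n_group=25)
            cur_str = node_strength(zcc).as_array()
            if prev_abs is not None:
                assert np.all(cur_abs <= prev_abs + 1e-15)
                assert np.all(cur_str <= prev_str + 1e-12)
            prev_abs, prev_str = cur_abs, cur_str

    def test_region_mismatch_rejected(self, abc_regions):
        other = RegionSet(("X", "Y", "Z"))
        a = _corrnet(np.zeros((3, 3)), abc_regions)
        b = _corrnet(np.zeros((3, 3)), other)
        with pytest.raises(ValueError, match="different regions"):
            residual_network(a, b, 0.3)


class TestZScoreNetwork:
    def test_zero_residual_gives_zero_z(self, abc_regions):
        ref = _corrnet(from_upper_triangle([0.5, -0.3, 0.2], 3), abc_regions)
        res = ResidualNetwork(np.zeros((3, 3)), abc_regions, 0.3)
        zcc = zscore_network(res, ref, n_group=25)
        assert np.all(zcc.matrix == 0.0)

    def test_zero_reference_scaling(self, abc_regions):
        """With refNET = 0 and N = 25 the Z-score is 24 times the residual."""
        d = 0.125
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = ResidualNetwork(from_upper_triangle([d, 0.0, 0.0], 3), abc_regions, 0.0)
        zcc = zscore_network(res, ref, n_group=25)
        assert zcc.matrix[0, 1] == pytest.approx(24.0 * d, abs=1e-15)

    def test_random_matrices_match_scalar_oracle(self):
        regions = RegionSet(tuple("VWXYZ"))
        rng = np.random.default_rng(21)
        ref_edges = rng.uniform(-0.9, 0.9, size=10)
        res_edges = rng.uniform(-0.4, 0.4, size=10)
        ref = _corrnet(from_upper_triangle(ref_edges, 5), regions)
        res = ResidualNetwork(from_upper_triangle(res_edges, 5), regions, 0.0)
        zcc = zscore_network(res, ref, n_group=25)
        expected = zcc_oracle(res.matrix, ref.matrix, 25)
        np.testing.assert_allclose(zcc.matrix, expected, atol=1e-12, rtol=0)

    def test_saturated_reference_edge_is_named(self, abc_regions):
        ref = _corrnet(from_upper_triangle([1.0, 0.0, 0.0], 3), abc_regions)
        res = ResidualNetwork(np.zeros((3, 3)), abc_regions, 0.0)
        with pytest.raises(ValueError, match=r"\('A', 'B'\)"):
            zscore_network(res, ref, n_group=25)

    def test_sqrt_variant(self, abc_regions):
        ref = _corrnet(from_upper_triangle([0.6, 0.0, 0.0], 3), abc_regions)
        res = ResidualNetwork(from_upper_triangle([0.2, 0.0, 0.0], 3), abc_regions, 0.0)
        z = zscore_network(res, ref, n_group=25, sqrt_denominator=True)
        expected = 0.2 / np.sqrt((1 - 0.36) / 24)
        assert z.matrix[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_small_group_rejected(self, abc_regions):
        ref = _corrnet(np.zeros((3, 3)), abc_regions)
        res = ResidualNetwork(np.zeros((3, 3)), abc_regions, 0.0)
        with pytest.raises(ValueError, match="n_group"):
            zscore_network(res, ref, n_group=3)


class TestNodeStrength:
    def test_null_network(self, abc_regions):
        zcc = ZScoreNetwork(np.zeros((3, 3)), abc_regions, 25)
        strength = node_strength(zcc)
        assert strength.as_array().tolist() == [0.0, 0.0, 0.0]
        assert strength.summed_strength == 0.0

    def test_single_negative_edge_divisor(self, abc_regions):
        """STR averages |ZCC| over M-1 neighbours: one edge of -3 at M=3."""
        zcc = ZScoreNetwork(from_upper_triangle([-3.0, 0.0, 0.0], 3), abc_regions, 25)
        strength = node_strength(zcc)
        assert strength.values["A"] == pytest.approx(1.5)
        assert strength.values["B"] == pytest.approx(1.5)
        assert strength.values["C"] == 0.0

    def test_constant_magnitude_18_regions(self):
        """All off-diagonal |ZCC| = c makes every STR equal c (divisor 17)."""
        regions = default_region_set()
        c = 2.75
        zcc = ZScoreNetwork(
            from_upper_triangle(np.full(153, -c), 18), regions, 25
        )
        strength = node_strength(zcc)
        np.testing.assert_allclose(strength.as_array(), c, rtol=1e-15)
        assert strength.summed_strength == pytest.approx(18 * c)

    def test_zero_strength_iff_all_incident_edges_zero(self, abc_regions):
        zcc = ZScoreNetwork(from_upper_triangle([2.0, 0.0, 0.0], 3), abc_regions, 25)
        strength = node_strength(zcc)
        assert strength.values["C"] == 0.0
        assert strength.values["A"] > 0 and strength.values["B"] > 0


class TestEdgeSignificance:
    def test_null_z_flags_nothing(self, abc_regions):
        zcc = ZScoreNetwork(np.zeros((3, 3)), abc_regions, 25)
        for alpha in (0.5, 0.05, 0.001):
            assert edge_significance(zcc, alpha).n_significant == 0

    def test_bonferroni_critical_value_18_regions(self):
        """alpha = 0.01 over 153 edges: critical z is the 1 - 0.01/306 quantile."""
        regions = default_region_set()
        zcc = ZScoreNetwork(np.zeros((18, 18)), regions, 25)
        sig = edge_significance(zcc, alpha=0.01)
        assert sig.n_tests == 153
        assert sig.critical_z == pytest.approx(stats.norm.ppf(1 - 0.01 / 306), rel=1e-12)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_single_extreme_edge_flagged(self, sign):
        regions = default_region_set()
        edges = np.zeros(153)
        edges[0] = sign * 10.0
        zcc = ZScoreNetwork(from_upper_triangle(edges, 18), regions, 25)
        sig = edge_significance(zcc, alpha=0.01)
        assert sig.n_significant == 1
        assert sig.significant_edges() == [regions.edge_pairs()[0]]


class TestScoreSubject:
    def test_pipeline_outputs_are_symmetric(self, small_cohort):
        subject = SubjectRecord(
            "NEW", 48.0, 0, {r: 3.0 + 0.5 * i for i, r in enumerate(small_cohort.region_set)}
        )
        zcc, strength = score_subject(small_cohort, subject)
        assert np.allclose(zcc.matrix, zcc.matrix.T, atol=1e-12)
        assert zcc.n_group == small_cohort.n_subjects + 1
        assert strength.summed_strength >= 0.0

    def test_precomputed_reference_matches(self, small_cohort):
        subject = SubjectRecord(
            "NEW", 48.0, 0, {r: 2.5 for r in small_cohort.region_set}
        )
        ref = partial_corr_network(small_cohort)
        z1, _ = score_subject(small_cohort, subject)
        z2, _ = score_subject(small_cohort, subject, ref=ref)
        np.testing.assert_array_equal(z1.matrix, z2.matrix)
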