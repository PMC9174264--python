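"""Shannon diversity, content summaries, Bray-Curtis, PCoA, ellipses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from periobiome.diversity import (
    bray_curtis_matrix,
    compare_content,
    confidence_ellipse,
    group_content_summary,
    pcoa,
    restrict_species_for_pcoa,
    shannon_index,
)

from conftest import make_abundance_table


class TestShannon:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5, 0, 0], 0.0),
            ([0.5, 0.25, 0.25], 1.0397207708399179),  # -sum p ln p by hand
        ],
    )
    def test_known_values(self, vec, expected):
        assert shannon_index(vec) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])

    @settings(max_examples=50, deadline=None)
    @given(
        vec=st.lists(st.floats(0.01, 100), min_size=2, max_size=20),
        k=st.floats(0.1, 50),
        seed=st.integers(0, 10_000),
    )
    def test_scale_and_permutation_invariance(self, vec, k, seed):
        x = np.array(vec)
        h = shannon_index(x)
        assert shannon_index(k * x) == pytest.approx(h, rel=1e-10)
        perm = np.random.default_rng(seed).permutation(x)
        assert shannon_index(perm) == pytest.approx(h, rel=1e-10)

    def test_uniform_attains_log_s_exactly(self):
        for s in range(2, 65):
            assert abs(shannon_index(np.ones(s)) - np.log(s)) < 1e-12


class TestContentSummary:
    def test_constant_group_has_point_interval(self):
        at = make_abundance_table({"a": [5.0, 5.0, 5.0]}, groups=["G", "G", "G"])
        row = group_content_summary(at, "bacteria").iloc[0]
        assert row["mean_rpm"] == row["ci_low"] == row["ci_high"] == 5.0

    def test_interval_matches_t_quantile(self):
        at = make_abundance_table({"a": [1.0, 2.0, 3.0]}, groups=["G"] * 3)
        row = group_content_summary(at, "bacteria").iloc[0]
        half = sps.t.ppf(0.975, 2) * 1.0 / np.sqrt(3)  # s = 1 for (1,2,3)
        assert row["mean_rpm"] == pytest.approx(2.0)
        assert row["ci_high"] - row["mean_rpm"] == pytest.approx(half, rel=1e-6)
        assert half == pytest.approx(4.302653 / np.sqrt(3), rel=1e-5)

    def test_absent_kingdom_gives_zero_totals(self):
        at = make_abundance_table({"a": [1.0, 2.0]}, groups=["G", "G"], kingdom="bacteria")
        row = group_content_summary(at, "virus").iloc[0]
        assert row["mean_rpm"] == 0.0

    def test_single_sample_group_rejected(self):
        at = make_abundance_table({"a": [1.0, 2.0, 3.0]}, groups=["G", "G", "H"])
        with pytest.raises(ValueError, match="H"):
            group_content_summary(at, "bacteria")


class TestCompareContent:
    def test_identical_groups(self):
        r = compare_content([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0

    def test_closed_form_example(self):
        r = compare_content([1, 2, 3], [2, 3, 4])
        assert r.t == pytest.approx(-1.224745, abs=1e-6)
        assert r.df == 4
        assert r.p == pytest.approx(0.287885, abs=1e-4)

    def test_swap_negates_t_keeps_p(self):
        a, b = [1.0, 2.5, 3.0], [2.0, 4.0, 4.5]
        r1, r2 = compare_content(a, b), compare_content(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)


class TestRestrictSpecies:
    @pytest.mark.parametrize("mean,kept", [(600.0, False), (499.0, True), (500.0, False)])
    def test_cap_is_strict(self, mean, kept):
        at = make_abundance_table({"sp": [mean, mean], "other": [10, 10]})
        out, removed = restrict_species_for_pcoa(at)
        assert ("sp" in out.taxon_ids) is kept
        assert ("sp" in removed) is not kept

    def test_genus_rows_not_touched(self):
        at = make_abundance_table({"g": [900.0, 900.0]}, level="genus")
        out, removed = restrict_species_for_pcoa(at)
        assert out.taxon_ids == ["g"] and removed == []


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        at = make_abundance_table({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert bray_curtis_matrix(at).iloc[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        at = make_abundance_table({"a": [1.0, 0.0], "b": [0.0, 3.0]})
        assert bray_curtis_matrix(at).iloc[0, 1] == 1.0

    def test_hand_value(self):
        at = make_abundance_table({"a": [2.0, 1.0], "b": [2.0, 3.0]})
        assert bray_curtis_matrix(at).iloc[0, 1] == pytest.approx(0.25)

    def test_all_zero_sample_rejected(self):
        at = make_abundance_table({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        with pytest.raises(ValueError, match="s2"):
            bray_curtis_matrix(at)

    def test_bounded_and_symmetric(self, default_study):
        from periobiome.tables import filter_low_abundance, normalize_rpm

        at = filter_low_abundance(normalize_rpm(default_study["counts"]))
        d = bray_curtis_matrix(at).to_numpy()
        assert np.all(d >= 0) and np.all(d <= 1)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0, atol=1e-12)


class TestPcoa:
    def test_two_points(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        res = pcoa(d)
        assert res.n_positive == 1
        np.testing.assert_allclose(sorted(res.coordinates["PC1"]), [-0.4, 0.4], atol=1e-12)

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(d)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        np.testing.assert_allclose(pos[0], pos[1], rtol=1e-10)
        np.testing.assert_allclose(res.proportion_explained, [0.5, 0.5], atol=1e-10)

    def test_collinear_points_single_axis_reproduces_distances(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(d)
        assert res.n_positive == 1
        x = res.coordinates["PC1"].to_numpy()
        recon = np.abs(x[:, None] - x[None, :])
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_euclidean_input_reconstructs(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(12, 4))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = squareform(pdist(coords))
        np.testing.assert_allclose(recon, d, atol=1e-8)
        assert res.proportion_explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_scikit_bio(self):
        """Independent cross-check of the classical-scaling decomposition."""
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(10, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        ours = pcoa(d)
        theirs = skbio_ord.pcoa(d, method="eigh")
        k = ours.n_positive
        np.testing.assert_allclose(
            ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-8,
        )

    def test_reordering_invariance_up_to_sign(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(8, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        perm = rng.permutation(8)
        res1 = pcoa(d)
        res2 = pcoa(d[np.ix_(perm, perm)])
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
        c1 = res1.coordinates.to_numpy()[perm]
        c2 = res2.coordinates.to_numpy()
        for k in range(c1.shape[1]):
            assert np.allclose(c1[:, k], c2[:, k], atol=1e-8) or np.allclose(
                c1[:, k], -c2[:, k], atol=1e-8
            )

    def test_eigenvalue_sum_equals_centered_trace(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        res = pcoa(d)
        n = d.shape[0]
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d * d) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-8)

    @pytest.mark.parametrize(
        "bad",
        [np.array([[0.0, 1.0], [2.0, 0.0]]), np.array([[1.0, 1.0], [1.0, 0.0]])],
        ids=["asymmetric", "nonzero-diagonal"],
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            pcoa(bad)


class TestConfidenceEllipse:
    CHI2_95 = 5.991464547107979  # chi2.ppf(0.95, 2)

    def test_identity_covariance_circle(self):
        # 4 points engineered so the sample covariance is exactly I
        s = np.sqrt(1.5)
        pts = np.array([[s, 0], [-s, 0], [0, s], [0, -s]])
        e = confidence_ellipse(pts)
        assert not e.degenerate
        np.testing.assert_allclose(e.semi_axes, np.sqrt(self.CHI2_95), rtol=1e-10)
        assert np.sqrt(self.CHI2_95) == pytest.approx(2.4477, abs=1e-4)

    def test_diag_4_1_covariance(self):
        s = np.sqrt(1.5)
        pts = np.array([[2 * s, 0], [-2 * s, 0], [0, s], [0, -s]])
        e = confidence_ellipse(pts)
        np.testing.assert_allclose(
            e.semi_axes, [2 * np.sqrt(self.CHI2_95), np.sqrt(self.CHI2_95)], rtol=1e-10
        )
        assert e.angle == pytest.approx(0.0, abs=1e-10)

    def test_collinear_points_degenerate(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert confidence_ellipse(pts).degenerate

    def test_center_is_mean(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(20, 2))
        e = confidence_ellipse(pts)
        np.testing.assert_allclose(e.center, pts.mean(axis=0), atol=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))
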