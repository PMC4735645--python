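"""Group statistics: distances, regressions, Fisher z, mixed ANOVA."""

import numpy as np
import pytest

from phasegraph import (bundled_montage, compare_correlations,
                        compare_regression_slopes, cross_frequency_coupling,
                        distance_regression, edgewise_group_map, fisher_z,
                        group_band_anova, physical_distance)


class TestPhysicalDistance:
    def test_pythagoras(self):
        d = physical_distance(np.array([[0, 0, 0], [3, 4, 0]], float))
        assert np.isclose(d[0, 1], 5.0)
        assert d[0, 0] == 0.0

    def test_identical_points(self):
        d = physical_distance(np.zeros((2, 3)))
        assert d[0, 1] == 0.0

    def test_montage_elementwise_oracle(self):
        _, coords = bundled_montage("1020-19")
        d = physical_distance(coords)
        for i in range(19):
            for j in range(19):
                expected = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
                assert abs(d[i, j] - expected) <= 1e-12


class TestDistanceRegression:
    def _p(self):
        _, coords = bundled_montage("1020-19")
        return physical_distance(coords)

    def test_exact_linear(self):
        p = self._p()
        values = 2.0 - 0.01 * p
        res = distance_regression(values, p)
        assert np.isclose(res.r, -1.0)
        assert np.isclose(res.slope, -0.01)
        assert res.n == 171

    def test_infinite_exclusion_bookkeeping(self):
        p = self._p()
        values = 1.0 + 0.02 * p
        values[0, 1] = values[1, 0] = np.inf
        values[3, 7] = values[7, 3] = np.inf
        res = distance_regression(values, p)
        assert res.n == 169 and res.n_excluded == 2

    def test_too_few_edges(self):
        p = physical_distance(np.eye(3))
        values = np.full((3, 3), np.inf)
        with pytest.raises(ValueError):
            distance_regression(values, p)

    def test_null_p_uniform(self):
        """Distance-independent values: p roughly uniform over seeds."""
        p = self._p()
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            values = rng.uniform(size=(19, 19))
            values = (values + values.T) / 2
            pvals.append(distance_regression(values, p).p)
        assert 0.01 < np.mean(np.array(pvals) < 0.5) < 0.99
        assert np.mean(np.array(pvals) < 0.05) < 0.12


class TestCompareRegressionSlopes:
    def _p(self):
        _, coords = bundled_montage("1020-19")
        return physical_distance(coords)

    def test_identical_groups_t_zero(self):
        p = self._p()
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(19, 19))
        v = (v + v.T) / 2
        res = compare_regression_slopes(v, p, v, p)
        assert abs(res.t) < 1e-10

    def test_planted_slope_difference(self):
        p = self._p()
        rng = np.random.default_rng(1)
        noise = 0.01 * rng.standard_normal((19, 19))
        noise = (noise + noise.T) / 2
        va = 1.0 + 0.001 * p + noise
        vb = 1.0 + 0.004 * p + noise
        res = compare_regression_slopes(va, p, vb, p)
        assert res.t > 0 and res.p < 0.01
        assert np.isclose(res.slope_diff, 0.003, atol=5e-4)

    def test_label_swap_negates(self):
        p = self._p()
        rng = np.random.default_rng(2)
        va = rng.uniform(size=(19, 19)); va = (va + va.T) / 2
        vb = rng.uniform(size=(19, 19)); vb = (vb + vb.T) / 2
        r1 = compare_regression_slopes(va, p, vb, p)
        r2 = compare_regression_slopes(vb, p, va, p)
        assert np.isclose(r1.t, -r2.t) and np.isclose(r1.p, r2.p)


class TestFisherZ:
    def test_hand_values(self):
        z, se = fisher_z(0.5, 103)
        assert np.isclose(z, 0.54931, atol=1e-5)
        assert np.isclose(se, 0.1)
        assert fisher_z(0.0, 10)[0] == 0.0

    def test_antisymmetry(self):
        assert np.isclose(fisher_z(-0.3, 20)[0], -fisher_z(0.3, 20)[0])

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_z(1.0, 10)
        with pytest.raises(ValueError):
            fisher_z(0.5, 3)


class TestCompareCorrelations:
    def test_equal_correlations(self):
        z, p = compare_correlations(0.4, 50, 0.4, 80)
        assert z == 0.0 and np.isclose(p, 1.0)

    def test_hand_value(self):
        z, p = compare_correlations(0.5, 103, 0.0, 103)
        assert np.isclose(z, 0.54931 / np.sqrt(0.02), atol=1e-3)  # ~3.884
        assert p < 0.001

    def test_group_swap_negates(self):
        z1, p1 = compare_correlations(0.6, 40, 0.2, 60)
        z2, p2 = compare_correlations(0.2, 60, 0.6, 40)
        assert np.isclose(z1, -z2) and np.isclose(p1, p2)


class TestCrossFrequency:
    def _sym(self, rng, n=19):
        m = rng.uniform(1, 5, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        return m

    def test_identical_matrices_r_one(self):
        d = self._sym(np.random.default_rng(3))
        res = cross_frequency_coupling(d, d)
        assert np.isclose(res.r, 1.0)
        assert res.n == 171

    def test_antimonotone_r_minus_one(self):
        d = self._sym(np.random.default_rng(4))
        res = cross_frequency_coupling(d, 10.0 - d)
        assert np.isclose(res.r, -1.0)

    def test_matches_direct_pearson(self):
        rng = np.random.default_rng(5)
        a, b = self._sym(rng), self._sym(rng)
        res = cross_frequency_coupling(a, b)
        iu = np.triu_indices(19, 1)
        expected = np.corrcoef(a[iu], b[iu])[0, 1]
        assert np.isclose(res.r, expected, atol=1e-12)

    def test_infinite_edges_intersected(self):
        rng = np.random.default_rng(6)
        a, b = self._sym(rng), self._sym(rng)
        a[0, 1] = a[1, 0] = np.inf
        b[2, 3] = b[3, 2] = np.inf
        res = cross_frequency_coupling(a, b)
        assert res.n == 169


class TestEdgewiseMap:
    def _setup(self, n=10):
        rng = np.random.default_rng(7)
        w = rng.uniform(0.3, 0.6, size=(n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        from phasegraph import functional_distance, weight_to_length
        d = functional_distance(weight_to_length(w))
        return w, d

    def test_identical_groups_no_significant(self):
        w, d = self._setup()
        res = edgewise_group_map(w, w, d, d, 100, 100, alpha_level=0.05)
        assert res.n_a_longer == 0 and res.n_b_longer == 0
        assert res.n_not_significant == 45

    def test_single_weakened_edge_flagged(self):
        from phasegraph import functional_distance, weight_to_length
        w, _ = self._setup()
        wa = w.copy()
        wa[0, 1] = wa[1, 0] = 0.1
        wb = w.copy()
        wb[0, 1] = wb[1, 0] = 0.8
        da = functional_distance(weight_to_length(wa))
        db = functional_distance(weight_to_length(wb))
        res = edgewise_group_map(wa, wb, da, db, 500, 500)
        assert res.map[0, 1] == 1  # group A's distance is longer
        assert res.n_a_longer == 1 and res.n_b_longer == 0
        # direct z verification on the flagged edge
        z_hand = (np.arctanh(0.1) - np.arctanh(0.8)) / np.sqrt(2 / 497)
        assert np.isclose(res.z[0, 1], z_hand)

    def test_partition_sums_to_edge_count(self):
        w, d = self._setup()
        rng = np.random.default_rng(8)
        wb = np.clip(w + 0.1 * rng.standard_normal(w.shape), 0.01, 0.95)
        wb = (wb + wb.T) / 2
        np.fill_diagonal(wb, 0.0)
        res = edgewise_group_map(w, wb, d, d + 1.0, 200, 200)
        assert (res.n_a_longer + res.n_b_longer
                + res.n_not_significant) == 45


class TestGroupBandAnova:
    def test_identical_groups(self):
        rng = np.random.default_rng(9)
        vals = rng.standard_normal((10, 8))
        res = group_band_anova(vals, vals.copy())
        assert res.group.f < 1e-20
        assert res.interaction.f < 1e-20
        assert all(c.p_one_tailed > 0.49 for c in res.contrasts)

    def test_constant_offset_main_effect_only(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((12, 8))
        res = group_band_anova(base, base + 5.0)
        assert res.group.p < 1e-6
        assert res.interaction.f < 1e-20

    def test_single_band_offset_interaction(self):
        rng = np.random.default_rng(11)
        a = 0.1 * rng.standard_normal((12, 8))
        b = 0.1 * rng.standard_normal((12, 8))
        b[:, 2] += 3.0
        names = [f"b{k}" for k in range(8)]
        res = group_band_anova(a, b, band_names=names)
        assert res.interaction.p < 1e-6
        sig = [c.band for c in res.contrasts if c.p_one_tailed < 0.05]
        assert sig == ["b2"]
        assert res.contrasts[2].direction == "B>A"

    def test_against_pingouin_oracle(self):
        """Split-plot F and p agree with an independent implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        a = rng.standard_normal((9, 4)) + np.array([0, 0.5, 1.0, 0.2])
        b = rng.standard_normal((9, 4)) + 0.8
        res = group_band_anova(a, b, band_names=list("wxyz"))

        rows = []
        for g, arr in (("A", a), ("B", b)):
            for s in range(arr.shape[0]):
                for k, band in enumerate("wxyz"):
                    rows.append((f"{g}{s}", g, band, arr[s, k]))
        df = pd.DataFrame(rows, columns=["subj", "group", "band", "value"])
        table = pingouin.mixed_anova(df, dv="value", within="band",
                                     subject="subj", between="group")
        f_group = table.loc[table.Source == "group", "F"].item()
        f_inter = table.loc[table.Source == "Interaction", "F"].item()
        p_group = table.loc[table.Source == "group", "p_unc"].item()
        assert np.isclose(res.group.f, f_group, rtol=1e-8)
        assert np.isclose(res.interaction.f, f_inter, rtol=1e-8)
        assert np.isclose(res.group.p, p_group, rtol=1e-6)

    def test_unbalanced_band_structure_rejected(self):
        with pytest.raises(ValueError):
            group_band_anova(np.ones((4, 8)), np.ones((4, 7)))
        bad = np.ones((4, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            group_band_anova(bad, np.ones((4, 8)))
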