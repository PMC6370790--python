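"""Shape classification, spatial GLS, Tukey contrasts and the full model
battery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import studentized_range

from melanomap.lightness import SpeciesTrait
from melanomap.stats import (fit_gls_spatial, fit_shape_models,
                             gaussian_correlation, manhattan_distances,
                             table1_battery, tukey_side_family)


def trait(sid, dorsal, ventral, family="Pieridae"):
    return SpeciesTrait(species_id=sid, family=family,
                        lightness_dorsal=dorsal, lightness_ventral=ventral,
                        n_images_dorsal=1, n_images_ventral=1)


class TestFitShapeModels:
    def test_exact_linear_relationship(self):
        x = np.linspace(0, 10, 50)
        rec = fit_shape_models(2 * x, x)
        assert rec.shape == "linear"
        assert rec.linear_sign == "+"
        assert rec.linear_r2 == pytest.approx(1.0)
        assert rec.delta_r2 == pytest.approx(0.0, abs=1e-10)

    def test_centred_parabola_is_u_shaped(self):
        x = np.linspace(-5, 5, 51)        # symmetric design
        rec = fit_shape_models((x - x.mean()) ** 2, x)
        assert rec.shape == "U"
        assert rec.linear_r2 == pytest.approx(0.0, abs=1e-10)
        assert rec.quad_r2 == pytest.approx(1.0)
        assert rec.delta_r2 == pytest.approx(1.0)

    def test_inverted_parabola_is_hump_shaped(self):
        x = np.linspace(-5, 5, 51)
        rec = fit_shape_models(-(x ** 2), x)
        assert rec.shape == "hump"
        assert rec.quad_sign == "-"

    def test_noisy_negative_slope_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 10, size=500)
        y = -x + rng.normal(0, 1, size=500)
        rec = fit_shape_models(y, x)
        assert rec.linear_sign == "-"
        assert rec.shape == "linear"
        xc, yc = x - x.mean(), y - y.mean()
        r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        assert rec.linear_r2 == pytest.approx(r2, abs=1e-10)

    def test_delta_threshold_is_strict(self):
        # construct y = 3 z + q with orthogonal unit-variance z, q so that
        # delta r2 = 1/10 exactly, then place the threshold at the measured
        # delta: "larger than" must not classify the boundary as quadratic
        x = np.linspace(-5, 5, 101)
        z = (x - x.mean()) / x.std()
        q = z * z - np.mean(z * z)
        q = q / q.std() * z.std()
        y = 3 * z + q
        rec = fit_shape_models(y, x)
        assert rec.delta_r2 == pytest.approx(0.1, abs=1e-12)
        boundary = fit_shape_models(y, x, delta_threshold=rec.delta_r2)
        assert boundary.shape == "linear"
        below = fit_shape_models(y, x, delta_threshold=rec.delta_r2 - 1e-9)
        assert below.shape == "U"

    def test_insignificant_relationship_is_ns(self, rng):
        x = rng.uniform(0, 1, size=100)
        y = rng.normal(size=100)          # pure noise
        rec = fit_shape_models(y, x)
        assert rec.shape == "n.s."

    def test_quadratic_r2_never_below_linear(self, rng):
        for _ in range(25):
            x = rng.uniform(-3, 3, size=40)
            y = rng.normal(size=40)
            rec = fit_shape_models(y, x, alpha=0.5)
            assert rec.quad_r2 >= rec.linear_r2 - 1e-10
            assert rec.delta_r2 >= 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="10 cells"):
            fit_shape_models(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="variance"):
            fit_shape_models(np.full(20, 3.0), np.arange(20.0))


class TestGLS:
    @staticmethod
    def simulate(n, rho_true, seed, slope=1.0, iid_sd=0.5):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 1000, size=(n, 2))
        d = manhattan_distances(coords)
        C = gaussian_correlation(d, rho_true)
        w, V = np.linalg.eigh(C)
        eps = V @ (np.sqrt(np.clip(w, 0, None)) * rng.normal(size=n))
        x = rng.normal(size=n)
        y = 2.0 + slope * x + eps + iid_sd * rng.normal(size=n)
        return y, x, coords

    def test_two_point_correlation_formula(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        d = manhattan_distances(coords)
        assert d[0, 1] == 7.0
        rho = 10.0
        C = gaussian_correlation(d, rho)
        assert C[0, 1] == pytest.approx(np.exp(-(7.0 / rho) ** 2))

    def test_independent_errors_close_to_ols(self):
        rng = np.random.default_rng(5)
        n = 150
        coords = rng.uniform(0, 1000, size=(n, 2))
        x = rng.normal(size=n)
        y = 1.0 + 0.8 * x + rng.normal(size=n)
        rec = fit_gls_spatial(y, x, coords)
        z = (x - x.mean()) / x.std()
        ols = sm.OLS(y, sm.add_constant(z)).fit()
        assert abs(rec.params[1] - ols.params[1]) < 2 * ols.bse[1]

    def test_range_recovery_within_factor_two(self):
        rhos = []
        for s in range(5):
            y, x, coords = self.simulate(150, 100.0, s)
            rec = fit_gls_spatial(y, x, coords, seed=s, nugget=True)
            rhos.append(rec.rho_km)
        med = np.median(rhos)
        assert 50.0 <= med <= 200.0

    def test_subsampling_recorded(self):
        y, x, coords = self.simulate(120, 50.0, 0)
        rec = fit_gls_spatial(y, x, coords, max_n=80, seed=1)
        assert rec.subsampled
        assert rec.n_cells_used == 80

    def test_duplicate_coordinates_are_handled(self):
        rng = np.random.default_rng(2)
        n = 60
        coords = np.repeat(rng.uniform(0, 100, size=(n // 2, 2)), 2, axis=0)
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        rec = fit_gls_spatial(y, x, coords,
                              cell_ids=[f"c{i}" for i in range(n)])
        assert rec.converged


class TestTukey:
    def test_constructed_offset_detected(self, rng):
        traits = [trait(f"s{i}", 100.0 + rng.normal(0, 1e-3),
                        130.0 + rng.normal(0, 1e-3)) for i in range(20)]
        contrasts = tukey_side_family(traits, continent="syn")
        allc = [c for c in contrasts if c.family_scope == "all"][0]
        assert allc.difference == pytest.approx(30.0, abs=0.01)
        assert allc.p_adj < 1e-6

    def test_three_balanced_groups_match_studentized_range_oracle(self):
        # by-hand studentized-range computation for a one-way layout
        from melanomap.stats import tukey_hsd_pairwise
        g1 = np.array([10.0, 12.0, 11.0, 13.0])
        g2 = np.array([15.0, 16.0, 14.0, 17.0])
        g3 = np.array([20.0, 22.0, 21.0, 19.0])
        values = np.concatenate([g1, g2, g3])
        groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4, dtype=object)
        padj = tukey_hsd_pairwise(values, groups)
        msw = sum(((g - g.mean()) ** 2).sum() for g in (g1, g2, g3)) / 9
        for (a, b), pair in [((g1, g2), ("a", "b")), ((g1, g3), ("a", "c")),
                             ((g2, g3), ("b", "c"))]:
            qstat = abs(a.mean() - b.mean()) / np.sqrt(msw / 4)
            p_oracle = studentized_range.sf(qstat, 3, 9)
            assert padj[pair] == pytest.approx(p_oracle, abs=1e-10)

    def test_pairwise_p_values_match_statsmodels(self, rng):
        # independent cross-check against the reference implementation
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        from melanomap.stats import tukey_hsd_pairwise
        values = rng.normal(size=30)
        groups = np.array([f"g{i % 3}" for i in range(30)], dtype=object)
        mine = tukey_hsd_pairwise(values, groups)
        ref = pairwise_tukeyhsd(values, groups)
        import itertools
        gu = [str(g) for g in ref.groupsunique]
        for (i, j), p in zip(itertools.combinations(range(len(gu)), 2),
                             np.atleast_1d(ref.pvalues)):
            assert mine[(gu[i], gu[j])] == pytest.approx(float(p), abs=1e-6)

    def test_small_groups_excluded_with_warning(self):
        traits = [trait("a", 100, 130, "Pieridae"),
                  trait("b", 105, 135, "Pieridae"),
                  trait("c", 110, 140, "Pieridae"),
                  trait("d", 120, 150, "Lycaenidae")]   # singleton family
        with pytest.warns(UserWarning, match="excluded"):
            contrasts = tukey_side_family(traits)
        assert all(c.family_scope != "Lycaenidae" for c in contrasts)

    def test_null_false_positive_rate_quick(self):
        # 200 replicates of 4 null groups: FWER should hover near alpha
        rng = np.random.default_rng(11)
        hits = 0
        reps = 200
        for _ in range(reps):
            traits = [trait(f"s{i}", 100 + rng.normal(0, 10),
                            100 + rng.normal(0, 10),
                            family=["Pieridae", "Lycaenidae"][i % 2])
                      for i in range(24)]
            contrasts = tukey_side_family(traits)
            if any(c.p_adj < 0.05 for c in contrasts
                   if c.family_scope != "all"):
                hits += 1
        rate = hits / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)


class TestBattery:
    @staticmethod
    def make_tables(rng, n_cells=60, families=("Pieridae", "Lycaenidae"),
                    missing_family=None):
        cells = [f"r0c{i}" for i in range(n_cells)]
        tmp = np.linspace(-5, 25, n_cells)
        env = pd.DataFrame({"cell_id": cells, "TMP": tmp,
                            "INS": 150 + 5 * tmp + rng.normal(0, 5, n_cells),
                            "HUM": 75 - tmp + rng.normal(0, 1, n_cells)})
        rows = []
        for side in ("dorsal", "ventral"):
            for scope in ("all",) + tuple(families):
                if scope == missing_family:
                    continue
                y = 100 + 2 * tmp + rng.normal(0, 3, n_cells)
                for cid, v in zip(cells, y):
                    rows.append({"cell_id": cid, "side": side,
                                 "family_scope": scope, "mean_lightness": v,
                                 "n_species": 6})
        return pd.DataFrame(rows), env

    def test_full_two_continent_design_has_sixty_records(self, rng):
        asm_a, env_a = self.make_tables(rng)
        asm_b, env_b = self.make_tables(rng)
        families = ["Pieridae", "Lycaenidae", "Nymphalidae", "Papilionidae"]
        records = table1_battery({"A": asm_a, "B": asm_b},
                                 {"A": env_a, "B": env_b},
                                 ["A", "B"], families)
        assert len(records) == 60
        ok = [r for r in records if r.status == "ok"]
        # two families were never generated: absent, not silently skipped
        absent = [r for r in records if r.status == "absent"]
        assert len(ok) + len(absent) == 60
        assert {r.family_scope for r in absent} == {"Nymphalidae",
                                                    "Papilionidae"}

    def test_positive_coupling_recovers_positive_linear_tmp(self, rng):
        asm, env = self.make_tables(rng)
        records = table1_battery({"A": asm}, {"A": env}, ["A"],
                                 ["Pieridae", "Lycaenidae"])
        rec = [r for r in records if r.family_scope == "all"
               and r.side == "ventral" and r.variable == "TMP"][0]
        assert rec.linear_sign == "+"
        assert rec.shape == "linear"
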