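"""Screening, averaging, r-squared, and held-out validation behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pcptox as p
from pcptox.design import AssayCondition, StudyDesign, training_abiotic_grid
from pcptox.evaluation import prediction_band
from pcptox.inhibition import inhibition_to_frame
from pcptox.kinetics import slopes_to_frame


def rank_formula_rho(x, y):
    """Independent oracle: Pearson correlation of average ranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_monotone_series(self):
        x = [1, 2, 3, 4, 5]
        assert p.spearman(x, [10, 20, 30, 40, 50])[0] == pytest.approx(1.0)
        assert p.spearman(x, [50, 40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_hand_case_against_rank_formula(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        # exhaustive rank formula: 1 - 6 * sum(d^2) / (n (n^2 - 1)) = 1 - 24/120
        rho, _ = p.spearman(x, y)
        assert rho == pytest.approx(0.8)
        assert rho == pytest.approx(rank_formula_rho(x, y))

    @settings(max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(-100, 100), st.floats(-100, 100)),
            min_size=5, max_size=25, unique_by=lambda t: t[0],
        )
    )
    def test_matches_rank_oracle_and_monotone_invariance(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data])
        if np.ptp(y) == 0:
            return
        rho, _ = p.spearman(x, y)
        assert rho == pytest.approx(rank_formula_rho(x, y), abs=1e-12)
        # strictly monotone transform of x leaves rho unchanged
        rho2, _ = p.spearman(np.exp(x / 100.0), y)
        assert rho2 == pytest.approx(rho, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 4"):
            p.spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            p.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestScreening:
    def _control_design(self):
        return StudyDesign(
            "controls",
            [AssayCondition(ab, 0.0, r)
             for ab in training_abiotic_grid() for r in (1, 2, 3)],
        )

    def test_conductivity_excluded_ph_temp_retained(self, calib):
        # Monte Carlo over 100 seeded repetitions of the 81-well control plate
        design = self._control_design()
        n_cond_ns, n_ph_sig, n_temp_sig = 0, 0, 0
        for rep in range(100):
            ds = p.simulate_study(design, calib, p.NoiseModel(), seed=30_000 + rep)
            df = slopes_to_frame(p.fit_all(ds))
            res = p.screen_factors(df, "slope_au")
            tab = res.table.set_index("factor")
            n_cond_ns += not tab.loc["conductivity_ms_cm", "significant"]
            n_ph_sig += bool(tab.loc["ph", "significant"])
            n_temp_sig += bool(tab.loc["temperature_c", "significant"])
        assert n_cond_ns >= 90
        assert n_ph_sig >= 99
        assert n_temp_sig >= 99

    def test_null_response_type_i_error_near_alpha(self):
        # response independent of all factors: each factor rejected at ~5%
        design = self._control_design()
        grid = pd.DataFrame(
            [(c.abiotic.ph, c.abiotic.temperature_c, c.abiotic.conductivity_ms_cm)
             for c in design],
            columns=["ph", "temperature_c", "conductivity_ms_cm"],
        )
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(100):
            df = grid.copy()
            df["resp"] = rng.normal(size=len(df))
            res = p.screen_factors(df, "resp")
            rejections += int(res.table["significant"].sum())
        # 300 independent tests at alpha 0.05: expect ~15; 4-sigma band
        assert 2 <= rejections <= 31

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"ph": [5.0] * 10, "temperature_c": np.arange(10.0),
                           "conductivity_ms_cm": np.arange(10.0),
                           "resp": np.arange(10.0)})
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            p.screen_factors(df, "resp")


class TestAveraging:
    def test_conductivity_averaging_triples_replication(self, noisy_slope_df):
        controls = noisy_slope_df[noisy_slope_df["pcp_mg_l"] == 0]
        out = p.average_over_factor(controls, "conductivity_ms_cm", "slope_au")
        assert len(out) == 9  # 3 pH x 3 temperature cells
        assert (out["n"] == 9).all()  # 3 replicates x 3 conductivities

    def test_means_match_grouping_oracle(self, noisy_slope_df):
        controls = noisy_slope_df[noisy_slope_df["pcp_mg_l"] == 0]
        out = p.average_over_factor(controls, "conductivity_ms_cm", "slope_au")
        want = controls.groupby(["ph", "temperature_c"])["slope_au"].mean()
        for row in out.itertuples():
            assert row.slope_au == pytest.approx(want.loc[(row.ph, row.temperature_c)])

    def test_single_level_factor_is_identity_on_values(self, noisy_slope_df):
        controls = noisy_slope_df[
            (noisy_slope_df["pcp_mg_l"] == 0) & (noisy_slope_df["replicate"] == 1)
        ]
        sub = controls[controls["conductivity_ms_cm"] == 8.13]
        out = p.average_over_factor(sub, "conductivity_ms_cm", "slope_au")
        assert sorted(out["slope_au"]) == sorted(sub["slope_au"])
        assert (out["n"] == 1).all()


class TestRSquared:
    def test_perfect_and_affine(self):
        obs = np.array([1.0, 2.0, 4.0, 8.0])
        assert p.r_squared(obs, obs) == pytest.approx(1.0)
        assert p.r_squared(obs, 3.0 - 2.0 * obs) == pytest.approx(1.0)

    def test_hand_case_matches_covariance_oracle(self):
        obs = np.array([1.0, 2.0, 3.0, 5.0])
        pred = np.array([1.2, 1.8, 3.5, 4.4])
        cov = np.cov(obs, pred, ddof=1)
        want = cov[0, 1] ** 2 / (cov[0, 0] * cov[1, 1])
        assert p.r_squared(obs, pred) == pytest.approx(want, rel=1e-12)
        assert p.r_squared(pred, obs) == pytest.approx(want, rel=1e-12)  # symmetry

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            p.r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_residual_r2_penalizes_bias(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        pred = obs + 10.0
        assert p.r_squared(obs, pred) == pytest.approx(1.0)
        assert p.r_squared_residual(obs, pred) < 0


class TestValidate:
    @pytest.fixture(scope="class")
    @staticmethod
    def effect_model(noisy_inhibition_df):
        feats = ["ph", "temperature_c", "conductivity_ms_cm", "pcp_mg_l"]
        search = p.MLPArchitectureSearch(random_state=33, n_restarts=3,
                                         output_bounds=(0.0, 1.0))
        return search.fit(noisy_inhibition_df[feats].to_numpy(float),
                          noisy_inhibition_df["inhibition"].to_numpy(float)).best_model_

    def test_leakage_guard(self, effect_model, noisy_inhibition_df):
        train_abiotics = {
            tuple(r) for r in noisy_inhibition_df[
                ["ph", "temperature_c", "conductivity_ms_cm"]
            ].drop_duplicates().to_numpy()
        }
        with pytest.raises(ValueError, match="overlap"):
            p.validate(effect_model, noisy_inhibition_df,
                       training_abiotics=train_abiotics)

    def test_noise_free_validation_recovers_surface(self, calib, validation_design,
                                                    clean_inhibition_df):
        feats = ["ph", "temperature_c", "conductivity_ms_cm", "pcp_mg_l"]
        search = p.MLPArchitectureSearch(random_state=34, output_bounds=(0.0, 1.0))
        model = search.fit(clean_inhibition_df[feats].to_numpy(float),
                           clean_inhibition_df["inhibition"].to_numpy(float)).best_model_
        ds = p.simulate_study(validation_design, calib, p.NoiseModel(0.0, 0.0), seed=0)
        vinh = inhibition_to_frame(p.pair_with_controls(p.fit_all(ds)))
        report = p.validate(model, vinh)
        assert report.r2 >= 0.98
        assert len(report.table) == len(vinh)

    def test_prediction_band_brackets_centre(self):
        rng = np.random.default_rng(12)
        obs = rng.uniform(0, 1, 80)
        pred = obs + rng.normal(0, 0.05, 80)
        band = prediction_band(obs, pred)
        assert (band["lower"] < band["fit"]).all()
        assert (band["upper"] > band["fit"]).all()
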