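"""Trait assembly: PGLS with Pagel's lambda, predictor selection, phalanx
IV-4 filling, wingspan computation and the estimation cascade."""

import math

import numpy as np
import pandas as pd
import pytest

import copetrend as ct
from copetrend.errors import ValidationError
from copetrend.synthetic import make_ultrametric


@pytest.fixture(scope="module")
def ultra_tree():
    return make_ultrametric(ct.simulate_tree(30, 100.0, seed=31, root_age=120.0))


def felsenstein_contrast_slope(tree, x, y):
    """Independent-contrasts regression through the origin (the oracle)."""

    def contrasts(vals):
        v = {t.id: (vals[t.label], t.length) for t in tree.tips()}
        out = []
        for node in tree.postorder():
            if node.is_tip:
                continue
            (x1, b1), (x2, b2) = v[node.children[0].id], v[node.children[1].id]
            out.append((x1 - x2) / math.sqrt(b1 + b2))
            anc = (x1 / b1 + x2 / b2) / (1 / b1 + 1 / b2)
            v[node.id] = (anc, (node.length or 0.0) + b1 * b2 / (b1 + b2))
        return np.array(out)

    cx, cy = contrasts(x), contrasts(y)
    return float(cx @ cy / (cx @ cx))


class TestPglsFit:
    def test_lambda_zero_equals_ols_exactly(self, fossil_tree):
        rng = np.random.default_rng(1)
        x = {t: float(rng.normal()) for t in fossil_tree.tip_labels()}
        y = {t: 1.0 + 0.5 * x[t] + float(rng.normal(0, 0.3)) for t in x}
        fit = ct.pgls_fit(x, y, fossil_tree, "fixed0")
        xa = np.array([x[t] for t in fossil_tree.tip_labels()])
        ya = np.array([y[t] for t in fossil_tree.tip_labels()])
        slope, intercept = np.polyfit(xa, ya, 1)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.lam == 0.0

    def test_lambda_one_equals_contrasts_slope(self):
        t6 = make_ultrametric(ct.simulate_tree(6, 80.0, seed=9, root_age=100.0))
        rm = ct.single_regime_map(t6)
        x = ct.simulate_trait(t6, rm, {"all": ct.OUParams(0.0, 0.01, 0.0)}, 0.0, seed=3)
        y = ct.simulate_trait(t6, rm, {"all": ct.OUParams(0.0, 0.01, 0.0)}, 0.0, seed=4)
        fit = ct.pgls_fit(x.values, y.values, t6, "fixed1")
        oracle = felsenstein_contrast_slope(t6, x.values, y.values)
        assert fit.slope == pytest.approx(oracle, rel=1e-10)

    def test_r2_bounded_for_fixed_lambdas(self, ultra_tree):
        rng = np.random.default_rng(7)
        labels = ultra_tree.tip_labels()
        x = {t: float(rng.normal()) for t in labels}
        y = {t: float(rng.normal()) for t in labels}  # no relationship
        for mode in ("fixed0", "fixed1"):
            fit = ct.pgls_fit(x, y, ultra_tree, mode)
            assert 0.0 <= fit.r2 <= 1.0

    def test_ml_lambda_recovers_brownian_signal(self, ultra_tree):
        rm = ct.single_regime_map(ultra_tree)
        hits = 0
        for r in range(20):
            x = ct.simulate_trait(ultra_tree, rm, {"all": ct.OUParams(0.0, 0.002, 0.0)},
                                  0.0, seed=100 + r)
            resid = ct.simulate_trait(ultra_tree, rm, {"all": ct.OUParams(0.0, 0.001, 0.0)},
                                      0.0, seed=200 + r)
            y = {t: 0.8 * x.values[t] + resid.values[t] for t in x.values}
            fit = ct.pgls_fit(x.values, y, ultra_tree, "ml")
            hits += 0.6 <= fit.lam <= 1.3
        assert hits >= 15  # n = 30 tips; lambda is noisy but centered at 1

    def test_needs_three_complete_cases(self, fossil_tree):
        labels = fossil_tree.tip_labels()[:2]
        x = {t: 1.0 for t in labels}
        with pytest.raises(ValidationError):
            ct.pgls_fit(x, x, fossil_tree, "fixed0")


class TestSelectPredictor:
    def test_zero_noise_predictor_ranks_first(self, ultra_tree):
        rng = np.random.default_rng(3)
        labels = ultra_tree.tip_labels()
        y = {t: float(rng.normal()) for t in labels}
        perfect = {t: 2.0 * y[t] + 1.0 for t in labels}
        noisy = {t: y[t] + float(rng.normal(0, 1.0)) for t in labels}
        fits = ct.select_predictor({"noisy": noisy, "perfect": perfect}, y, ultra_tree)
        assert fits[0].predictor == "perfect"
        assert fits[0].r2 == pytest.approx(1.0, abs=1e-9)

    def test_identical_candidates_keep_input_order(self, ultra_tree):
        rng = np.random.default_rng(4)
        labels = ultra_tree.tip_labels()
        y = {t: float(rng.normal()) for t in labels}
        x = {t: y[t] + float(rng.normal(0, 0.5)) for t in labels}
        fits = ct.select_predictor({"first": x, "second": dict(x)}, y, ultra_tree)
        assert [f.predictor for f in fits] == ["first", "second"]

    def test_lambda_choice_tracks_signal_structure(self, ultra_tree):
        # phylogenetic predictor-response pairs should prefer lambda = 1;
        # white-noise pairs lambda = 0 (the Table-2-style dichotomy)
        rm = ct.single_regime_map(ultra_tree)
        labels = ultra_tree.tip_labels()
        phylo_wins = white_wins = 0
        n_rep = 40
        for r in range(n_rep):
            xp = ct.simulate_trait(ultra_tree, rm, {"all": ct.OUParams(0.0, 0.002, 0.0)},
                                   0.0, seed=300 + r)
            ep = ct.simulate_trait(ultra_tree, rm, {"all": ct.OUParams(0.0, 0.0005, 0.0)},
                                   0.0, seed=400 + r)
            yp = {t: 1.2 * xp.values[t] + ep.values[t] for t in labels}
            f0 = ct.pgls_fit(xp.values, yp, ultra_tree, "fixed0")
            f1 = ct.pgls_fit(xp.values, yp, ultra_tree, "fixed1")
            phylo_wins += f1.aicc < f0.aicc

            rng = np.random.default_rng(500 + r)
            xw = {t: float(rng.normal()) for t in labels}
            yw = {t: 1.2 * xw[t] + float(rng.normal(0, 0.5)) for t in labels}
            g0 = ct.pgls_fit(xw, yw, ultra_tree, "fixed0")
            g1 = ct.pgls_fit(xw, yw, ultra_tree, "fixed1")
            white_wins += g0.aicc < g1.aicc
        assert phylo_wins >= 0.8 * n_rep
        assert white_wins >= 0.8 * n_rep

    def test_empty_candidate_set_rejected(self, ultra_tree):
        with pytest.raises(ValidationError):
            ct.select_predictor({}, {}, ultra_tree)


def _table_from_rows(rows):
    df = pd.DataFrame(rows)
    for col in ct.ELEMENTS + ["rescale_factor", "age_max", "age_min"]:
        if col not in df.columns:
            df[col] = np.nan
    df["rescale_factor"] = df["rescale_factor"].fillna(1.0)
    df["age_max"] = df["age_max"].fillna(100.0)
    df["age_min"] = df["age_min"].fillna(100.0)
    if "status" not in df.columns:
        df["status"] = "adult"
    cols = ["taxon"] + ct.ELEMENTS + ["status", "rescale_factor", "age_max", "age_min"]
    return ct.MeasurementTable(df[cols])


class TestComputeWingspan:
    def test_worked_sum(self):
        row = pd.Series(
            {"humerus": 100.0, "ulna": 200.0, "mcIV": 150.0, "phIV1": 250.0,
             "phIV2": 220.0, "phIV3": 180.0, "phIV4": 60.0, "rescale_factor": 1.0}
        )
        value, se = ct.compute_wingspan(row)
        assert value == pytest.approx(math.log10(1.160), abs=1e-12)
        assert se == 0.0

    def test_rescale_factor_is_log_additive(self):
        row = pd.Series(
            {"humerus": 100.0, "ulna": 200.0, "mcIV": 150.0, "phIV1": 250.0,
             "phIV2": 220.0, "phIV3": 180.0, "phIV4": 60.0, "rescale_factor": 2.0}
        )
        value, _ = ct.compute_wingspan(row)
        assert value == pytest.approx(math.log10(1.160) + math.log10(2.0), abs=1e-12)

    def test_missing_element_not_computable(self):
        row = pd.Series(
            {"humerus": 100.0, "ulna": np.nan, "mcIV": 150.0, "phIV1": 250.0,
             "phIV2": 220.0, "phIV3": 180.0, "phIV4": 60.0, "rescale_factor": 1.0}
        )
        assert ct.compute_wingspan(row) is None


class TestEstimatePhalanx4:
    def test_observed_values_untouched_and_idempotent(self, study_dataset):
        tree, _, _, _, _, meas = study_dataset
        adults = ct.filter_adults(meas)
        filled = ct.estimate_phalanx4(adults, tree, exclude=())
        obs = adults.data["phIV4"].notna()
        pd.testing.assert_series_equal(
            filled.data.loc[obs, "phIV4"], adults.data.loc[obs, "phIV4"]
        )
        again = ct.estimate_phalanx4(filled, tree, exclude=())
        pd.testing.assert_frame_equal(again.data, filled.data)

    def test_records_without_phiv3_pass_through(self, study_dataset):
        tree, _, _, _, _, meas = study_dataset
        filled = ct.estimate_phalanx4(meas, tree, exclude=())
        no_pred = meas.data["phIV4"].isna() & meas.data["phIV3"].isna()
        assert filled.data.loc[no_pred, "phIV4"].isna().all()

    def test_filled_values_unbiased_on_synthetic_truth(self):
        # elements are exact proportions of the wing sum when element noise
        # is zero, so the generative IV-4 ~ IV-3 line is known
        scenario = ct.SimScenario(n_tips=60, seed=77)
        tree = ct.simulate_tree(60, 160.0, seed=77, root_age=228.0)
        rm = ct.scenario_regime_map(tree, scenario)
        traits = ct.simulate_trait(tree, rm, scenario.regimes, 0.0, seed=77)
        full = ct.simulate_measurements(tree, traits, scenario)
        holed = ct.apply_missingness(full, {"phIV4": 0.4}, seed=78)
        filled = ct.estimate_phalanx4(holed, tree, exclude=())
        was_missing = holed.data["phIV4"].isna()
        err = np.log10(filled.data.loc[was_missing, "phIV4"].to_numpy()) - np.log10(
            full.data.loc[was_missing, "phIV4"].to_numpy()
        )
        assert len(err) >= 10
        assert abs(err.mean()) < 2 * err.std(ddof=1) / math.sqrt(len(err))


class TestCascade:
    def test_engineered_tiers_give_expected_provenance(self):
        rng = np.random.default_rng(11)
        # training block: 10 complete taxa spanning a size range
        rows = []
        spans = np.geomspace(400, 8000, 10)  # mm
        fracs = {"humerus": 0.11, "ulna": 0.16, "mcIV": 0.13, "phIV1": 0.22,
                 "phIV2": 0.17, "phIV3": 0.13, "phIV4": 0.08}
        for i, s in enumerate(spans):
            row = {"taxon": f"c{i}", "mandible": 0.24 * s}
            row.update({el: f * s * float(np.exp(rng.normal(0, 0.02)))
                        for el, f in fracs.items()})
            rows.append(row)
        # tier rows: one taxon per cascade level
        rows.append({"taxon": "only_ph2", "phIV2": 0.17 * 1000})
        rows.append({"taxon": "only_ph1", "phIV1": 0.22 * 1200})
        rows.append({"taxon": "only_hum", "humerus": 0.11 * 1500})
        rows.append({"taxon": "only_mand", "mandible": 0.24 * 2000})
        rows.append({"taxon": "hopeless", "rostrum": 100.0})
        table = _table_from_rows(rows)
        tree = ct.simulate_tree(len(table.taxa), 100.0, seed=12, root_age=120.0)
        for tip, name in zip(tree.tips(), table.taxa):
            tip.label = name
        tree = ct.CalibratedTree(tree.root, root_age=120.0)
        traits = ct.estimate_wingspan_cascade(table, tree, exclude=())
        prov = traits.provenance
        assert prov["only_ph2"] == "estimated:phIV2"
        assert prov["only_ph1"] == "estimated:phIV1"
        assert prov["only_hum"] == "estimated:humerus"
        assert prov["only_mand"] == "estimated:mandible"
        assert "hopeless" not in traits.values
        assert all(prov[f"c{i}"] == "measured" for i in range(10))
        assert all(traits.se[f"c{i}"] == 0.0 for i in range(10))
        assert all(traits.se[t] > 0 for t in
                   ("only_ph2", "only_ph1", "only_hum", "only_mand"))

    def test_cascade_estimates_unbiased_on_study_scenario(self):
        # signed log10 error of cascade estimates vs generative truth
        errors = []
        for r in range(8):
            scenario = ct.SimScenario(n_tips=60, seed=900 + r)
            tree, rm, traits, clad, ages, meas = ct.generate_dataset(scenario)
            est = ct.estimate_wingspan_cascade(meas, tree, exclude=())
            for t, v in est.values.items():
                if est.provenance[t] != "measured":
                    errors.append(v - traits.values[t])
        errors = np.array(errors)
        assert len(errors) > 50
        assert abs(errors.mean()) < 2 * errors.std(ddof=1) / math.sqrt(len(errors))

    def test_exclusion_only_affects_fitting_not_output(self, study_dataset):
        tree, _, _, _, _, meas = study_dataset
        out = ct.estimate_wingspan_cascade(meas, tree, exclude=(meas.taxa[0],))
        assert meas.taxa[0] in out.values  # excluded from fitting, kept in traits


class TestFilterAdults:
    def test_all_adult_identity(self, study_dataset):
        *_, meas = study_dataset
        assert len(ct.filter_adults(meas)) == len(meas)

    def test_mixed_statuses_filtered(self):
        table = _table_from_rows(
            [{"taxon": "a", "humerus": 10.0}, {"taxon": "b", "humerus": 12.0}]
        )
        table.data.loc[1, "status"] = "juvenile"
        out = ct.filter_adults(ct.MeasurementTable(table.data))
        assert out.taxa == ["a"]

    def test_no_adults_is_error(self):
        table = _table_from_rows([{"taxon": "a", "humerus": 10.0}])
        table.data["status"] = "juvenile"
        with pytest.raises(ValidationError):
            ct.filter_adults(ct.MeasurementTable(table.data))
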