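"""Score construction, APOE calling, encoding and scaling."""

import numpy as np
import pandas as pd
import pytest

from loadrisk import features as ft
from loadrisk.errors import (
    AlignmentError,
    DegenerateDataError,
    InvalidParameterError,
)
from loadrisk.synthetic import SimParams, simulate_cohort


def stats_frame(betas, snps=None):
    snps = snps or [f"s{i}" for i in range(len(betas))]
    return pd.DataFrame(
        {
            "snp_id": snps,
            "effect_allele": ["A"] * len(betas),
            "other_allele": ["G"] * len(betas),
            "beta": betas,
        }
    )


class TestRawWeightedScore:
    def test_hand_example(self):
        # (2+1)*0.5 + (0+1)*0.3 = 1.8
        stats = stats_frame([0.5, 0.3])
        score = ft.raw_weighted_score(np.array([2.0, 0.0]), stats)
        assert score == pytest.approx(1.8, abs=1e-12)

    def test_zero_betas(self, rng):
        stats = stats_frame([0.0, 0.0, 0.0])
        score = ft.raw_weighted_score(rng.integers(0, 3, 3).astype(float), stats)
        assert score == 0.0

    def test_negative_beta_orientation(self):
        # beta=-0.4, dosage 0 -> oriented g = 2, contribution (2+1)*0.4
        stats = stats_frame([-0.4])
        score = ft.raw_weighted_score(np.array([0.0]), stats)
        assert score == pytest.approx(1.2, abs=1e-12)

    def test_unaligned_snps_raise(self):
        stats = stats_frame([0.1, 0.2], snps=["a", "b"])
        G = pd.DataFrame({"a": [1.0]})
        with pytest.raises(AlignmentError):
            ft.raw_weighted_scores(G, stats)

    def test_missing_policies(self):
        stats = stats_frame([0.5, 0.5], snps=["a", "b"])
        G = pd.DataFrame(
            {"a": [0.0, 2.0, np.nan], "b": [1.0, 1.0, 1.0]},
            index=["c1", "c2", "x"],
        )
        zero = ft.raw_weighted_scores(G, stats, missing_policy="zero")
        assert zero["x"] == pytest.approx((0 + 1) * 0.5 + (1 + 1) * 0.5)
        ctrl = ft.raw_weighted_scores(
            G, stats, missing_policy="control_mean",
            control_mask=[True, True, False],
        )
        assert ctrl["x"] == pytest.approx((1.0 + 1) * 0.5 + (1 + 1) * 0.5)


class TestStandardization:
    def test_hand_example(self):
        raw = pd.Series([1.0, 3.0, 3.0], index=["c1", "c2", "case"])
        z, std = ft.standardize_scores(raw, [True, True, False])
        assert std.mu_control == pytest.approx(2.0)
        assert std.sigma_control == pytest.approx(np.sqrt(2.0))
        assert z["case"] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_control_moments(self, rng):
        raw = pd.Series(rng.normal(size=200))
        mask = np.zeros(200, dtype=bool)
        mask[:150] = True
        z, _ = ft.standardize_scores(raw, mask)
        assert z[mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[mask].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_offset_invariance(self, rng):
        # (g + c) scoring leaves standardized scores unchanged for any c
        stats = stats_frame(list(rng.normal(0, 0.1, 12)))
        G = pd.DataFrame(
            rng.integers(0, 3, size=(40, 12)).astype(float),
            columns=stats["snp_id"],
        )
        mask = np.arange(40) < 30
        ref = None
        for c in (0.0, 1.0, 5.0):
            raw = ft.raw_weighted_scores(G, stats, missing_policy="zero", offset=c)
            z, _ = ft.standardize_scores(raw, mask)
            if ref is None:
                ref = z
            else:
                assert np.allclose(z, ref, atol=1e-12)

    def test_degenerate_controls(self):
        raw = pd.Series([1.0, 1.0, 5.0])
        with pytest.raises(DegenerateDataError):
            ft.standardize_scores(raw, [True, True, False])


class TestApoe:
    # (rs429358 C-count, rs7412 C-count) -> (diplotype, ordinal code)
    TABLE = {
        (0, 0): ("e2/e2", -1),
        (0, 1): ("e2/e3", -1),
        (0, 2): ("e3/e3", 0),
        (1, 1): ("e2/e4", 1),
        (1, 2): ("e3/e4", 1),
        (2, 2): ("e4/e4", 2),
        # epsilon-1-implying genotypes, coded as epsilon-4-equivalents
        (1, 0): ("e1/e2", 1),
        (2, 0): ("e1/e1", 2),
        (2, 1): ("e1/e4", 2),
    }

    @pytest.mark.parametrize("gts,expected", sorted(TABLE.items()))
    def test_totality(self, gts, expected):
        d = ft.call_apoe_diplotype(*gts)
        assert (d.value, d.ordinal_code) == expected

    def test_out_of_domain(self):
        with pytest.raises(InvalidParameterError):
            ft.call_apoe_diplotype(3, 0)

    def test_monotone_risk_in_simulation(self):
        # with a positive APOE weight, case fraction rises across the
        # -1 -> 0 -> 2 risk codes (code 1 mixes protective/risk haplotypes)
        params = SimParams(
            n_cases=400, n_controls=1600, n_snps=5, seed=17,
            w_score=0.0, w_age=0.0, w_diabetes=0.0, w_cholesterol=0.0,
            w_apoe=1.2, missing_rate=0.0,
        )
        cohort = simulate_cohort(params)
        codes = ft.apoe_codes(cohort.apoe)
        y = cohort.labels
        fractions = [y[codes == c].mean() for c in (-1, 0, 2)]
        assert fractions[0] <= fractions[1] <= fractions[2]


class TestEncodingAndAssembly:
    def test_binary_validation(self):
        raw = pd.DataFrame(
            {"sex": [0, 2], "smoker": [0, 1], "diabetes": [1, 0],
             "age": [70, 75], "cholesterol": [5.0, 6.0]}
        )
        with pytest.raises(InvalidParameterError):
            ft.encode_phenotypes(raw)

    def test_passthrough_and_missing(self):
        raw = pd.DataFrame(
            {"sex": [0, 1], "smoker": [1, 0], "diabetes": [1, np.nan],
             "age": [72.0, 88.0], "cholesterol": [np.nan, 6.1]}
        )
        enc = ft.encode_phenotypes(raw)
        assert enc.loc[0, "age"] == 72.0
        assert np.isnan(enc.loc[0, "cholesterol"])
        assert np.isnan(enc.loc[1, "diabetes"])

    def test_complete_case_drop(self):
        idx = pd.Index([f"i{k}" for k in range(10)])
        z = pd.Series(np.arange(10.0), index=idx)
        apoe = pd.Series(np.zeros(10), index=idx)
        enc = pd.DataFrame(
            {"age": 70.0, "sex": 0.0, "smoker": 0.0, "diabetes": 0.0,
             "cholesterol": 5.5},
            index=idx,
        )
        enc.loc["i3", "diabetes"] = np.nan
        labels = pd.Series(np.zeros(10, dtype=int), index=idx)
        X, y, dropped = ft.build_feature_matrix(z, apoe, enc, labels)
        assert len(X) == 9 and dropped == ["i3"]
        assert list(X.columns) == list(ft.FEATURE_COLUMNS)


class TestScaler:
    def test_train_moments_and_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        scaling = ft.fit_scaler(X)
        Xs = ft.apply_scaler(scaling, X)
        assert np.allclose(Xs.mean(), 0.0, atol=1e-12)
        assert np.allclose(Xs.std(ddof=1), 1.0, atol=1e-12)
        assert np.allclose(ft.invert_scaler(scaling, Xs), X, atol=1e-10)

    def test_constant_column_unit_scale(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        scaling = ft.fit_scaler(X)
        assert scaling.sds["b"] == 1.0
        assert np.allclose(ft.apply_scaler(scaling, X)["b"], 0.0)

    def test_mean_row_maps_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        scaling = ft.fit_scaler(X)
        row = pd.DataFrame([X.mean()], columns=X.columns)
        assert np.allclose(ft.apply_scaler(scaling, row), 0.0, atol=1e-12)
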