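"""Moderator encoding and mixed-effects meta-regression."""

import numpy as np
import pytest

from glymeta.exceptions import ConstantModeratorError, DegenerateInputError
from glymeta.model import MetaRegression, r2_explained, random_effects
from glymeta.moderators import encode_moderator, fit_moderator, run_moderator_screen
from glymeta.records import normalize_record
from glymeta.effects import compute_effects
from glymeta.simulate import ModeratorSpec, SimulationConfig, simulate_meta_dataset, replicate_rng

from conftest import mk_effects


def covs(values, name="x"):
    return [{name: v} for v in values]


class TestEncodeModerator:
    def test_treatment_coding_against_reference(self):
        enc = encode_moderator(
            covs(["KX", "avertin", "chloral", "KX"], "anesthesia"),
            "anesthesia",
            reference_level="KX",
        )
        assert enc.term_labels == ["intercept", "avertin", "chloral"]
        np.testing.assert_array_equal(
            enc.design,
            [[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 0, 0]],
        )
        assert enc.reference_level == "KX"

    def test_default_reference_is_most_frequent(self):
        enc = encode_moderator(
            covs(["a", "b", "b", "c"], "anesthesia"), "anesthesia"
        )
        assert enc.reference_level == "b"

    def test_numeric_passthrough_is_single_centered_column(self):
        enc = encode_moderator(covs([6.0, 12.0, 24.0], "age_weeks"), "age_weeks")
        assert enc.term_labels == ["intercept", "age_weeks"]
        np.testing.assert_allclose(enc.design[:, 1], [-8.0, -2.0, 10.0])

    def test_missing_categorical_becomes_unreported_dummy(self):
        # resolve_covariates maps a missing duration to the token "unreported"
        enc = encode_moderator(
            covs(["30", "unreported", "60"], "duration"), "duration"
        )
        assert "unreported" in enc.term_labels

    def test_missing_numeric_rows_excluded_with_notice(self):
        enc = encode_moderator(covs([6.0, None, 24.0], "age_weeks"), "age_weeks")
        np.testing.assert_array_equal(enc.used_mask, [True, False, True])
        assert any("missing" in n for n in enc.notices)

    def test_mixed_tokens_coerce_to_categorical(self):
        enc = encode_moderator(
            covs(["1", "2", "pulsed_10psi"], "injection_rate"), "injection_rate"
        )
        assert enc.reference_level is not None  # categorical path
        assert any("coerced" in n for n in enc.notices)

    def test_constant_moderator_rejected(self):
        with pytest.raises(ConstantModeratorError):
            encode_moderator(covs(["KX", "KX"], "anesthesia"), "anesthesia")
        with pytest.raises(ConstantModeratorError):
            encode_moderator(covs([5.0, 5.0, 5.0], "age_weeks"), "age_weeks")

    def test_absent_reference_level_rejected(self):
        with pytest.raises(KeyError):
            encode_moderator(
                covs(["a", "b"], "anesthesia"), "anesthesia", reference_level="zzz"
            )


class TestFit:
    def test_two_homogeneous_groups_hand_wls(self):
        """Four studies, v = 0.25 each, a binary moderator separating two
        homogeneous pairs: exact WLS solution with zero residual tau2."""
        eff = mk_effects([-2.0, -2.0, 0.0, 0.0], [0.25] * 4)
        X = np.column_stack([np.ones(4), [0.0, 0.0, 1.0, 1.0]])
        res = MetaRegression(eff, X, ["intercept", "group"]).fit("DL")
        beta = {r["term"]: r for r in res.coefficients.rows()}
        assert beta["intercept"]["beta"] == pytest.approx(-2.0, abs=1e-12)
        assert beta["group"]["beta"] == pytest.approx(2.0, abs=1e-12)
        assert beta["group"]["se"] == pytest.approx(0.5, abs=1e-12)
        assert res.QM == pytest.approx(16.0, abs=1e-10)
        assert res.tau2_resid == pytest.approx(0.0, abs=1e-12)
        # intercept-only DL tau2 on the same data: Q = 16, C = 12
        assert res.tau2_total == pytest.approx(13.0 / 12.0, abs=1e-12)
        assert res.r2_percent == pytest.approx(100.0)

    @pytest.mark.parametrize("tau2_method", ["DL", "REML"])
    def test_intercept_only_nests_random_effects(self, fixture_effects, tau2_method):
        X = np.ones((len(fixture_effects), 1))
        reg = MetaRegression(fixture_effects, X, ["intercept"]).fit(tau2_method)
        pooled = random_effects(fixture_effects, tau2_method)
        row = reg.coefficients.rows()[0]
        assert row["beta"] == pytest.approx(pooled.est, abs=1e-10)
        assert row["se"] == pytest.approx(pooled.se, abs=1e-10)
        assert reg.tau2_resid == pytest.approx(pooled.tau2, abs=1e-10)

    def test_qm_invariant_under_reference_change(self, fixture_effects):
        values = ["a", "b", "c", "a", "b"]
        cov = covs(values, "anesthesia")
        res_a = fit_moderator(fixture_effects, cov, "anesthesia", reference_level="a")
        res_c = fit_moderator(fixture_effects, cov, "anesthesia", reference_level="c")
        assert res_a.QM == pytest.approx(res_c.QM, abs=1e-8)
        assert res_a.p_QM == pytest.approx(res_c.p_QM, abs=1e-8)
        assert res_a.tau2_resid == pytest.approx(res_c.tau2_resid, abs=1e-10)

    def test_rank_deficient_design_rejected(self, fixture_effects):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(DegenerateInputError, match="rank"):
            MetaRegression(fixture_effects, X, ["intercept", "dup"])

    def test_too_many_columns_rejected(self):
        eff = mk_effects([-1.0, 0.0], [0.3, 0.3])
        X = np.column_stack([np.ones(2), [0.0, 1.0]])
        with pytest.raises(DegenerateInputError, match="studies"):
            MetaRegression(eff, X, ["intercept", "x"])

    def test_perfect_subgroup_moderator_explains_everything(self):
        eff = mk_effects([-1.5, -1.5, -1.5, 0.5, 0.5, 0.5], [0.2] * 6)
        cov = covs(["g1"] * 3 + ["g2"] * 3, "ko_line")
        res = fit_moderator(eff, cov, "ko_line")
        assert res.tau2_resid == 0.0
        assert res.r2_percent == pytest.approx(100.0)


class TestR2Explained:
    def test_worked_values(self):
        assert r2_explained(13.0 / 12.0, 0.0) == pytest.approx(100.0)
        assert r2_explained(0.5, 0.5) == 0.0
        assert r2_explained(0.5, 0.9) == 0.0  # floored
        assert r2_explained(0.0, 0.0) == 0.0

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            r2_explained(-1.0, 0.0)


class TestScreen:
    def test_empty_covariate_list(self, fixture_effects):
        records = []  # not used when covariate list is empty
        res = run_moderator_screen(
            [None] * 0, [], covariate_names=()
        )
        assert res.entries == []

    def test_constant_covariate_reported_as_failed(self):
        cfg = SimulationConfig(seed=3, moderators=())
        records = [normalize_record(r) for r in simulate_meta_dataset(cfg)]
        effects = compute_effects(records)
        res = run_moderator_screen(records, effects, covariate_names=("species",))
        entry = res["species"]
        assert not entry.ok
        assert entry.failure_reason == "constant moderator"
        assert (res.table["failure_reason"] == "constant moderator").any()

    def test_informative_moderator_ranks_first(self):
        """Across 500 simulated tables where only anesthesia carries a true
        effect, its moderator test beats the null age covariate in >= 95%."""
        mods = (
            ModeratorSpec(
                name="anesthesia", kind="categorical",
                levels=("ketamine_xylazine", "avertin"), probs=(0.5, 0.5),
                betas={"avertin": 1.5},
            ),
            ModeratorSpec(
                name="age_weeks", kind="numeric", value_range=(6.0, 24.0), beta=0.0
            ),
        )
        cfg = SimulationConfig(
            k=24, mu=-1.7, tau2=0.1, moderators=mods,
            n_ctrl=10, n_ko=10, sem_fraction=0.0, n_range_fraction=0.0, seed=11,
        )
        wins = 0
        n_reps = 500
        for rep in range(n_reps):
            records = [
                normalize_record(r)
                for r in simulate_meta_dataset(cfg, rng=replicate_rng(cfg.seed, rep))
            ]
            effects = compute_effects(records)
            screen = run_moderator_screen(
                records, effects, covariate_names=("anesthesia", "age_weeks")
            )
            a, g = screen["anesthesia"], screen["age_weeks"]
            if a.ok and g.ok and a.result.p_QM < g.result.p_QM:
                wins += 1
        assert wins / n_reps >= 0.95


def test_binary_moderator_coefficient_recovery():
    """k = 40, tau2 = 0.2, binary moderator with beta1 = 1.0: the mean
    estimated slope over 500 replicates recovers the truth within 0.1."""
    mods = (
        ModeratorSpec(
            name="anesthesia", kind="categorical",
            levels=("ketamine_xylazine", "avertin"), probs=(0.5, 0.5),
            betas={"avertin": 1.0},
        ),
    )
    cfg = SimulationConfig(
        k=40, mu=-1.0, tau2=0.2, moderators=mods,
        n_ctrl=20, n_ko=20, sem_fraction=0.0, n_range_fraction=0.0, seed=17,
    )
    slopes = []
    for rep in range(500):
        records = [
            normalize_record(r)
            for r in simulate_meta_dataset(cfg, rng=replicate_rng(cfg.seed, rep))
        ]
        effects = compute_effects(records)
        res = fit_moderator(
            effects,
            [{"anesthesia": r.anesthesia} for r in records],
            "anesthesia",
            reference_level="ketamine_xylazine",
        )
        slopes.append(
            {r["term"]: r["beta"] for r in res.coefficients.rows()}["avertin"]
        )
    assert abs(np.mean(slopes) - 1.0) < 0.1
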