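import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mammorisk import effects as eff
from mammorisk import synthetic as syn


class TestPooling:
    def test_single_study_identity(self):
        # the printed CI is symmetric on the log scale only to rounding,
        # so the identity holds to the printed precision
        pooled = eff.pool_odds_ratios([(1.20, (1.10, 1.31))])
        assert pooled.odds_ratio == pytest.approx(1.20)
        assert pooled.ci_low == pytest.approx(1.10, abs=5e-3)
        assert pooled.ci_high == pytest.approx(1.31, abs=5e-3)
        assert pooled.n_sources == 1

    def test_two_identical_estimates_narrow_the_interval(self):
        est = (1.20, (1.10, 1.31))
        pooled = eff.pool_odds_ratios([est, est])
        assert pooled.odds_ratio == pytest.approx(1.20)
        assert pooled.ci_low > 1.10 and pooled.ci_high < 1.31

    def test_three_unequal_estimates_match_hand_weighted_mean(self):
        # independent hand computation of the inverse-variance mean
        ests = [(1.12, (1.00, 1.25)), (1.28, (1.15, 1.43)), (1.05, (0.95, 1.16))]
        z = 1.959963984540054
        logs = np.log([e[0] for e in ests])
        ses = [(np.log(hi) - np.log(lo)) / (2 * z) for _, (lo, hi) in ests]
        w = 1 / np.square(ses)
        expected = np.exp(np.sum(w * logs) / np.sum(w))
        pooled = eff.pool_odds_ratios(ests)
        assert pooled.odds_ratio == pytest.approx(expected, rel=1e-12)

    def test_k_copies_divide_variance_by_k(self):
        est = (1.30, (1.12, 1.51))
        one = eff.pool_odds_ratios([est])
        se1 = (np.log(one.ci_high) - np.log(one.ci_low)) / 2
        for k in (2, 4):
            many = eff.pool_odds_ratios([est] * k)
            se_k = (np.log(many.ci_high) - np.log(many.ci_low)) / 2
            assert many.odds_ratio == pytest.approx(1.30)
            assert se_k == pytest.approx(se1 / np.sqrt(k), rel=1e-10)

    def test_degenerate_ci_rejected_with_identity(self):
        with pytest.raises(ValueError, match="estimate 1"):
            eff.pool_odds_ratios([(1.2, (1.1, 1.3)), (1.5, (1.5, 1.5))])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            eff.pool_odds_ratios([])


class TestRecoding:
    @pytest.mark.parametrize(
        "or_in, dose_in, or_out, dose_out",
        [(1.26, 1, 1.26, 1), (0.80, 2, 1.25, 0), (0.80, 0, 1.25, 2), (1.0, 1, 1.0, 1)],
    )
    def test_recode_examples(self, or_in, dose_in, or_out, dose_out):
        o, d = eff.recode_to_risk_allele(or_in, dose_in)
        assert o == pytest.approx(or_out)
        assert d == dose_out

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            eff.recode_to_risk_allele(0.0, 1)

    def test_snp_rr_invariant_under_recoding(self, table):
        """Flipping a locus to protective coding and back must not change
        any subject's relative risk."""
        rng = np.random.default_rng(5)
        # express every locus in its protective-allele coding (OR < 1,
        # dosage counted on the other allele)
        protective = [
            eff.SnpEffect(s.rsid, 1 / s.odds_ratio, 1 - s.allele_freq)
            for s in table.snp_effects
        ]
        for _ in range(20):
            risk_dosages = {s.rsid: int(rng.integers(0, 3)) for s in table.snp_effects}
            prot_dosages = {k: 2 - d for k, d in risk_dosages.items()}
            recoded_effects, recoded_dosages = [], {}
            for s in protective:
                o, d = eff.recode_to_risk_allele(s.odds_ratio, prot_dosages[s.rsid])
                recoded_effects.append(eff.SnpEffect(s.rsid, o, 1 - s.allele_freq))
                recoded_dosages[s.rsid] = d
            assert all(s.odds_ratio >= 1 for s in recoded_effects)
            assert recoded_dosages == risk_dosages
            # normalised relative risk is coding-invariant
            rr_risk = eff.snp_relative_risk(risk_dosages, table.snp_effects)
            rr_prot = eff.snp_relative_risk(prot_dosages, protective)
            assert rr_prot == pytest.approx(rr_risk, rel=1e-12)


class TestSnpRelativeRisk:
    def test_all_zero_dosages_give_unit_product(self, table):
        dosages = {s.rsid: 0 for s in table.snp_effects}
        assert eff.snp_relative_risk(dosages, table.snp_effects, normalize=False) == 1.0

    def test_single_locus_homozygote_squares_odds_ratio(self):
        effs = [eff.SnpEffect("rs0", 1.26, 0.3)]
        assert eff.snp_relative_risk({"rs0": 2}, effs, normalize=False) == pytest.approx(
            1.5876
        )

    def test_random_profile_matches_per_locus_loop(self, table):
        rng = np.random.default_rng(7)
        for _ in range(10):
            dosages = {s.rsid: int(rng.integers(0, 3)) for s in table.snp_effects}
            loop = 1.0
            for s in table.snp_effects:
                loop *= s.odds_ratio ** dosages[s.rsid]
            assert eff.snp_relative_risk(
                dosages, table.snp_effects, normalize=False
            ) == pytest.approx(loop, rel=1e-12)

    def test_missing_loci_are_neutral(self, table):
        # missing loci contribute factor 1 before normalisation
        assert eff.snp_relative_risk({}, table.snp_effects, normalize=False) == 1.0
        partial = {table.rsids[0]: 1}
        full_one = dict(partial, **{r: 0 for r in table.rsids[1:]})
        assert eff.snp_relative_risk(
            partial, table.snp_effects, normalize=False
        ) == pytest.approx(
            eff.snp_relative_risk(full_one, table.snp_effects, normalize=False)
        )

    def test_bad_dosage_rejected(self, table):
        with pytest.raises(ValueError):
            eff.snp_relative_risk({table.rsids[0]: 3}, table.snp_effects)

    def test_hardy_weinberg_population_mean_is_one(self, table):
        """Normalised SNP relative risk averages to 1 over a simulated
        Hardy-Weinberg population of 100,000."""
        rng = np.random.default_rng(11)
        rr = np.ones(100_000)
        mean = eff.snp_mean_relative_risk(table.snp_effects)
        for s in table.snp_effects:
            d = rng.binomial(2, s.allele_freq, size=100_000)
            rr = rr * s.odds_ratio**d
        assert np.mean(rr / mean) == pytest.approx(1.0, abs=0.02)


class TestCategorisation:
    @pytest.mark.parametrize(
        "pd_pct, rr",
        [(0.0, 1.00), (5.0, 1.27), (10.0, 2.00), (30.0, 2.98), (60.0, 3.70), (75.0, 5.86), (80.0, 5.86), (100.0, 5.86)],
    )
    def test_pd_categories(self, table, pd_pct, rr):
        assert eff.categorize_pd(pd_pct, table.pd_effects) == pytest.approx(rr)

    @pytest.mark.parametrize(
        "bmi, rr",
        [(20.0, 1.00), (21.79, 1.16), (23.30, 1.13), (26.0, 1.28), (27.64, 1.67), (30.0, 1.67)],
    )
    def test_bmi_categories(self, table, bmi, rr):
        assert eff.categorize_bmi(bmi, table.bmi_effects) == pytest.approx(rr)

    def test_out_of_range_rejected(self, table):
        with pytest.raises(ValueError):
            eff.categorize_pd(101.0, table.pd_effects)
        with pytest.raises(ValueError):
            eff.categorize_bmi(-1.0, table.bmi_effects)

    @given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    def test_pd_step_function_is_monotone(self, a, b):
        t = eff.load_reference_effects()
        lo, hi = sorted((a, b))
        assert eff.categorize_pd(lo, t.pd_effects) <= eff.categorize_pd(hi, t.pd_effects)

    @given(st.floats(min_value=10, max_value=60), st.floats(min_value=10, max_value=60))
    def test_bmi_risk_not_below_reference(self, a, b):
        t = eff.load_reference_effects()
        assert eff.categorize_bmi(a, t.bmi_effects) >= 1.0
        assert eff.categorize_bmi(b, t.bmi_effects) >= 1.0


class TestCombinedRelativeRisk:
    def test_empty_model_spec_gives_one(self, table, ref):
        p = eff.RiskProfile(age=60)
        assert eff.combined_relative_risk(p, table, [], ref) == 1.0

    def test_reference_clinical_profile_is_inverse_mean(self, table, ref):
        # enumerate the configured category distribution by hand
        ce = table.clinical_effects
        mean = (
            sum(p * ce["menarche"] ** k for k, p in enumerate(ref.menarche_probs))
            * sum(p * ce["first_birth"] ** k for k, p in enumerate(ref.first_birth_probs))
            * (1 - ref.bbd_prev + ref.bbd_prev * ce["bbd"])
            * (1 - ref.fh_prev + ref.fh_prev * ce["fh"])
        )
        p = eff.RiskProfile(age=60)
        assert eff.combined_relative_risk(p, table, "clinical", ref) == pytest.approx(
            1 / mean, rel=1e-12
        )

    def test_full_model_is_product_of_components(self, table, ref):
        rng = np.random.default_rng(3)
        dosages = {s.rsid: int(rng.integers(0, 3)) for s in table.snp_effects}
        p = eff.RiskProfile(
            age=62, menarche_level=2, first_birth_level=1, bbd=1, fh=0,
            pd_percent=33.0, bmi=24.5, dosages=dosages,
        )
        full = eff.combined_relative_risk(p, table, "full", ref)
        parts = [
            eff.combined_relative_risk(p, table, [c], ref)
            for c in ("clinical", "pd_bmi", "snp18")
        ]
        assert full == pytest.approx(np.prod(parts), rel=1e-12)

    def test_missing_field_rejected_with_name(self, table, ref):
        p = eff.RiskProfile(age=60, pd_percent=None, bmi=24.0)
        with pytest.raises(ValueError, match="pd_percent"):
            eff.combined_relative_risk(p, table, "gail+pd", ref)

    def test_population_mean_combined_rr_is_one(self, table, ref):
        """Scoring the generator's own population with the matching
        reference distribution gives mean relative risk ~1."""
        cfg = syn.GeneratorConfig(n_cases=10, n_controls=10)
        rng = np.random.default_rng(13)
        profiles = syn._draw_profiles(cfg, 30_000, rng)
        rr = eff.score_cohort(profiles, table, "full", ref)
        assert rr.mean() == pytest.approx(1.0, abs=0.03)

    def test_scalar_and_vectorised_paths_agree(self, table, ref, small_cohort):
        df = small_cohort.data.head(40)
        vec = eff.score_cohort(df, table, "full", ref)
        for i, (_, row) in enumerate(df.iterrows()):
            p = eff.RiskProfile(
                age=row.age, menarche_level=int(row.menarche_level),
                first_birth_level=int(row.first_birth_level), bbd=int(row.bbd),
                fh=int(row.fh), pd_percent=row.pd_percent, bmi=row.bmi,
                dosages={s.rsid: int(row[s.rsid]) for s in table.snp_effects},
            )
            assert eff.combined_relative_risk(p, table, "full", ref) == pytest.approx(
                vec[i], rel=1e-10
            )


class TestProxyEffects:
    def test_null_association_recovers_or_one(self, table):
        rng = np.random.default_rng(17)
        n = 20_000
        df = pd.DataFrame(
            {
                "status": rng.integers(0, 2, n),
                "bbd": rng.random(n) < 0.15,
                "fh": rng.random(n) < 0.10,
                "menarche_level": rng.integers(0, 3, n),
                "first_birth_level": rng.integers(0, 3, n),
            }
        ).astype(int)
        res = eff.estimate_proxy_effects(df, table)
        assert abs(np.log(res.or_bbd)) < 3 * res.se_log_bbd
        assert abs(np.log(res.or_fh)) < 3 * res.se_log_fh

    def test_zero_offset_equals_unconstrained_fit(self, table, small_cohort):
        """With both offset components at reference level the fit reduces
        to an ordinary two-covariate logistic regression."""
        import statsmodels.api as sm

        df = small_cohort.data.copy()
        df["menarche_level"] = 0
        df["first_birth_level"] = 0
        res = eff.estimate_proxy_effects(df, table)
        exog = sm.add_constant(df[["bbd", "fh"]].to_numpy(float))
        free = sm.GLM(
            df["status"].to_numpy(float), exog, family=sm.families.Binomial()
        ).fit()
        assert res.or_bbd == pytest.approx(np.exp(free.params[1]), rel=1e-6)
        assert res.or_fh == pytest.approx(np.exp(free.params[2]), rel=1e-6)

    def test_complete_separation_reported(self, table):
        n = 200
        df = pd.DataFrame(
            {
                "status": np.repeat([0, 1], n // 2),
                "bbd": np.repeat([0, 1], n // 2),
                "fh": np.zeros(n, dtype=int),
                "menarche_level": np.zeros(n, dtype=int),
                "first_birth_level": np.zeros(n, dtype=int),
            }
        )
        with pytest.raises(eff.EstimationError):
            eff.estimate_proxy_effects(df, table)


class TestEffectSizeTableValidation:
    def test_packaged_table_reproduces_published_values(self, table):
        assert [rr for _, rr in table.pd_effects] == [1.00, 1.27, 2.00, 2.98, 3.70, 5.86]
        assert [rr for _, rr in table.bmi_effects] == [1.00, 1.16, 1.13, 1.28, 1.67]
        assert table.clinical_effects == {
            "menarche": 1.10, "first_birth": 1.24, "bbd": 1.65, "fh": 2.07,
        }
        assert len(table.snp_effects) == 18
        by_id = {s.rsid: s.odds_ratio for s in table.snp_effects}
        assert by_id["rs2981582"] == 1.26
        assert by_id["rs3803662"] == 1.20
        assert by_id["rs6504950"] == 1.05

    def test_wrong_category_counts_rejected(self, table):
        with pytest.raises(ValueError):
            eff.EffectSizeTable(
                snp_effects=table.snp_effects,
                pd_effects=table.pd_effects[:5],
                bmi_effects=table.bmi_effects,
                clinical_effects=table.clinical_effects,
            )

    def test_tsv_round_trip(self, table, tmp_path):
        p = tmp_path / "effects.tsv"
        table.to_tsv(p)
        back = eff.EffectSizeTable.from_tsv(p)
        assert back.pd_effects == table.pd_effects
        assert back.clinical_effects == table.clinical_effects
        assert [s.rsid for s in back.snp_effects] == table.rsids
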