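"""Normalizations, report quantities, tail outliers, era shifts, bin scans."""

import numpy as np
import pandas as pd
import pytest

import switchfit as sf
from switchfit.mixfit import ConvergenceError
from switchfit.polyphenism import NormalizationError


def _cohort(traits, genotypes=None, litters=None, **extra):
    n = len(traits)
    return pd.DataFrame({
        "individual_id": [f"i{j}" for j in range(n)],
        "trait": np.asarray(traits, dtype=float),
        "genotype": genotypes if genotypes is not None else ["mutant"] * n,
        "sex": extra.get("sex", ["M"] * n),
        "litter_id": litters if litters is not None else ["L0"] * n,
        "site_or_era": "x",
        "weight": 1.0,
        "age_group": extra.get("age_group", ["all"] * n),
        "true_class": "",
    })


def _report_for(values, bin_width, seed=0):
    binned = sf.bin_trait(values, bin_width=bin_width)
    return sf.summarize(
        sf.fit_double_gaussian(binned, seed=seed),
        sf.fit_single_gaussian(binned),
        binned, values, em_seed=seed,
    )


class TestNormalizeToWildtype:
    def test_per_litter_arithmetic(self):
        cohort = _cohort([30, 30, 42], ["WT", "WT", "mutant"])
        out = sf.normalize_to_wildtype(cohort, scope="per-litter")
        assert out.loc[2, "trait"] == pytest.approx(1.4)

    def test_all_wildtype_means_become_one(self):
        rng = np.random.default_rng(0)
        cohort = _cohort(rng.normal(30, 2, 40), ["WT"] * 40,
                         [f"L{i % 4}" for i in range(40)])
        out = sf.normalize_to_wildtype(cohort, scope="per-litter")
        means = out.groupby("litter_id")["trait"].mean()
        np.testing.assert_allclose(means, 1.0)

    def test_missing_wildtype_scope_lists_offenders(self):
        cohort = _cohort([1, 2, 3], ["WT", "mutant", "mutant"],
                         ["L0", "L0", "L9"])
        with pytest.raises(NormalizationError, match="L9"):
            sf.normalize_to_wildtype(cohort, scope="per-litter")

    def test_normalized_heavy_mode_reflects_generative_shift(self):
        cohort = sf.simulate_cohort(sf.get_preset("nnat", n=3000), seed=2,
                                    n_wildtype=1000)
        out = sf.normalize_to_wildtype(cohort, scope="global")
        mut = out[out["genotype"] == "mutant"]
        heavy = mut.loc[mut["true_class"] == "heavy", "trait"]
        assert heavy.mean() == pytest.approx(1.40, abs=0.02)


class TestAgeSexNormalize:
    def test_median_example(self):
        cohort = _cohort([1, 2, 3])
        out = sf.age_sex_normalize(cohort, grouping=["age_group"], method="median")
        np.testing.assert_allclose(sorted(out["trait"]), [0.5, 1.0, 1.5])

    def test_winsor_frac_zero_equals_plain_mean(self):
        rng = np.random.default_rng(3)
        traits = rng.normal(10, 2, 50)
        cohort = _cohort(traits)
        out = sf.age_sex_normalize(cohort, grouping=["age_group"],
                                   method="winsorized_mean", winsor_frac=0.0)
        np.testing.assert_allclose(out["trait"], traits / traits.mean())

    def test_mode_normalization_aligns_lean_modes_across_eras(self):
        a, b = sf.simulate_two_era(
            sf.get_preset("nhanes_child_1963"), sf.get_preset("nhanes_child_1999"),
            seed=4,
        )
        na = sf.age_sex_normalize(a, grouping=["age_group"], method="mode")
        nb = sf.age_sex_normalize(b, grouping=["age_group"], method="mode")
        mode = lambda df: sf.bin_trait(df["trait"].to_numpy(), bin_width=0.03)
        ma, mb = mode(na), mode(nb)
        peak_a = ma.midpoints[np.argmax(ma.counts)]
        peak_b = mb.midpoints[np.argmax(mb.counts)]
        assert abs(peak_a - peak_b) < 0.03  # within one (normalized) bin

    def test_unknown_method_and_small_mode_group(self):
        cohort = _cohort([1, 2, 3])
        with pytest.raises(ValueError):
            sf.age_sex_normalize(cohort, grouping=["age_group"], method="trimmed")
        with pytest.raises(NormalizationError):
            sf.age_sex_normalize(cohort, grouping=["age_group"], method="mode")


class TestSummarize:
    def test_on_rate_and_effect_size_arithmetic(self, nnat_fits):
        rep = sf.summarize(nnat_fits["double"], nnat_fits["single"],
                           nnat_fits["binned"], nnat_fits["values"])
        assert rep.on_rate == pytest.approx(0.26, abs=0.03)
        assert rep.effect_size_pct == pytest.approx(40.0, abs=3.0)
        assert rep.preferred_k == 2
        assert rep.on_rate + (1 - rep.on_rate) == 1.0

    def test_classification_fraction_tracks_on_rate(self, nnat_fits):
        rep = sf.summarize(nnat_fits["double"], nnat_fits["single"],
                           nnat_fits["binned"], nnat_fits["values"])
        assigned = (rep.class_labels["assigned"] == "heavy").mean()
        assert assigned == pytest.approx(rep.on_rate, abs=0.02)

    def test_peg3_small_n_mean_recovery(self):
        # small-n recovery across seeds at the published cohort size
        fracs = []
        for seed in range(1, 41):
            x = sf.simulate_cohort(sf.get_preset("peg3"), seed=seed)["trait"].to_numpy()
            fit = sf.fit_double_gaussian(sf.bin_trait(x, bin_width=1.0))
            if fit.converged:
                fracs.append(fit.heavy_fraction)
        assert np.mean(fracs) == pytest.approx(0.20, abs=0.05)

    def test_unimodal_cohort_prefers_k1_without_classification(self, unimodal_values):
        rep = _report_for(unimodal_values, bin_width=0.5)
        assert rep.preferred_k == 1
        assert rep.class_labels is None

    def test_nonconverged_fit_refused(self, nnat_fits):
        bad = sf.MixtureFit(k=2, components=nnat_fits["double"].components,
                            method="binned-nls", converged=False, r2=0.5)
        with pytest.raises(ConvergenceError):
            sf.summarize(bad, nnat_fits["single"], nnat_fits["binned"],
                         nnat_fits["values"])

    def test_normalization_invariance_of_rate_and_effect(self, nnat_fits):
        scaled = nnat_fits["values"] / 30.0
        binned = sf.bin_trait(scaled, bin_width=1.0 / 30.0)
        rep_scaled = sf.summarize(
            sf.fit_double_gaussian(binned), sf.fit_single_gaussian(binned),
            binned, scaled,
        )
        rep = sf.summarize(nnat_fits["double"], nnat_fits["single"],
                           nnat_fits["binned"], nnat_fits["values"])
        assert rep_scaled.on_rate == pytest.approx(rep.on_rate, abs=0.01)
        assert rep_scaled.effect_size_pct == pytest.approx(rep.effect_size_pct, abs=0.5)


class TestTailOutliers:
    def test_calibration_on_data_from_the_fitted_curve(self, nnat_fits):
        # multinomial draws from the fitted model: ~5% of bins outside a 95% PI
        fit = nnat_fits["double"]
        binned = nnat_fits["binned"]
        rng = np.random.default_rng(0)
        p = fit.predict_counts(binned)
        p = p / p.sum()
        rates, thresholds = [], 0
        for _ in range(20):
            counts = rng.multinomial(int(binned.n_effective), p)
            b = sf.BinnedDistribution(binned.edges, counts.astype(float))
            out = sf.tail_outliers(fit, b, ci_level=0.95)
            rates.append(out["outside_bin_fraction"])
            thresholds += out["systematic_threshold"] is not None
        assert np.mean(rates) < 0.12
        assert thresholds <= 2

    def test_constructed_extreme_tail_detected(self):
        x = sf.simulate_cohort(sf.get_preset("nhanes_child_1999"), seed=3)["trait"].to_numpy()
        rng = np.random.default_rng(1)
        tail = rng.uniform(31.0, 36.0, size=int(0.01 * len(x)))
        values = np.concatenate([x, tail])
        binned = sf.bin_trait(values, bin_width=0.5)
        fit = sf.fit_double_gaussian(binned)
        out = sf.tail_outliers(fit, binned, ci_level=0.95)
        assert out["systematic_threshold"] is not None
        assert out["systematic_threshold"] > 28.0
        assert out["exceeding_mass_fraction"] == pytest.approx(0.01, abs=0.01)

    def test_negative_control_no_systematic_exceedance(self):
        x = sf.simulate_cohort(sf.get_preset("nhanes_child_1999"), seed=5)["trait"].to_numpy()
        binned = sf.bin_trait(x, bin_width=0.5)
        fit = sf.fit_double_gaussian(binned)
        out = sf.tail_outliers(fit, binned, ci_level=0.95)
        assert out["systematic_threshold"] is None


class TestEraShift:
    def test_printed_era_contrast_arithmetic(self):
        # reports built directly from the printed lean means and fractions
        def fake(lean_mu, frac):
            return sf.PolyphenismReport(
                on_rate=frac, effect_size_pct=28.0, lean_mean=lean_mu,
                heavy_mean=lean_mu + 4.5,
                model_comparison={}, preferred_k=2, class_labels=None,
            )
        shift = sf.era_shift(fake(15.81, 0.12), fake(15.87, 0.38))
        assert shift["lean_mean_delta"] == pytest.approx(0.06, abs=1e-12)
        assert shift["lean_mean_pct"] == pytest.approx(0.4, abs=0.03)
        assert shift["heavy_fraction_ratio"] == pytest.approx(3.17, abs=0.01)

    def test_identical_reports_null_shift(self):
        x = sf.simulate_cohort(sf.get_preset("nnat", n=4000), seed=7)["trait"].to_numpy()
        rep = _report_for(x, bin_width=1.0)
        shift = sf.era_shift(rep, rep)
        assert shift["lean_mean_delta"] == 0.0
        assert shift["heavy_fraction_ratio"] == 1.0

    def test_recovered_era_contrast_matches_generative_truth(self):
        a, b = sf.simulate_two_era(
            sf.get_preset("nhanes_child_1963"), sf.get_preset("nhanes_child_1999"),
            seed=2,
        )
        shift = sf.era_shift(
            _report_for(a["trait"].to_numpy(), 0.5),
            _report_for(b["trait"].to_numpy(), 0.5),
        )
        assert shift["heavy_fraction_b"] == pytest.approx(0.38, abs=0.06)
        assert shift["heavy_fraction_ratio"] == pytest.approx(3.17, rel=0.35)

    def test_unimodal_report_refused(self, unimodal_values):
        rep1 = _report_for(unimodal_values, bin_width=0.5)
        x = sf.simulate_cohort(sf.get_preset("nnat", n=4000), seed=7)["trait"].to_numpy()
        rep2 = _report_for(x, bin_width=1.0)
        with pytest.raises(ConvergenceError, match="k=1"):
            sf.era_shift(rep1, rep2)


class TestBinSensitivity:
    def test_coarse_bins_mask_bimodality(self):
        # weakly separated equal mixture plus a sparse wide background:
        # fine bins resolve the dip, a bin wider than the 2.5-unit component
        # separation collapses the two modes into one
        rng = np.random.default_rng(0)
        x = np.concatenate([
            rng.normal(0, 1, 1950), rng.normal(2.5, 1, 1950),
            rng.uniform(-8, 12, 100),
        ])
        table = sf.bin_sensitivity(x, [0.2, 0.4, 3.0])
        assert (table[table["width"] <= 0.4]["preferred_k"] == 2).all()
        coarse = table[table["width"] == 3.0].iloc[0]
        assert coarse["preferred_k"] == 1
        assert bool(table["preference_flip"].any())

    def test_unimodal_negative_control(self, unimodal_values):
        table = sf.bin_sensitivity(unimodal_values, [0.25, 0.5, 1.0])
        evaluated = table.dropna(subset=["preferred_k"])
        assert (evaluated["preferred_k"] == 1).all()
        assert not table["preference_flip"].any()

    def test_on_rate_stable_across_fine_widths(self, nnat_fits):
        table = sf.bin_sensitivity(nnat_fits["values"], [0.5, 1.0, 1.5, 2.0])
        rates = table["on_rate"].dropna()
        assert rates.max() - rates.min() < 0.03

    def test_too_sparse_widths_warned_not_crashed(self):
        x = sf.simulate_cohort(sf.get_preset("nnat", n=300), seed=0)["trait"].to_numpy()
        table = sf.bin_sensitivity(x, [1.0, 50.0])
        assert table[table["width"] == 50.0]["warning"].iloc[0] != ""
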