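"""Slope synthesis, baseline blending, rescaling and TG back-transform."""
import math

import numpy as np
import pandas as pd
import pytest

import genomethate as g
from genomethate.phenotype import (
    MonomorphicSnpError,
    apply_baseline_correlation,
    draw_slope,
    draw_zenv,
    emit_tg,
    project_postRx,
    rescale_slope,
    standardize_genotypes,
)

CORR = -0.41881


def zero_ssnp(spec, n=3):
    ids = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    return pd.DataFrame(
        np.zeros((n, len(spec.snps))),
        index=ids,
        columns=[s.marker_name for s in spec.snps],
    )


def causal_meth(spec, value, n=3):
    ids = pd.Index([f"S{i}" for i in range(n)], name="subject_id")
    return pd.DataFrame(
        {c.cpg_name: np.full(n, float(value)) for c in spec.causal_cpgs}, index=ids
    )


class TestStandardizeGenotypes:
    def test_balanced_dosages_give_unit_zscores(self):
        d = pd.DataFrame({"rsA": [0.0, 1.0, 2.0]})
        z = standardize_genotypes(d)
        assert list(z["rsA"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_columns_have_zero_mean_unit_sd(self, small_cohort):
        z = standardize_genotypes(small_cohort.genotypes)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_monomorphic_column_error_names_marker(self):
        d = pd.DataFrame({"rsA": [0.0, 1.0, 2.0], "rsBAD": [1.0, 1.0, 1.0]})
        with pytest.raises(MonomorphicSnpError, match="rsBAD"):
            standardize_genotypes(d)


class TestDrawSlope:
    def test_full_methylation_leaves_only_residual(self, spec):
        z = np.array([0.3, -1.2, 2.0])
        slope = draw_slope(zero_ssnp(spec), causal_meth(spec, 1.0), spec, z)
        assert slope == pytest.approx(list(z * spec.residual_scale), abs=1e-12)

    def test_unmethylated_single_snp_carries_sqrt_hg2(self, spec):
        ssnp = zero_ssnp(spec)
        ssnp.loc["S0", "rs9661059"] = 1.0
        slope = draw_slope(ssnp, causal_meth(spec, 0.0), spec, np.zeros(3))
        assert slope[0] == pytest.approx(math.sqrt(0.125))
        assert slope[1] == 0.0

    def test_half_methylation_halves_the_contribution(self, spec):
        ssnp = zero_ssnp(spec)
        ssnp["rs9661059"] = 1.0
        full = draw_slope(ssnp, causal_meth(spec, 0.0), spec, np.zeros(3))
        half = draw_slope(ssnp, causal_meth(spec, 0.5), spec, np.zeros(3))
        assert half == pytest.approx(list(full / 2), abs=1e-12)

    def test_attenuation_is_linear_and_vanishes_at_one(self, spec):
        ssnp = zero_ssnp(spec)
        ssnp["rs9661059"] = 1.0
        vals = [
            draw_slope(ssnp, causal_meth(spec, m), spec, np.zeros(3))[0]
            for m in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert vals[-1] == 0.0
        diffs = np.diff(vals)
        assert np.allclose(diffs, diffs[0], atol=1e-12)  # linear in methylation

    def test_background_snps_ignore_methylation(self, spec):
        ssnp = zero_ssnp(spec)
        ssnp["rs2352866"] = 1.0
        s0 = draw_slope(ssnp, causal_meth(spec, 0.0), spec, np.zeros(3))
        s1 = draw_slope(ssnp, causal_meth(spec, 1.0), spec, np.zeros(3))
        assert s0[0] == pytest.approx(math.sqrt(0.001))
        assert s1[0] == pytest.approx(s0[0])

    def test_missing_causal_cpg_is_a_configuration_error(self, spec):
        meth = causal_meth(spec, 0.0).drop(columns=[spec.causal_cpgs[0].cpg_name])
        with pytest.raises(ValueError, match="causal CpG"):
            draw_slope(zero_ssnp(spec), meth, spec, np.zeros(3))

    def test_force_meth_overrides_simulated_values(self, spec):
        ssnp = zero_ssnp(spec)
        ssnp["rs9661059"] = 1.0
        forced = draw_slope(ssnp, causal_meth(spec, 0.7), spec, np.zeros(3), force_meth=0.0)
        assert forced[0] == pytest.approx(math.sqrt(0.125))


class TestBlendRescaleProject:
    def test_corrz_constant_when_slope_zero(self):
        assert apply_baseline_correlation(np.zeros(1), np.ones(1), CORR)[0] == CORR

    def test_corrz_scales_slope_by_complement(self):
        out = apply_baseline_correlation(np.array([2.0]), np.zeros(1), CORR)
        assert out[0] == pytest.approx(2.0 * math.sqrt(1 - CORR**2))
        assert math.sqrt(1 - CORR**2) == pytest.approx(0.9080739, abs=5e-7)

    def test_zero_correlation_passes_slope_through(self):
        s = np.array([1.5, -0.3])
        assert list(apply_baseline_correlation(s, np.ones(2), 0.0)) == list(s)

    @pytest.mark.parametrize("corrz,expected", [(0.0, -0.01), (1.0, -0.01 + 0.004)])
    def test_rescale_affine_map(self, corrz, expected):
        out = rescale_slope(np.array([corrz]), mean_slope=-0.01, sd_slope=0.004)
        assert out[0] == pytest.approx(expected)

    def test_projection(self):
        assert project_postRx(np.zeros(1), np.array([21.0]), np.array([4.6]))[0] == 4.6
        out = project_postRx(np.array([-0.01]), np.array([21.0]), np.array([4.6]))[0]
        assert out == pytest.approx(4.39)
        # doubling daysRx doubles the change from baseline
        out2 = project_postRx(np.array([-0.01]), np.array([42.0]), np.array([4.6]))[0]
        assert out2 - 4.6 == pytest.approx(2 * (out - 4.6))


class TestEmitTg:
    TG3, TG4 = np.array([90.0]), np.array([95.0])
    POST = (np.log(TG3) + np.log(TG4)) / 2

    def test_identity_when_sim_equals_observed(self):
        t3, t4 = emit_tg(self.POST, self.TG3, self.TG4, self.POST)
        assert t3[0] == pytest.approx(90.0, rel=1e-12)
        assert t4[0] == pytest.approx(95.0, rel=1e-12)

    def test_log_mean_of_outputs_is_sim_postRx(self):
        sim_post = self.POST + 0.37
        t3, t4 = emit_tg(sim_post, self.TG3, self.TG4, self.POST)
        assert (np.log(t3) + np.log(t4)) / 2 == pytest.approx(sim_post, abs=1e-12)

    def test_log_shift_multiplies_both_visits(self):
        t3, t4 = emit_tg(self.POST + math.log(2), self.TG3, self.TG4, self.POST)
        assert t3[0] == pytest.approx(180.0)
        assert t4[0] == pytest.approx(190.0)

    def test_missing_real_post_data_propagates(self):
        t3, t4 = emit_tg(self.POST, np.array([np.nan]), self.TG4, np.array([np.nan]))
        assert np.isnan(t3[0]) and np.isnan(t4[0])


class TestReplicateLevel:
    def test_roundtrip_slope_from_outputs(self, small_run):
        rep = g.simulate_replicate(small_run, k=5, diagnostics=True)
        t = small_run.baseline.table
        recon = (
            (np.log(rep.tg["SIMTG3"]) + np.log(rep.tg["SIMTG4"])) / 2
            - t["O_preRx_TG"].to_numpy()
        ) / t["O_daysRx"].to_numpy()
        assert np.allclose(recon, rep.diagnostics["sim_slope_jk"], atol=1e-10)

    def test_zenv_stream_independent_of_methylation_stream(self, spec, small_cohort):
        z = draw_zenv(spec, 1, 80)
        sim = g.simulate_v4(small_cohort.methylation, spec, 1, keep_raw=True)
        causal = spec.causal_cpgs[0].cpg_name
        noise = sim.raw_v4[causal].to_numpy() - g.methylation.anchor_matrix(
            small_cohort.methylation, spec
        )[causal].to_numpy()
        r = np.corrcoef(z, noise)[0, 1]
        assert abs(r) < 4 / np.sqrt(80)

    def test_replicates_reproducible_and_order_free(self, small_run):
        a = g.simulate_replicate(small_run, k=7)
        b = g.simulate_replicate(small_run, k=7)
        assert a.tg.equals(b.tg)
        assert a.methylation.v4_sim.equals(b.methylation.v4_sim)
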