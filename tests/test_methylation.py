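"""Three-branch visit-4 methylation simulation, clipping and its moments."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import genomethate as g
from genomethate.methylation import (
    MethylationPanel,
    anchor_matrix,
    base_value,
    simulate_v4,
    site_for,
    v4_moments,
)
from genomethate.validation import clipped_normal_moments


@pytest.fixture()
def tiny_panel(spec):
    causal = spec.causal_cpgs[0].cpg_name
    rh = spec.red_herring_cpgs[0].cpg_name
    v2 = pd.DataFrame(
        {causal: [0.49, 0.5], rh: [0.2, 0.3], "cg_other": [0.5, 0.33]},
        index=pd.Index(["A", "B"], name="subject_id"),
    )
    v4 = pd.DataFrame(
        {causal: [0.80], rh: [0.25], "cg_other": [0.80]},
        index=pd.Index(["A"], name="subject_id"),
    )
    return MethylationPanel(v2, v4)


class TestAnchors:
    def test_causal_site_always_anchors_on_visit2(self, spec, tiny_panel):
        site = spec.causal_cpgs[0]
        assert base_value(site, "A", tiny_panel) == 0.49  # even though v4 = 0.80

    def test_noncausal_site_prefers_real_visit4(self, spec, tiny_panel):
        site = site_for("cg_other", spec)
        assert site.site_class == "background" and site.sd_response == 0.03
        assert base_value(site, "A", tiny_panel) == 0.80

    def test_noncausal_site_falls_back_to_visit2(self, spec, tiny_panel):
        assert base_value(site_for("cg_other", spec), "B", tiny_panel) == 0.33

    def test_red_herring_gets_causal_noise_but_noncausal_anchor(self, spec, tiny_panel):
        site = spec.red_herring_cpgs[0]
        assert site.sd_response == 0.4
        assert base_value(site, "A", tiny_panel) == 0.25

    def test_anchor_matrix_matches_scalar_op(self, spec, tiny_panel):
        anchors = anchor_matrix(tiny_panel, spec)
        for subj in tiny_panel.subjects:
            for name in tiny_panel.sites:
                assert anchors.at[subj, name] == base_value(
                    site_for(name, spec), subj, tiny_panel
                )

    def test_beta_values_outside_unit_interval_rejected(self):
        v2 = pd.DataFrame({"cg": [1.2]}, index=["A"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            MethylationPanel(v2, v2.iloc[:0])


class TestSimulateV4:
    def test_outputs_clipped_to_unit_interval(self, spec, small_cohort):
        sim = simulate_v4(small_cohort.methylation, spec, k=1, keep_raw=True)
        assert (sim.v4_sim.to_numpy() >= 0).all()
        assert (sim.v4_sim.to_numpy() <= 1).all()
        assert np.allclose(
            sim.v4_sim.to_numpy(), np.clip(sim.raw_v4.to_numpy(), 0, 1)
        )
        # a 0.4-SD site on interior anchors must actually hit the boundaries
        causal = spec.causal_cpgs[0].cpg_name
        vals = sim.v4_sim[causal].to_numpy()
        assert ((vals == 0.0) | (vals == 1.0)).any()

    def test_boundary_mass_matches_gaussian_tail(self, spec, small_cohort):
        """Fraction of exact 1s across replicates ~ mean P(anchor + 0.4 Z > 1)."""
        causal = spec.causal_cpgs[0]
        anchors = anchor_matrix(small_cohort.methylation, spec)[causal.cpg_name]
        p_hi = stats.norm.sf((1.0 - anchors.to_numpy()) / causal.sd_response).mean()
        sims = [simulate_v4(small_cohort.methylation, spec, k) for k in range(1, 51)]
        ones = np.mean([
            (s.v4_sim[causal.cpg_name].to_numpy() == 1.0).mean() for s in sims
        ])
        n = 50 * len(anchors)
        se = np.sqrt(p_hi * (1 - p_hi) / n)
        assert abs(ones - p_hi) < 3 * se

    def test_identical_seed_and_replicate_are_bit_identical(self, spec, small_cohort):
        a = simulate_v4(small_cohort.methylation, spec, k=3)
        b = simulate_v4(small_cohort.methylation, spec, k=3)
        assert a.v4_sim.equals(b.v4_sim)

    def test_replicates_are_independent(self, spec, small_cohort):
        a = simulate_v4(small_cohort.methylation, spec, k=1, keep_raw=True)
        b = simulate_v4(small_cohort.methylation, spec, k=2, keep_raw=True)
        anchors = anchor_matrix(small_cohort.methylation, spec).to_numpy()
        na = (a.raw_v4.to_numpy() - anchors).ravel()
        nb = (b.raw_v4.to_numpy() - anchors).ravel()
        r = np.corrcoef(na, nb)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(na))

    def test_noise_sd_and_zero_drift(self, spec, small_cohort):
        anchors = anchor_matrix(small_cohort.methylation, spec)
        sims = [
            simulate_v4(small_cohort.methylation, spec, k, keep_raw=True)
            for k in range(1, 26)
        ]
        for site, sd_true in [(spec.causal_cpgs[0].cpg_name, 0.4), ("cg_bg_0001", 0.03)]:
            noise = np.concatenate(
                [s.raw_v4[site].to_numpy() - anchors[site].to_numpy() for s in sims]
            )
            n = noise.size
            assert abs(noise.mean()) < 3 * sd_true / np.sqrt(n)  # no treatment drift
            assert abs(noise.std(ddof=1) - sd_true) < 3 * sd_true / np.sqrt(2 * n)


class TestMoments:
    def test_zero_noise_reproduces_anchor_moments(self, spec, small_cohort):
        cfg = {"cpgs": [
            {"cpg_name": "cg00000363", "site_class": "causal", "sd_response": 0.0,
             "linked_snp": "rs9661059", "v2_mean": 0.488, "v2_sd": 0.0589},
        ]}
        s0 = g.load_spec(cfg)
        sim = simulate_v4(small_cohort.methylation, s0, k=1)
        mean, sd = v4_moments(sim, "cg00000363")
        v2 = small_cohort.methylation.v2["cg00000363"]
        assert mean == pytest.approx(v2.mean())
        assert sd == pytest.approx(v2.std(ddof=1))

    def test_closed_form_matches_quadrature(self):
        """The clipped-normal moment formula against numeric integration."""
        for mu, sigma in [(0.5, 0.4), (0.488, 0.404), (0.9, 0.4), (0.1, 0.03), (-0.2, 0.5)]:
            m1_cf, sd_cf = clipped_normal_moments(mu, sigma)
            clip_pdf_m1 = integrate.quad(
                lambda x: x * stats.norm.pdf(x, mu, sigma), 0, 1
            )[0] + 1 * stats.norm.sf(1, mu, sigma)
            clip_pdf_m2 = integrate.quad(
                lambda x: x**2 * stats.norm.pdf(x, mu, sigma), 0, 1
            )[0] + 1 * stats.norm.sf(1, mu, sigma)
            assert m1_cf == pytest.approx(clip_pdf_m1, abs=1e-10)
            assert sd_cf == pytest.approx(
                np.sqrt(clip_pdf_m2 - clip_pdf_m1**2), abs=1e-10
            )

    def test_monte_carlo_agrees_with_oracle_at_half(self, spec):
        """Constant anchor 0.5, sd 0.4: simulated moments vs the oracle."""
        ids = pd.Index([f"S{i}" for i in range(500)], name="subject_id")
        causal = spec.causal_cpgs[0].cpg_name
        panel = MethylationPanel(
            pd.DataFrame({causal: np.full(500, 0.5)}, index=ids),
            pd.DataFrame(columns=[causal], index=ids[:0], dtype=float),
        )
        sims = [simulate_v4(panel, spec, k) for k in range(1, 41)]
        vals = np.concatenate([s.v4_sim[causal].to_numpy() for s in sims])
        m_or, sd_or = clipped_normal_moments(0.5, 0.4)
        assert abs(vals.mean() - m_or) < 3 * sd_or / np.sqrt(vals.size)
        assert abs(vals.std(ddof=1) - sd_or) < 3 * sd_or / np.sqrt(2 * vals.size)
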