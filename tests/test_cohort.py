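"""Synthetic cohort generator: determinism, distributions, fixture, round trips."""

import dataclasses

import numpy as np
import pytest

from neuroasym import (
    BATTERY_ISIS,
    GeneratorConfig,
    GroupParams,
    TraceParams,
    build_recovery_cycle,
    fixture_cohort,
    generate_blink_traces,
    generate_cohort,
    r2brrc_ai,
)
from neuroasym.cohort import build_target_curves, truncated_moments
from neuroasym.errors import ConfigurationError, ProtocolError


def _small_config(seed=0, mode_traces=False, **trace_kw):
    pd_g = dataclasses.replace(GeneratorConfig().pd, n=3)
    cbs_g = dataclasses.replace(GeneratorConfig().cbs, n=2)
    return GeneratorConfig(pd=pd_g, cbs=cbs_g, seed=seed,
                           traces=TraceParams(**trace_kw))


def _zero_sd_group(base: GroupParams, n):
    return dataclasses.replace(
        base, n=n, age=(base.age[0], 0.0), disease_duration=(base.disease_duration[0], 0.0),
        updrs_me=(base.updrs_me[0], 0.0), hy_stage=(2.0, 0.0),
        ai_r2brrc={isi: (m, 0.0) for isi, (m, _) in base.ai_r2brrc.items()},
        ai_mri=(base.ai_mri[0], 0.0), total_gm_volume=(base.total_gm_volume[0], 0.0),
    )


class TestGenerateCohort:
    def test_seed_determinism_summary(self):
        cfg = GeneratorConfig(seed=7)
        a = generate_cohort(cfg).to_frame()
        b = generate_cohort(cfg).to_frame()
        assert a.equals(b)

    def test_seed_determinism_traces_bitwise(self):
        cfg = _small_config(seed=7)
        a = generate_cohort(cfg, mode="trace")
        b = generate_cohort(cfg, mode="trace")
        for pid in a.traces:
            for side in ("MAS", "LAS"):
                for ta, tb in zip(a.traces[pid][side], b.traces[pid][side]):
                    assert np.array_equal(ta.samples, tb.samples)

    def test_different_seeds_differ(self):
        a = generate_cohort(GeneratorConfig(seed=1)).to_frame()
        b = generate_cohort(GeneratorConfig(seed=2)).to_frame()
        assert not a.equals(b)

    def test_zero_sd_degenerate_distribution(self):
        base = GeneratorConfig()
        cfg = GeneratorConfig(pd=_zero_sd_group(base.pd, 5), cbs=_zero_sd_group(base.cbs, 4))
        df = generate_cohort(cfg).to_frame()
        assert (df.loc[df.group == "PD", "ai_r2brrc_100"] == 0.86).all()
        assert (df.loc[df.group == "CBS", "ai_mri"] == 0.02).all()

    def test_ai_in_unit_interval_and_volumes_positive(self):
        df = generate_cohort(GeneratorConfig(seed=3)).to_frame()
        for col in ("ai_r2brrc_100", "ai_r2brrc_150", "ai_r2brrc_200", "ai_mri"):
            assert df[col].between(0, 1).all()
        assert (df["left_volume_mm3"] > 0).all() and (df["right_volume_mm3"] > 0).all()

    def test_large_n_mean_recovery(self):
        """Group means at n = 10,000 recover the configured (truncation-
        corrected) targets within Monte-Carlo error."""
        base = GeneratorConfig(seed=42)
        cfg = GeneratorConfig(pd=dataclasses.replace(base.pd, n=10_000),
                              cbs=dataclasses.replace(base.cbs, n=10_000), seed=42)
        df = generate_cohort(cfg).to_frame()
        pd_df = df[df.group == "PD"]
        cbs_df = df[df.group == "CBS"]
        assert pd_df["ai_r2brrc_100"].mean() == pytest.approx(0.86, abs=0.02)
        assert cbs_df["ai_r2brrc_100"].mean() == pytest.approx(0.10, abs=0.02)
        assert pd_df["age"].mean() == pytest.approx(64.6, abs=0.3)
        assert cbs_df["ai_mri"].mean() == pytest.approx(0.02, abs=0.002)
        # empirical SD matches the sampler's own analytic truncated moments
        m, sd = truncated_moments(0.86, 0.36, 0.0, 1.0)
        assert pd_df["ai_r2brrc_100"].std() == pytest.approx(sd, abs=0.01)
        assert m == pytest.approx(0.86, abs=1e-9)

    def test_hemispheres_realise_drawn_mri_ai(self):
        ds = generate_cohort(GeneratorConfig(seed=5))
        from neuroasym import mri_ai
        for p in ds.patients:
            ai = mri_ai(ds.metrics[p.patient_id], p.mas_side)
            assert ai == pytest.approx(ds.profiles[p.patient_id].ai_mri, abs=1e-12)

    @pytest.mark.parametrize("mutate", [
        lambda g: dataclasses.replace(g, ai_mri=(0.02, -0.1)),
        lambda g: dataclasses.replace(g, age=(np.nan, 7.5)),
        lambda g: dataclasses.replace(g, n=0),
        lambda g: dataclasses.replace(g, male_prop=1.4),
    ])
    def test_invalid_config_rejected(self, mutate):
        cfg = GeneratorConfig(pd=mutate(GeneratorConfig().pd))
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg)


class TestFixtureCohort:
    def test_group_sizes(self, fixture_df):
        assert (fixture_df.group == "PD").sum() == 14
        assert (fixture_df.group == "CBS").sum() == 10

    def test_misclassification_narrative_counts(self, fixture_df):
        pd_df = fixture_df[fixture_df.group == "PD"]
        cbs = fixture_df[fixture_df.group == "CBS"]
        assert (pd_df.ai_r2brrc_100 > 0.75).sum() == 12
        assert (cbs.ai_r2brrc_100 > 0.75).sum() == 1
        assert (cbs.ai_mri > 0.014).sum() == 7
        assert (pd_df.ai_mri > 0.014).sum() == 2

    def test_misclassified_cells_per_narrative(self, fixture_df):
        pd_low = fixture_df[(fixture_df.group == "PD") & (fixture_df.ai_r2brrc_100 <= 0.75)]
        assert (pd_low.ai_mri <= 0.014).all()
        cbs_high = fixture_df[(fixture_df.group == "CBS") & (fixture_df.ai_r2brrc_100 > 0.75)]
        assert len(cbs_high) == 1 and (cbs_high.ai_mri > 0.014).all()

    def test_linearly_separable_in_two_ai_plane(self, fixture_df):
        # explicit witness direction: score = ai_r2brrc - 40 * ai_mri
        score = fixture_df.ai_r2brrc_100 - 40 * fixture_df.ai_mri
        assert score[fixture_df.group == "PD"].min() > score[fixture_df.group == "CBS"].max()

    def test_all_ai_in_unit_interval(self, fixture_df):
        for col in ("ai_r2brrc_100", "ai_r2brrc_150", "ai_r2brrc_200", "ai_mri"):
            assert fixture_df[col].between(0, 1).all()

    def test_demographic_means_match_targets(self, fixture_df):
        pd_df = fixture_df[fixture_df.group == "PD"]
        cbs = fixture_df[fixture_df.group == "CBS"]
        assert pd_df.age.mean() == pytest.approx(64.6, abs=0.1)
        assert cbs.age.mean() == pytest.approx(71.1, abs=0.1)
        assert (pd_df.sex == "M").sum() == 7
        assert (cbs.mas_side == "right").sum() == 7

    def test_deterministic(self):
        assert fixture_cohort().to_frame().equals(fixture_cohort().to_frame())


class TestTraceMode:
    def test_noise_free_round_trip_exact(self):
        cfg = _small_config(seed=1, noise_sd_uv=0.0)
        ds = generate_cohort(cfg, mode="trace")
        for p in ds.patients:
            curves = {side: build_recovery_cycle(sw)
                      for side, sw in ds.traces[p.patient_id].items()}
            prof = ds.profiles[p.patient_id]
            for isi, target in prof.ai_r2brrc.items():
                got = r2brrc_ai(curves["MAS"], curves["LAS"], isi)
                assert got == pytest.approx(target, abs=1e-9)

    def test_noisy_extraction_within_declared_tolerance(self):
        cfg = _small_config(seed=2, trials_per_isi=10)  # default noise
        ds = generate_cohort(cfg, mode="trace")
        pid = ds.patients[0].patient_id
        prof_ai = ds.profiles[pid].ai_r2brrc
        targets = build_target_curves(prof_ai, ds.patients[0].group, cfg.traces,
                                      np.random.default_rng(0))
        curves = {side: build_recovery_cycle(sw) for side, sw in ds.traces[pid].items()}
        # extracted ratios within the declared +/-5 pp of the programmed base
        # profile envelope for every battery cell
        for side in ("MAS", "LAS"):
            for isi in BATTERY_ISIS:
                lo = cfg.traces.base_profile[isi] * (1 - prof_ai.get(isi, 0.0))
                hi = cfg.traces.base_profile[isi] * (1 + prof_ai.get(isi, 0.0))
                got = curves[side].ratios[isi]
                tol = cfg.traces.roundtrip_tol_pp
                assert lo - tol <= got <= hi + tol

    def test_pd_las_exceeds_mas_at_short_isi(self):
        cfg = _small_config(seed=3, noise_sd_uv=0.2)
        ds = generate_cohort(cfg, mode="trace")
        pd_patients = [p for p in ds.patients if p.group == "PD"]
        for p in pd_patients:
            curves = {side: build_recovery_cycle(sw)
                      for side, sw in ds.traces[p.patient_id].items()}
            if ds.profiles[p.patient_id].ai_r2brrc[100] > 0.1:
                assert curves["LAS"].ratios[100] > curves["MAS"].ratios[100]

    def test_group_mean_round_trip_between_modes(self):
        """Extracted per-ISI group-mean AIs from trace mode agree with the
        drawn (summary-mode) targets within the declared tolerance."""
        pd_g = dataclasses.replace(GeneratorConfig().pd, n=60)
        cbs_g = dataclasses.replace(GeneratorConfig().cbs, n=60)
        cfg = GeneratorConfig(pd=pd_g, cbs=cbs_g, seed=11)
        ds = generate_cohort(cfg, mode="trace")
        drawn = {"PD": {isi: [] for isi in (100, 150, 200)},
                 "CBS": {isi: [] for isi in (100, 150, 200)}}
        extracted = {"PD": {isi: [] for isi in (100, 150, 200)},
                     "CBS": {isi: [] for isi in (100, 150, 200)}}
        for p in ds.patients:
            curves = {side: build_recovery_cycle(sw)
                      for side, sw in ds.traces[p.patient_id].items()}
            for isi in (100, 150, 200):
                drawn[p.group][isi].append(ds.profiles[p.patient_id].ai_r2brrc[isi])
                extracted[p.group][isi].append(r2brrc_ai(curves["MAS"], curves["LAS"], isi))
        for grp in ("PD", "CBS"):
            for isi in (100, 150, 200):
                # AI tolerance propagated from the declared per-cell ratio
                # tolerance: |dAI| <= tol_pp / base_ratio at that ISI
                tol = cfg.traces.roundtrip_tol_pp / cfg.traces.base_profile[isi]
                assert np.mean(extracted[grp][isi]) == pytest.approx(
                    np.mean(drawn[grp][isi]), abs=tol)

    def test_missing_target_isi_protocol_error(self):
        cfg = _small_config()
        ds = generate_cohort(cfg)
        p = ds.patients[0]
        targets = build_target_curves(ds.profiles[p.patient_id].ai_r2brrc, p.group,
                                      cfg.traces, np.random.default_rng(0))
        del targets["MAS"][300]
        with pytest.raises(ProtocolError) as exc:
            generate_blink_traces(p, cfg, targets)
        assert 300 in exc.value.missing

    def test_battery_complete_per_protocol(self):
        cfg = _small_config(seed=4)
        ds = generate_cohort(cfg, mode="trace")
        for pid, battery in ds.traces.items():
            for side in ("MAS", "LAS"):
                isis = {int(round(t.isi_ms)) for t in battery[side] if t.is_conditioned}
                assert isis == set(BATTERY_ISIS)
                assert any(not t.is_conditioned for t in battery[side])
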