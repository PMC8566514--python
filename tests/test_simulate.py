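"""Synthetic-study generator: determinism, kinetics, spectra rendering,
and recovery of the planted ground truth by the screening pipeline."""

from __future__ import annotations

import math

import numpy as np
import pytest

from halomet import chem, io, pipeline, quant, simulate
from halomet.simulate import (
    MetaboliteSpec,
    StudyConfig,
    TissueKinetics,
    default_config,
    render_spectra,
    simulate_study,
)

SMALL = dict(tissues=("mature_leaves", "flowers"), dats=(14, 21, 28, 42), n_replicates=3)


@pytest.fixture(scope="module")
def small_study():
    cfg = default_config(seed=11, **SMALL)
    samples, truth = simulate_study(cfg)
    return cfg, samples, truth


class TestDeterminism:
    def test_same_seed_identical(self):
        cfg = default_config(seed=5, **SMALL)
        s1, t1 = simulate_study(cfg)
        s2, t2 = simulate_study(cfg)
        f1 = io.features_to_frame([f for s in s1 for f in s.features])
        f2 = io.features_to_frame([f for s in s2 for f in s.features])
        assert f1.equals(f2)
        assert t1.true_parent_conc == t2.true_parent_conc

    def test_different_seed_differs(self):
        s1, _ = simulate_study(default_config(seed=5, **SMALL))
        s2, _ = simulate_study(default_config(seed=6, **SMALL))
        assert s1[0].features[0].mz != s2[0].features[0].mz

    def test_render_spectra_deterministic(self, small_study):
        cfg, samples, _ = small_study
        treated = next(s for s in samples if s.meta.group == "treated")
        a = render_spectra(treated, cfg)
        b = render_spectra(treated, cfg)
        assert a == b


class TestKinetics:
    def test_xylem_series_peaks_early_then_declines(self):
        kin = simulate.DEFAULT_KINETICS["xylem_sap"]
        grid = simulate.DEFAULT_DATS["xylem_sap"]
        series = {t: kin.concentration(t) for t in grid}
        peak_dat = max(series, key=series.get)
        assert peak_dat in (7, 14)
        assert series[84] < 0.15 * series[peak_dat]
        # monotone decline after the peak
        tail = [series[t] for t in grid if t >= peak_dat]
        assert all(a >= b for a, b in zip(tail, tail[1:]))

    def test_mp_ratios_below_10pct_through_28_dat(self):
        cfg = default_config(seed=0)
        for spec in cfg.metabolites:
            for t in (7, 14, 21, 28):
                assert spec.fraction(t) < 0.10

    def test_invalid_kinetics_rejected(self):
        with pytest.raises(ValueError):
            TissueKinetics(amplitude=-1.0, t_peak=10.0)
        with pytest.raises(ValueError):
            StudyConfig(
                metabolites=(MetaboliteSpec("x", f84=1.5, tissues=("flowers",)),)
            )


class TestDegenerateConfigs:
    def test_zero_noise_zero_metabolites(self):
        cfg = default_config(
            seed=1,
            tissues=("mature_leaves",),
            dats=(28,),
            n_replicates=1,
            metabolites=(),
            n_matrix_features=0,
            n_noise_features=0,
            area_rsd=0.0,
            quant_rsd=0.0,
            bio_rsd=0.0,
            mz_jitter_ppm=0.0,
            rt_jitter_min=0.0,
            abundance_jitter_rsd=0.0,
        )
        samples, truth = simulate_study(cfg)
        treated = [s for s in samples if s.meta.group == "treated"]
        assert len(treated) == 1
        feats = treated[0].features
        # only the parent ion cluster remains, at its exact m/z
        assert len(feats) == 1
        assert feats[0].mz == pytest.approx(
            chem.cation_mz(chem.parse_formula("C19H14BrClN6O2")), abs=1e-9
        )
        kin = cfg.kinetics_for("mature_leaves")
        assert truth.true_parent_conc[treated[0].meta.sample_id] == pytest.approx(
            kin.concentration(28)
        )

    def test_noise_free_recovery_correction_is_exact(self):
        cfg = default_config(
            seed=2,
            tissues=("fruits",),
            dats=(42,),
            n_replicates=2,
            quant_rsd=0.0,
            bio_rsd=0.0,
        )
        samples, truth = simulate_study(cfg)
        for s in samples:
            if s.meta.group != "treated":
                continue
            corrected = quant.correct_concentration(s.parent_conc_raw, s.recovery_pct)
            assert corrected == pytest.approx(
                truth.true_parent_conc[s.meta.sample_id], rel=1e-9
            )


class TestRenderSpectra:
    def test_parent_triplet_in_ms1(self, small_study):
        cfg, samples, _ = small_study
        treated = next(s for s in samples if s.meta.group == "treated")
        frames, _ = render_spectra(treated, cfg)
        parent_feat = next(f for f in treated.features if f.label == "Cyantraniliprole")
        frame = min(frames, key=lambda fr: abs(fr[0] - parent_feat.rt))
        mzs = [mz for mz, _ in frame[1]]
        for ref in (473.012, 475.010, 477.007):
            assert any(abs(mz - ref) < 0.02 for mz in mzs), ref

    def test_glycoside_ms2_contains_aglycone(self, small_study):
        cfg, samples, _ = small_study
        anhydroglucose = chem.monoisotopic_mass(chem.parse_formula("C6H10O5"))
        for s in samples:
            spectra = render_spectra(s, cfg)[1]
            for spec in spectra:
                if spec["title"].endswith("TP651a"):
                    expected = spec["precursor_mz"] - anhydroglucose
                    assert any(
                        abs(mz - expected) < 1e-6 for mz, _ in spec["peaks"]
                    )
                    return
        pytest.fail("no TP651a MS2 spectrum rendered")

    def test_control_samples_render_without_study_compounds(self, small_study):
        cfg, samples, _ = small_study
        control = next(s for s in samples if s.meta.group == "control")
        frames, ms2 = render_spectra(control, cfg)
        assert frames and ms2 == []


class TestPipelineRecovery:
    def test_screen_recovers_ground_truth(self, small_study, suspects):
        cfg, samples, truth = small_study
        metrics = pipeline.evaluate_study(samples, truth, cfg, suspects)
        assert metrics["detection_rate"] >= 0.95
        assert metrics["matrix_false_positives"] == 0
        assert metrics["parent_rel_rmse"] <= 0.15
        assert metrics["mp_within_3sd_rate"] >= 0.9

    def test_noise_only_samples_produce_no_hits(self, suspects):
        cfg = default_config(
            seed=3,
            tissues=("flowers",),
            dats=(21,),
            n_replicates=2,
        )
        samples, _ = simulate_study(cfg)
        controls = [s for s in samples if s.meta.group == "control"]
        from halomet.screen import apply_thresholds, halogen_filter, match_suspects

        feats = [f for s in controls for f in s.features]
        survivors = halogen_filter(apply_thresholds(feats))
        assert match_suspects(survivors, suspects) == []

    def test_xylem_metabolite_free(self):
        # metabolites are never planted in xylem sap: translocation of
        # transformation products is negligible
        cfg = default_config(seed=4, tissues=("xylem_sap",), dats=(7, 14), n_replicates=2)
        samples, truth = simulate_study(cfg)
        assert truth.planted_fractions == {}
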