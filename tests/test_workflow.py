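import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from pstpupil import StudyConfig, run_study
from pstpupil.observer import ObserverParams
from pstpupil.pipeline import AnalysisConfig, analyze_session, read_eye_samples
from pstpupil.study import (ObserverStudyConfig, PupilStudyConfig, assign_subjects,
                            config_from_dict, generate_study,
                            simulate_test_session, training_day_amplitudes)
from pstpupil.workflow import training_trend

from conftest import clean_study_config, small_study_config


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = StudyConfig()
        assert (cfg.n_per_group, cfg.n_training_days, cfg.blocks_per_day,
                cfg.trials_per_block) == (10, 6, 2, 375)
        assert cfg.n_sets * cfg.set_size * 4 == 500

    def test_from_dict_round_trip(self):
        cfg = config_from_dict({
            "n_per_group": 3, "master_seed": 5,
            "staircase": {"check_every": 4, "ladder_ms": [300, 200, 100]},
            "observer": {"base": {"lapse_rate": 0.05}},
            "pupil": {"amplitudes_pre": {"1": 0, "2": 1, "3": 1, "4": 3}},
        })
        assert cfg.n_per_group == 3
        assert cfg.staircase.ladder_ms == (300.0, 200.0, 100.0)
        assert cfg.observer.base.lapse_rate == 0.05
        assert cfg.pupil.amplitudes_pre[4] == 3.0

    def test_unknown_key_rejected_with_message(self):
        with pytest.raises(ValueError, match="unknown top-level keys.*typo"):
            config_from_dict({"typo": 1})
        with pytest.raises(ValueError, match="unknown staircase keys"):
            config_from_dict({"staircase": {"chek": 4}})

    def test_group_assignment_balanced_and_deterministic(self):
        cfg = small_study_config(n_per_group=5)
        subs = assign_subjects(cfg)
        assert sum(s.group == "trained" for s in subs) == 5
        assert sum(s.group == "control" for s in subs) == 5
        again = assign_subjects(cfg)
        assert [s.group for s in subs] == [s.group for s in again]


class TestSessionSimulation:
    def test_session_independent_of_generation_order(self):
        cfg = clean_study_config({1: 0, 2: 1.0, 3: 1.0, 4: 2.0})
        subs = assign_subjects(cfg)
        direct = simulate_test_session(subs[1], "baseline", cfg)
        simulate_test_session(subs[0], "posttest", cfg)  # unrelated work
        after = simulate_test_session(subs[1], "baseline", cfg)
        pd.testing.assert_frame_equal(direct.eye, after.eye)
        pd.testing.assert_frame_equal(direct.responses, after.responses)

    def test_eye_stream_covers_every_trial(self):
        cfg = clean_study_config({1: 0, 2: 1.0, 3: 1.0, 4: 2.0})
        sess = simulate_test_session(assign_subjects(cfg)[0], "baseline", cfg)
        t = sess.eye["t_ms"].to_numpy()
        for row in sess.events.itertuples():
            n = np.searchsorted(t, row.probe_on_ms) - np.searchsorted(t, row.cue_on_ms)
            assert n == row.probe_on_ms - row.cue_on_ms


class TestGenerateStudy:
    def test_layout_and_manifest(self, tmp_path):
        cfg = small_study_config(n_per_group=1, n_sets=1, set_size=2,
                                 n_training_days=1, blocks_per_day=2,
                                 trials_per_block=12)
        manifest = generate_study(cfg, tmp_path)
        assert len(manifest["subjects"]) == 2
        groups = {v["group"] for v in manifest["subjects"].values()}
        assert groups == {"trained", "control"}
        for sid, entry in manifest["subjects"].items():
            assert set(entry["phases"]) >= {"baseline", "posttest"}
            if entry["group"] == "control":
                assert "training" not in entry["phases"]
            else:
                tr = entry["phases"]["training"]
                assert set(tr) == {"day1_block1", "day1_block2"}
                assert "trace" in tr["day1_block1"]
                assert "eye" in tr["day1_block1"]       # first block recorded
                assert "eye" not in tr["day1_block2"]   # second not, by default
        with open(tmp_path / "manifest.json") as fh:
            assert json.load(fh) == manifest

    def test_written_eye_round_trips_through_pipeline(self, tmp_path):
        cfg = clean_study_config({1: 0, 2: 1.0, 3: 1.0, 4: 3.0},
                                 n_per_group=1, n_sets=1, set_size=2)
        manifest = generate_study(cfg, tmp_path)
        sid, entry = next(iter(manifest["subjects"].items()))
        eye, meta = read_eye_samples(entry["phases"]["baseline"]["eye"])
        events = pd.read_csv(entry["phases"]["baseline"]["trials"])
        assert meta["subject"] == sid
        _, _, pct = analyze_session(eye, events, AnalysisConfig())
        sess = simulate_test_session(
            [s for s in assign_subjects(cfg) if s.subject_id == sid][0],
            "baseline", cfg)
        _, _, pct_mem = analyze_session(sess.eye, sess.events, AnalysisConfig())
        for lv in pct:
            assert pct[lv] == pytest.approx(pct_mem[lv], abs=1e-9)


class TestRunStudy:
    def test_report_structure_and_determinism(self):
        cfg = small_study_config()
        a = run_study(cfg, with_training=False)
        b = run_study(cfg, with_training=False)
        pd.testing.assert_frame_equal(a.subject_summary, b.subject_summary)
        # 2 groups x 2 times x 3 tasks pupil cells
        assert len(a.group_table) == 12
        assert set(a.anovas) == {"pupil_3way", "accuracy_3way", "rt_3way",
                                 "pupil_baseline_2way", "pupil_t4_minus_t2_2way"}
        assert a.followup.loc[0, "df"] == 2 * cfg.n_per_group - 2

    def test_zero_effect_config_yields_near_zero_cells(self):
        cfg = clean_study_config({1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
                                 n_per_group=2, n_sets=1, set_size=3)
        rep = run_study(cfg, with_training=False)
        assert np.allclose(rep.subject_summary["pupil_pct_change"], 0.0, atol=1e-9)

    def test_report_written_to_disk(self, tmp_path):
        cfg = small_study_config(n_per_group=2, n_training_days=1,
                                 trials_per_block=12)
        run_study(cfg, tmp_path)
        for name in ("subject_summary.tsv", "group_table.tsv", "anova_pupil_3way.tsv",
                     "posthoc_tests.tsv", "followup_test.tsv", "training_trend.tsv",
                     "qc_trials.tsv"):
            assert (tmp_path / name).exists(), name


class TestTrainingTrend:
    def _capable_clean_cfg(self, post_amps):
        cfg = clean_study_config({1: 0.0, 2: 1.0, 3: 1.0, 4: 3.17},
                                 n_per_group=1, n_training_days=3,
                                 trials_per_block=60)
        obs = ObserverStudyConfig(
            base=ObserverParams(threshold_ms={1: 2.0, 2: 2.0, 3: 2.0, 4: 2.0},
                                slope=5.0, lapse_rate=0.0),
            subject_threshold_log_sd=0.0, subject_rt_sd_s=0.0)
        pup = dataclasses.replace(cfg.pupil, amplitudes_post_trained=post_amps)
        return dataclasses.replace(cfg, observer=obs, pupil=pup)

    def test_constant_amplitudes_give_flat_trend(self):
        amps = {1: 0.0, 2: 1.0, 3: 1.0, 4: 3.17}
        cfg = self._capable_clean_cfg(amps)
        cfg = dataclasses.replace(
            cfg, pupil=dataclasses.replace(cfg.pupil, amplitudes_pre=amps,
                                           interpolate_training=False))
        daily, per_subject = training_trend(cfg)
        vals = daily["mean_t4_minus_t2_pct"].to_numpy()
        assert np.allclose(vals, vals[0], atol=1e-9)

    def test_shrinking_gap_recovered_monotone(self):
        cfg = self._capable_clean_cfg({1: 0.0, 2: 1.0, 3: 1.0, 4: 1.0})
        daily, per_subject = training_trend(cfg)
        vals = daily["mean_t4_minus_t2_pct"].to_numpy()
        assert np.all(np.diff(vals) < 0)  # injected gap shrinks linearly
        # the injected value is recovered exactly under clean conditions
        for day, got in zip(daily["day"], vals):
            amps = training_day_amplitudes(cfg, day)
            expect = 100 * ((1 + amps[4] / 100) / (1 + amps[2] / 100) - 1)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_low_trial_counts_flagged(self):
        cfg = self._capable_clean_cfg({1: 0.0, 2: 1.0, 3: 1.0, 4: 1.0})
        daily, per_subject = training_trend(cfg, low_n_trials=10)
        # the staircase rushes past Task 2, so 10 usable trials is rare
        assert (per_subject["low_n"] == 1).any()
        assert "n_task2_trials" in per_subject.columns
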