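from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ectopy import (
    BeatSeries,
    ClassifierConfig,
    RhythmLabel,
    classify_af_window,
    classify_nonaf_window,
    classify_recording,
    classify_window,
)
from ectopy.classifier import _alg1, _alg2
from ectopy.signal_io import compute_heart_rates
from ectopy.synthetic import RhythmSpec, generate_ibis, preset_for

from conftest import make_features

AF = RhythmLabel.AF
NSR = RhythmLabel.NSR
PACPVC = RhythmLabel.PACPVC


# ----- branch-enumeration tables: every leaf of both decision trees -----

ALG1_BRANCHES = [
    # (features, expected label, expected rule)
    # >=3 kites, both stds small -> PACPVC (incl. degenerate-count forcing)
    (dict(n123=3, std123=5.0), PACPVC, "alg1:9-10"),
    (dict(n123=2, n645=1, std123=4.0, std645=99.0), PACPVC, "alg1:9-10"),  # n645<=1 forced
    (dict(n123=1, n645=2, std123=99.0, std645=4.0), PACPVC, "alg1:9-10"),  # n123<=1 forced
    (dict(n123=0, n645=3, std645=9.9), PACPVC, "alg1:9-10"),
    # >=3 kites, dispersed angles -> rzero arbitration
    (dict(n123=4, std123=25.0, rzero=0.05), AF, "alg1:12-13"),
    (dict(n123=2, n645=2, std123=11.0, std645=2.0, rzero=0.12), AF, "alg1:12-13"),
    (dict(n123=4, std123=25.0, rzero=0.13), NSR, "alg1:14-15"),  # boundary: not < 0.13
    # <3 kites -> rzero only
    (dict(rzero=0.2), AF, "alg1:19-20"),
    (dict(rzero=0.9), NSR, "alg1:21-22"),
    (dict(rzero=0.5), NSR, "alg1:21-22"),  # boundary: not < 0.5
]

ALG2_BRANCHES = [
    # >=3 kites
    (dict(n123=3, std123=5.0), PACPVC, "alg2:9-10"),
    (dict(n123=2, n645=1, std123=4.0, std645=99.0), PACPVC, "alg2:9-10"),
    (dict(n123=1, n645=2, std123=99.0, std645=4.0), PACPVC, "alg2:9-10"),
    (dict(n123=4, std123=20.0, rzero=0.05), AF, "alg2:11-12"),
    (dict(n123=2, n645=2, std123=2.0, std645=10.5, rzero=0.9), AF, "alg2:11-12"),
    # bigeminy pair rule
    (dict(n24=6, n42=6, std24=3.0, std42=4.0, rzero=0.1), PACPVC, "alg2:16-17"),
    (dict(n24=5, n42=5, std24=10.0, std42=10.0, rzero=0.9), PACPVC, "alg2:16-17"),
    # edge families (D1: participation requires min pair-count > 3)
    (dict(n64=4, n45=4, std64=2.0, std45=3.0, rzero=0.9), PACPVC, "alg2:20-27(D1)"),
    (dict(n12=4, n23=5, std12=9.0, std23=1.0, rzero=0.9), PACPVC, "alg2:20-27(D1)"),
    (
        dict(n64=4, n45=4, n12=4, n23=4, std64=1.0, std45=1.0, std12=2.0, std23=2.0, rzero=0.2),
        PACPVC,
        "alg2:20-27(D1)",
    ),
    # participating family too dispersed -> fall through to rzero/noutside
    (dict(n64=4, n45=4, std64=30.0, std45=1.0, rzero=0.3), AF, "alg2:29-30"),
    (dict(rzero=0.3), AF, "alg2:29-30"),
    (dict(rzero=0.9, noutside=6), AF, "alg2:29-30"),
    # D1: no qualifying family, quiet window -> NSR, never vacuous PACPVC
    (dict(rzero=1.0, noutside=0), NSR, "alg2:31-32"),
    (dict(n12=3, n23=3, n64=3, n45=3, rzero=0.9, noutside=4), NSR, "alg2:31-32"),
]


class TestAlgorithm1:
    @pytest.mark.parametrize("kw,expected,rule", ALG1_BRANCHES)
    def test_branch(self, kw, expected, rule, cfg):
        f = make_features(**kw)
        label, fired = _alg1(f, cfg)
        assert label is expected
        assert fired == rule
        assert classify_af_window(f, cfg) is expected


class TestAlgorithm2:
    @pytest.mark.parametrize("kw,expected,rule", ALG2_BRANCHES)
    def test_branch(self, kw, expected, rule, cfg):
        f = make_features(**kw)
        label, fired = _alg2(f, cfg)
        assert label is expected
        assert fired == rule
        assert classify_nonaf_window(f, cfg) is expected

    def test_d1_quiet_window_is_not_pacpvc(self, cfg):
        # As printed, scarce families force std=0 and the max<=10 test would
        # label pure NSR as PAC/PVC; the amendment must prevent that.
        f = make_features()
        assert classify_nonaf_window(f, cfg) is NSR


def _random_features(rng):
    return make_features(
        n123=int(rng.integers(0, 8)),
        n645=int(rng.integers(0, 8)),
        n24=int(rng.integers(0, 12)),
        n42=int(rng.integers(0, 12)),
        n12=int(rng.integers(0, 12)),
        n23=int(rng.integers(0, 12)),
        n64=int(rng.integers(0, 12)),
        n45=int(rng.integers(0, 12)),
        std123=float(rng.uniform(0, 50)),
        std645=float(rng.uniform(0, 50)),
        std24=float(rng.uniform(0, 50)),
        std42=float(rng.uniform(0, 50)),
        std12=float(rng.uniform(0, 50)),
        std23=float(rng.uniform(0, 50)),
        std64=float(rng.uniform(0, 50)),
        std45=float(rng.uniform(0, 50)),
        rzero=float(rng.uniform(0, 1)),
        noutside=int(rng.integers(0, 30)),
    )


class TestTotalityAndMonotonicity:
    def test_every_feature_vector_gets_a_label(self, cfg, rng):
        for _ in range(5_000):
            f = _random_features(rng)
            for alg in (_alg1, _alg2):
                label, rule = alg(f, cfg)
                assert label in (NSR, AF, PACPVC)
                assert rule

    def test_std123_monotone(self, cfg, rng):
        # raising std123 through the threshold can only switch PACPVC off
        for _ in range(1_000):
            f = _random_features(rng)
            low = dataclasses.replace(f, std123=2.0)
            high = dataclasses.replace(f, std123=30.0)
            for alg in (_alg1, _alg2):
                label_low, _ = alg(low, cfg)
                label_high, _ = alg(high, cfg)
                if label_low is not PACPVC:
                    assert label_high is label_low
                assert label_high is not PACPVC or label_low is PACPVC


class TestConfigRoundTrip:
    def test_yaml_of_published_thresholds_equals_defaults(self, tmp_path, cfg, rng):
        p = tmp_path / "published.yaml"
        p.write_text(
            "std_angle_max: 10\nrzero_af: 0.13\nrzero_nsr: 0.5\n"
            "outside_min_af: 5\nmin_kites: 3\nmin_bigeminy_pairs: 5\n"
            "min_edge_pairs_exclusive: 3\nmin_beats: 10\n"
        )
        from_file = ClassifierConfig.from_yaml(p)
        for _ in range(300):
            f = _random_features(rng)
            assert classify_af_window(f, from_file) is classify_af_window(f, cfg)
            assert classify_nonaf_window(f, from_file) is classify_nonaf_window(f, cfg)


class TestClassifyWindow:
    def test_trigeminy_preset_nonaf_route(self):
        spec = dataclasses.replace(preset_for("trigeminy", "normal"), seed=3)
        hr = compute_heart_rates(generate_ibis(spec))
        decision = classify_window(hr, prior_af=False)
        assert decision.label is PACPVC
        assert decision.rule_fired == "alg2:9-10"
        assert decision.features is not None

    def test_af_simulation_af_route_monte_carlo(self):
        hits = 0
        n = 200
        for seed in range(n):
            hr = compute_heart_rates(generate_ibis(RhythmSpec("AF", base_hr=80, seed=seed)))
            if classify_window(hr, prior_af=True).label is AF:
                hits += 1
        assert hits / n >= 0.95

    def test_short_window_undetermined(self):
        decision = classify_window([60.0, 61.0, 60.0, 62.0], prior_af=False)
        assert decision.label is RhythmLabel.UNDETERMINED
        assert "min-beats" in decision.rule_fired

    def test_stub_routing_recorded(self):
        hr = compute_heart_rates(generate_ibis(RhythmSpec("AF", base_hr=80, seed=1)))
        decision = classify_window(hr, prior_af=None)
        assert decision.rule_fired.startswith("route=stub")
        assert decision.label is AF


class TestClassifyRecording:
    def _windows(self, n=3):
        out = []
        for i in range(n):
            spec = RhythmSpec("NSR", base_hr=70, jitter_sd=1.0, seed=i)
            times = generate_ibis(spec)
            out.append(BeatSeries(peak_times=times[times < 30.0], window_id=i))
        return out

    def test_routing_respects_labels(self):
        windows = self._windows(3)
        decisions = classify_recording(windows, prior_labels=[True, False, False])
        assert [d.window_id for d in decisions] == [0, 1, 2]
        assert decisions[0].rule_fired.startswith("alg1")
        assert decisions[1].rule_fired.startswith("alg2")

    def test_empty_recording(self):
        assert classify_recording([]) == []

    def test_misaligned_labels_rejected(self):
        with pytest.raises(ValueError, match="does not match"):
            classify_recording(self._windows(2), prior_labels=[True])

    def test_stub_noted_when_labels_absent(self):
        decisions = classify_recording(self._windows(2))
        assert all(d.rule_fired.startswith("route=stub") for d in decisions)
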