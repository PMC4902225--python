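"""Feature registry: closed forms, invariances, pruning, subsampling."""

import numpy as np
import pandas as pd
import pytest

import redstartcalls as rc
from redstartcalls.audio import HOP, Spectrogram, Waveform, compute_spectrogram
from redstartcalls.features import (
    DEFAULT_SPEC,
    METADATA_COLUMNS,
    SCALE_DEPENDENT_FEATURES,
    batch_features,
    compute_features,
    feature_columns,
    load_feature_table,
    prune_correlated,
    subsample_calls,
    subset_consistency,
)
from redstartcalls.synth import DEFAULT_TEMPLATES, CallClip


@pytest.fixture(scope="module")
def tone_clip():
    fs = 44100
    x = 0.8 * np.sin(2 * np.pi * 8000.0 * np.arange(4410) / fs)
    return Waveform(x, fs)


class TestComputeFeatures:
    def test_registry_has_95_unique_measurements(self):
        assert len(DEFAULT_SPEC) == 95
        assert len({d.name for d in DEFAULT_SPEC}) == 95

    def test_all_values_finite_on_real_call(self, default_population):
        _, clips, _ = default_population
        vec = compute_features(compute_spectrogram(clips[0].waveform))
        assert len(vec) == 95
        assert np.all(np.isfinite(vec.to_numpy()))

    def test_rectangular_envelope_closed_forms(self, tone_clip):
        """Stationary tone: uniform e(t), impulse-like s(f)."""
        sg = compute_spectrogram(tone_clip)
        vec = compute_features(sg)
        hop_ms = HOP / 44100 * 1e3
        frame_span_ms = sg.n_frames * hop_ms
        assert vec["dur_90"] == pytest.approx(0.9 * frame_span_ms, abs=hop_ms)
        assert vec["dur_50"] == pytest.approx(0.5 * frame_span_ms, abs=hop_ms)
        bin_width = 44100 / 256
        assert vec["bw_90"] <= 2 * bin_width if "bw_90" in vec else True
        assert vec["bw_pow_90"] <= 2 * bin_width
        assert abs(vec["f_pow_center"] - 8000.0) <= bin_width

    def test_empty_clip_raises(self):
        sg = Spectrogram(
            power=np.zeros((10, 129)),
            times=np.arange(10) * 38 / 44100,
            freqs=np.fft.rfftfreq(256, 1 / 44100),
        )
        with pytest.raises(ValueError, match="empty clip"):
            compute_features(sg)

    def test_amplitude_invariance(self, tone_clip):
        sg1 = compute_spectrogram(tone_clip)
        sg2 = compute_spectrogram(Waveform(tone_clip.samples * 0.37, 44100))
        v1, v2 = compute_features(sg1), compute_features(sg2)
        for d in DEFAULT_SPEC:
            if d.name in SCALE_DEPENDENT_FEATURES:
                continue
            assert np.isclose(v1[d.name], v2[d.name], rtol=1e-9, atol=1e-12), d.name

    def test_scale_dependent_features_scale_as_power(self, tone_clip):
        c = 0.5
        v1 = compute_features(compute_spectrogram(tone_clip))
        v2 = compute_features(
            compute_spectrogram(Waveform(tone_clip.samples * c, 44100))
        )
        for name in SCALE_DEPENDENT_FEATURES:
            assert v2[name] == pytest.approx(c**2 * v1[name], rel=1e-9)

    def test_padding_insensitivity(self):
        """5 ms of extra silence moves durations/bandwidths by <= 1 hop/bin."""
        fs = 44100
        body = np.sin(2 * np.pi * 7000 * np.arange(3000) / fs) * np.hanning(3000)
        pad = np.zeros(221)
        short = np.concatenate([pad, body, pad])
        longer = np.concatenate([pad, pad, body, pad, pad])
        v1 = compute_features(compute_spectrogram(Waveform(short, fs)))
        v2 = compute_features(compute_spectrogram(Waveform(longer, fs)))
        hop_ms = HOP / fs * 1e3
        bin_width = fs / 256
        for name, tol in [
            ("dur_90", hop_ms), ("dur_50", hop_ms),
            ("bw_pow_90", bin_width), ("bw_pow_50", bin_width),
            ("conc_time", hop_ms), ("ent_pow", 0.05),
        ]:
            assert abs(v1[name] - v2[name]) <= tol, name

    def test_time_shift_invariance(self):
        fs = 44100
        body = np.sin(2 * np.pi * 7000 * np.arange(3000) / fs) * np.hanning(3000)
        a = np.concatenate([np.zeros(38 * 5), body, np.zeros(38 * 40)])
        b = np.concatenate([np.zeros(38 * 40), body, np.zeros(38 * 5)])
        v1 = compute_features(compute_spectrogram(Waveform(a, fs)))
        v2 = compute_features(compute_spectrogram(Waveform(b, fs)))
        hop_ms = HOP / fs * 1e3
        for name in ("dur_90", "bw_pow_90", "conc_time", "conc_pow", "ent_time"):
            tol = hop_ms if "dur" in name or "conc_t" in name else 1e-6 * abs(v1[name]) + 0.05
            assert abs(v1[name] - v2[name]) <= max(tol, 1e-9), name

    def test_v_call_contour_shape(self):
        """V-type call: at least one inflection, minimum in the middle third."""
        profile = rc.BirdProfile("b", "M", "HY", {}, {"V": 1.0})
        zero = {k: 0.0 for k in ("duration_ms", "freq_hz", "tail_mod_depth_hz",
                                 "tail_mod_rate_hz")}
        cfg = rc.PopulationConfig(snr_db=np.inf, within_bird_sd=zero,
                                  between_bird_sd=zero, seed=0)
        clip = rc.synthesize_call(profile, DEFAULT_TEMPLATES["V"], cfg)
        vec = compute_features(compute_spectrogram(clip.waveform))
        assert vec["contour_inflections"] >= 1
        t5, t95 = vec["t_pct_5"], vec["t_pct_95"]
        # frame of the contour minimum lies in the middle third of the span
        sg = compute_spectrogram(clip.waveform)
        times_ms = sg.times * 1e3
        span = (times_ms >= t5) & (times_ms <= t95)
        contour = sg.freqs[np.argmax(sg.power[span], axis=1)]
        pos = np.argmin(contour) / (contour.size - 1)
        assert 1 / 3 <= pos <= 2 / 3


class TestPercentileProperties:
    """Distribution-helper invariants over arbitrary energy envelopes."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(np.float64, 40,
               elements=st.floats(0.0, 1e3, allow_nan=False)).filter(
            lambda w: w.sum() > 0
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_percentile_locations_monotone_and_bounded(self, w):
        from redstartcalls.features import _percentile_locations

        centers = np.arange(40, dtype=float)
        locs = _percentile_locations(w, centers, [2.5, 5, 25, 50, 75, 95, 97.5])
        assert np.all(np.diff(locs) >= -1e-12)
        assert locs[0] >= centers[0] - 0.5 - 1e-12
        assert locs[-1] <= centers[-1] + 0.5 + 1e-12

    @given(
        arrays(np.float64, 30,
               elements=st.floats(0.0, 1e3, allow_nan=False)).filter(
            lambda w: w.max() > 0
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_concentration_and_modewidth_bounded(self, w):
        from redstartcalls.features import _concentration, _modewidth

        assert 1.0 <= _concentration(w, 1.0) <= 30.0
        assert 1.0 <= _modewidth(w, 1.0) <= 30.0


class TestBatchFeatures:
    def test_full_population_table_shape(self, feature_table):
        assert feature_table.shape == (180, 5 + 95)
        assert list(feature_table.columns[:5]) == list(METADATA_COLUMNS)
        assert feature_table[feature_columns(feature_table)].notna().all().all()

    def test_empty_list_gives_empty_table_with_header(self):
        table, errors = batch_features([])
        assert len(table) == 0 and not errors
        assert len(table.columns) == 5 + 95

    def test_corrupt_clip_flagged_not_fatal(self, default_population):
        _, clips, _ = default_population
        bad = CallClip(Waveform(np.zeros(4410), 44100), "x", "M", "HY", "A")
        table, errors = batch_features(list(clips[:9]) + [bad])
        assert len(table) == 9
        assert len(errors) == 1 and errors[0][0] == 9


class TestPruneCorrelated:
    def test_exact_duplicate_column_removed(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        df["dup"] = df["a"]
        df["bird_id"] = "z"
        pruned, report = prune_correlated(df)
        feats = feature_columns(pruned)
        assert ("a" in feats) ^ ("dup" in feats)
        assert (report["reason"] == "correlated").sum() == 1

    def test_independent_columns_survive(self, rng):
        df = pd.DataFrame(rng.normal(size=(180, 20)),
                          columns=[f"x{i}" for i in range(20)])
        pruned, report = prune_correlated(df)
        assert len(feature_columns(pruned)) == 20
        assert len(report) == 0

    def test_constant_column_removed_first(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        df["const"] = 1.0
        pruned, report = prune_correlated(df)
        assert "const" not in pruned.columns
        assert report.iloc[0]["reason"] == "constant"

    def test_result_has_no_remaining_high_correlation(self, pruned_table):
        X = pruned_table[feature_columns(pruned_table)].to_numpy()
        corr = np.abs(np.corrcoef(X, rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.95

    def test_bad_threshold_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)))
        df.columns = ["a", "b", "c"]
        with pytest.raises(ValueError):
            prune_correlated(df, threshold=1.5)


class TestSubsample:
    def test_default_yields_180_rows(self, pruned_table):
        out = subsample_calls(pruned_table, seed=0)
        assert len(out) == 180
        assert (out.groupby("bird_id").size() == 5).all()

    def test_bird_below_threshold_excluded(self):
        df = pd.DataFrame(
            {"bird_id": ["a"] * 4 + ["b"] * 6, "f1": np.arange(10.0)}
        )
        out = subsample_calls(df, n_per_bird=5, min_calls=5, seed=0)
        assert set(out["bird_id"]) == {"b"}

    def test_seed_reproducible(self, pruned_table):
        a = subsample_calls(pruned_table, seed=42)
        b = subsample_calls(pruned_table, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_request_rejected(self, pruned_table):
        with pytest.raises(ValueError):
            subsample_calls(pruned_table, n_per_bird=6, min_calls=5)


class TestSubsetConsistency:
    def test_identity_subset_passes_with_zero_diffs(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=[f"f{i}" for i in range(5)])
        res = subset_consistency(df, df)
        assert res["pass"]
        assert np.allclose(res["per_feature"]["mean_diff"], 0.0)

    def test_rejection_rate_near_nominal(self, rng):
        """Random-half subsets: omnibus rejects at about the nominal level."""
        rej = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(60, 10)),
                              columns=[f"f{i}" for i in range(10)])
            sub = df.sample(30, random_state=int(rng.integers(2**31)))
            rej += not subset_consistency(df, sub)["pass"]
        rate = rej / reps
        half_band = 2.576 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= half_band

    def test_injected_shift_flagged(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 6)),
                          columns=[f"f{i}" for i in range(6)])
        sub = df.sample(40, random_state=1).copy()
        sub["f3"] = sub["f3"] + 5.0
        res = subset_consistency(df, sub)
        flagged = res["per_feature"].loc[res["per_feature"]["flagged"], "feature"]
        assert "f3" in set(flagged)
        assert not res["pass"]

    def test_mismatched_columns_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
        b = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "z"])
        with pytest.raises(ValueError, match="z"):
            subset_consistency(a, b)


class TestLoadFeatureTable:
    def test_column_mapped_csv_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(12, 4)),
                          columns=[f"feat{i}" for i in range(4)])
        df.insert(0, "Band ID", [f"b{i // 3}" for i in range(12)])
        df.insert(1, "Sex", ["M", "F"] * 6)
        path = tmp_path / "deposited_synthetic.csv"
        df.to_csv(path, index=False)
        table = load_feature_table(path, {"Band ID": "bird_id", "Sex": "sex"})
        assert list(table["bird_id"][:3]) == ["b0"] * 3
        assert len(feature_columns(table)) == 4

    def test_missing_metadata_is_an_error(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("abc"))
        path = tmp_path / "x.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="column_map"):
            load_feature_table(path)
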