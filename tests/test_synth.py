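"""Synthetic population generator: composition, determinism, latent effects."""

import numpy as np
import pytest
from scipy import stats

import redstartcalls as rc
from redstartcalls.audio import compute_spectrogram
from redstartcalls.synth import (
    DEFAULT_TEMPLATES,
    VariantTemplate,
    analytic_contour,
)


class TestPopulation:
    def test_default_composition_matches_study(self):
        profiles = rc.sample_population(rc.PopulationConfig(seed=0))
        sexes = [p.sex for p in profiles]
        ages = [p.age for p in profiles]
        assert len(profiles) == 36
        assert sexes.count("M") == 14 and sexes.count("F") == 22
        assert ages.count("HY") == 25 and ages.count("AHY") == 11

    def test_same_seed_same_profiles(self):
        cfg = rc.PopulationConfig(seed=7)
        assert rc.sample_population(cfg) == rc.sample_population(cfg)

    def test_sex_fraction_tracks_ratio(self):
        cfg = rc.PopulationConfig(n_birds=10_000, sex_ratio=0.4, seed=2)
        profiles = rc.sample_population(cfg)
        frac = np.mean([p.sex == "M" for p in profiles])
        half_band = 2.576 * np.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.4) <= half_band

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sex_ratio": 1.4},
            {"age_ratio": -0.1},
            {"n_birds": -1},
            {"freq_low_bound": 0.0},
            {"freq_low_bound": 9000.0, "freq_high_bound": 5000.0},
            {"calls_per_bird": (5, 2)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            rc.PopulationConfig(**kwargs)

    def test_zero_birds_rejected_by_sampler(self):
        cfg = rc.PopulationConfig(n_birds=0)
        with pytest.raises(ValueError):
            rc.sample_population(cfg)


def _pure_profile(sex="M"):
    return rc.BirdProfile(
        bird_id="pure",
        sex=sex,
        age="HY",
        param_offsets={},
        variant_propensity={"A": 1.0},
    )


def _clean_config(**kwargs):
    zero = {k: 0.0 for k in ("duration_ms", "freq_hz", "tail_mod_depth_hz",
                             "tail_mod_rate_hz")}
    defaults = dict(snr_db=np.inf, within_bird_sd=dict(zero),
                    between_bird_sd=dict(zero), seed=0)
    defaults.update(kwargs)
    return rc.PopulationConfig(**defaults)


class TestSynthesizeCall:
    def test_v_type_minimum_at_midpoint(self):
        """The V shape's frequency minimum sits near the call's midpoint."""
        cfg = _clean_config()
        clip = rc.synthesize_call(_pure_profile(), DEFAULT_TEMPLATES["V"], cfg)
        sg = compute_spectrogram(clip.waveform)
        e = sg.power.sum(axis=1)
        live = e > 0.01 * e.max()  # frames inside the call body
        contour = sg.freqs[np.argmax(sg.power[live], axis=1)]
        pos = np.argmin(contour) / (contour.size - 1)
        assert abs(pos - 0.5) <= 0.10

    def test_peak_contour_tracks_analytic_contour(self):
        """Noise-free render: frame peak frequency follows the target contour."""
        template = VariantTemplate(
            "V", ((0.0, 9100.0), (0.5, 6000.0), (1.0, 8900.0)),
            inflection_sharpness=0.04, tail_mod_depth=0.0,
            tail_mod_rate=1000.0, tail_fraction=0.0,
        )
        cfg = _clean_config()
        clip = rc.synthesize_call(_pure_profile(), template, cfg)
        sg = compute_spectrogram(clip.waveform)
        e = sg.power.sum(axis=1)
        n_body = int(round(72e-3 * cfg.sample_rate))
        target = analytic_contour(template, n_body, sample_rate=cfg.sample_rate)
        pad = int(round(cfg.pad_ms * 1e-3 * cfg.sample_rate))
        bin_width = cfg.sample_rate / 256
        # compare over the central 90%-energy span of frames
        cum = np.cumsum(e) / e.sum()
        span = (cum > 0.05) & (cum < 0.95)
        for i in np.flatnonzero(span):
            center = int(round(i * 38 + 255 / 2)) - pad
            if not 0 <= center < n_body:
                continue
            peak = sg.freqs[np.argmax(sg.power[i])]
            assert abs(peak - target[center]) <= bin_width

    def test_flat_template_is_pure_tone(self):
        template = VariantTemplate(
            "A", ((0.0, 8000.0), (1.0, 8000.0)),
            inflection_sharpness=0.0, tail_mod_depth=0.0,
            tail_mod_rate=1000.0, tail_fraction=0.0,
        )
        clip = rc.synthesize_call(_pure_profile(), template, _clean_config())
        sg = compute_spectrogram(clip.waveform)
        body = sg.power.sum(axis=1) > 0
        peak_bins = np.argmax(sg.power[body], axis=1)
        assert np.all(np.abs(peak_bins - round(8000 * 256 / 44100)) <= 1)

    def test_nyquist_violation_raises(self):
        template = VariantTemplate(
            "A", ((0.0, 21_000.0), (1.0, 25_000.0)),
            inflection_sharpness=0.0, tail_mod_depth=0.0,
            tail_mod_rate=1000.0, tail_fraction=0.0,
        )
        cfg = _clean_config(freq_high_bound=21_500.0)
        with pytest.raises(ValueError, match="Nyquist"):
            rc.synthesize_call(_pure_profile(), template, cfg)

    def test_peak_amplitude_bounded(self, default_population):
        _, clips, _ = default_population
        assert all(np.max(np.abs(c.waveform.samples)) <= 1.0 for c in clips)

    def test_template_invariants(self):
        v = DEFAULT_TEMPLATES["V"]
        tmin = v.breakpoint_times[np.argmin(v.breakpoint_freqs)]
        assert abs(tmin - 0.5) <= 0.05
        s = DEFAULT_TEMPLATES["S"]
        assert s.breakpoint_freqs[-1] < s.breakpoint_freqs[0]
        for t in DEFAULT_TEMPLATES.values():
            assert t.breakpoint_freqs.min() >= 3500.0
            assert t.breakpoint_freqs.max() <= 10_300.0


class TestDataset:
    def test_manifest_has_180_calls(self, default_population):
        _, clips, manifest = default_population
        assert len(manifest) == 180 and len(clips) == 180

    def test_calls_per_bird_range_respected(self):
        cfg = rc.PopulationConfig(n_birds=12, calls_per_bird=(1, 63), seed=3)
        _, manifest = rc.generate_clips(cfg)
        counts = manifest.groupby("bird_id").size()
        assert counts.between(1, 63).all() and len(counts) == 12

    def test_zero_calls_gives_empty_manifest(self, tmp_path):
        cfg = rc.PopulationConfig(calls_per_bird=0, seed=0)
        manifest = rc.generate_dataset(cfg, tmp_path / "empty")
        assert len(manifest) == 0
        assert not list((tmp_path / "empty").glob("*.wav"))

    def test_dataset_bytes_deterministic(self, tmp_path):
        cfg = rc.PopulationConfig(n_birds=3, seed=11)
        m1 = rc.generate_dataset(cfg, tmp_path / "a")
        m2 = rc.generate_dataset(cfg, tmp_path / "b")
        assert m1.equals(m2)
        for f in m1["file"]:
            assert (tmp_path / "a" / f).read_bytes() == (tmp_path / "b" / f).read_bytes()

    def test_contour_frequencies_within_bounds(self, default_population):
        """Realized spectral peaks stay inside the configured call band."""
        cfg, clips, _ = default_population
        bin_width = cfg.sample_rate / 256
        rng = np.random.default_rng(0)
        for clip in [clips[i] for i in rng.choice(len(clips), 30, replace=False)]:
            sg = compute_spectrogram(clip.waveform)
            e = sg.power.sum(axis=1)
            live = e > 0.05 * e.max()
            contour = sg.freqs[np.argmax(sg.power[live], axis=1)]
            assert contour.min() >= cfg.freq_low_bound - bin_width
            assert contour.max() <= cfg.freq_high_bound + bin_width


class TestLatentStructure:
    def test_sex_effect_on_duration(self):
        cfg = rc.PopulationConfig(n_birds=200, calls_per_bird=6, seed=21)
        _, manifest = rc.generate_clips(cfg)
        by_sex = manifest.groupby("sex")["realized_duration_ms"].mean()
        # configured 6 ms male-female gap, within Monte-Carlo error
        assert by_sex["M"] - by_sex["F"] == pytest.approx(6.0, abs=1.5)

    def test_identity_variance_dominates_within(self, default_population):
        _, _, manifest = default_population
        groups = [g["realized_duration_ms"].to_numpy()
                  for _, g in manifest.groupby("bird_id")]
        grand = manifest["realized_duration_ms"].to_numpy()
        between_var = np.var([g.mean() for g in groups], ddof=1)
        within_var = np.mean([np.var(g, ddof=1) for g in groups])
        assert len(groups) >= 30
        assert between_var > within_var

    def test_age_has_no_effect(self):
        cfg = rc.PopulationConfig(n_birds=120, calls_per_bird=5, seed=33)
        _, manifest = rc.generate_clips(cfg)
        for col in ("realized_duration_ms", "realized_freq_offset_hz"):
            hy = manifest.loc[manifest.age == "HY", col]
            ahy = manifest.loc[manifest.age == "AHY", col]
            assert stats.ks_2samp(hy, ahy).pvalue > 0.01
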