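"""Synthetic flight-call populations.

Generates WAV clips of short frequency-modulated calls with the latent
statistical structure the downstream analysis assumes: every bird carries an
individual signature (per-bird offsets on duration, frequency and tail
modulation that are larger than its call-to-call variation), males call
longer than females (72 vs 66 ms on average), call frequencies stay inside
3.5-10.3 kHz, variant-shape propensities differ by sex, and age has no
effect on anything.

Five qualitative contour shapes are modelled, labelled A, G, M, S and V:

* A - the typical 'tick-mark': a fall into a concave inflection followed by
  a rise and a modulated tail;
* G - an acute convex inflection, then a shallow obtuse one and a modulated
  tail;
* M - convex inflections at the beginning and tail with a concave one in
  the middle;
* S - an obtuse concave inflection mid-call, the tail ending lower in
  frequency than the start;
* V - an acute concave inflection with approximately equal durations on
  either side.

Each template is a piecewise-linear frequency contour (breakpoints in
relative time), smoothed with a raised-cosine kernel, with a sinusoidal
frequency modulation over the final portion of the call.  These breakpoint
tables are calibration constants of this package, not field measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import windows

from .audio import Waveform, write_wav

__all__ = [
    "VariantTemplate",
    "BirdProfile",
    "PopulationConfig",
    "CallClip",
    "DEFAULT_TEMPLATES",
    "DEFAULT_SEX_VARIANT_TABLE",
    "sample_population",
    "synthesize_call",
    "generate_clips",
    "generate_dataset",
]

VARIANT_CODES = ("A", "G", "M", "S", "V")

#: Identity / within-bird parameters that receive random offsets.
OFFSET_PARAMS = ("duration_ms", "freq_hz", "tail_mod_depth_hz", "tail_mod_rate_hz")


@dataclass(frozen=True)
class VariantTemplate:
    """Piecewise frequency-contour template for one call-shape variant."""

    variant_code: str
    contour_breakpoints: tuple  # ((rel_time, freq_hz), ...)
    inflection_sharpness: float  # smoothing half-width, fraction of duration
    tail_mod_depth: float  # Hz
    tail_mod_rate: float  # Hz
    tail_fraction: float  # fraction of duration carrying the modulated tail

    def __post_init__(self):
        t = np.array([b[0] for b in self.contour_breakpoints], dtype=float)
        if t[0] != 0.0 or t[-1] != 1.0 or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"template {self.variant_code}: breakpoint times must increase "
                "strictly from 0 to 1"
            )
        if not (0 <= self.tail_fraction < 1):
            raise ValueError("tail_fraction must lie in [0, 1)")

    @property
    def breakpoint_times(self) -> np.ndarray:
        return np.array([b[0] for b in self.contour_breakpoints], dtype=float)

    @property
    def breakpoint_freqs(self) -> np.ndarray:
        return np.array([b[1] for b in self.contour_breakpoints], dtype=float)


DEFAULT_TEMPLATES: dict[str, VariantTemplate] = {
    "A": VariantTemplate(
        "A",
        ((0.0, 8800.0), (0.35, 6600.0), (0.62, 8200.0), (1.0, 8000.0)),
        inflection_sharpness=0.08,
        tail_mod_depth=400.0,
        tail_mod_rate=950.0,
        tail_fraction=0.40,
    ),
    "G": VariantTemplate(
        "G",
        ((0.0, 7200.0), (0.22, 8800.0), (0.55, 7400.0), (1.0, 7800.0)),
        inflection_sharpness=0.10,
        tail_mod_depth=450.0,
        tail_mod_rate=900.0,
        tail_fraction=0.42,
    ),
    "M": VariantTemplate(
        "M",
        ((0.0, 7000.0), (0.2, 8600.0), (0.5, 6600.0), (0.78, 8500.0), (1.0, 7600.0)),
        inflection_sharpness=0.07,
        tail_mod_depth=300.0,
        tail_mod_rate=1000.0,
        tail_fraction=0.22,
    ),
    "S": VariantTemplate(
        "S",
        ((0.0, 8600.0), (0.5, 6200.0), (1.0, 7100.0)),
        inflection_sharpness=0.16,
        tail_mod_depth=260.0,
        tail_mod_rate=850.0,
        tail_fraction=0.35,
    ),
    "V": VariantTemplate(
        "V",
        ((0.0, 9100.0), (0.5, 6000.0), (1.0, 8900.0)),
        inflection_sharpness=0.04,
        tail_mod_depth=160.0,
        tail_mod_rate=1000.0,
        tail_fraction=0.15,
    ),
}

#: Default per-sex variant propensities, proportional to the observed
#: sex-by-variant call counts (males: A 40, G 0, M 6, S 1, V 23 of 70;
#: females: A 35, G 7, M 0, S 28, V 40 of 110).
DEFAULT_SEX_VARIANT_TABLE: dict[str, dict[str, float]] = {
    "M": {"A": 40 / 70, "G": 0.0, "M": 6 / 70, "S": 1 / 70, "V": 23 / 70},
    "F": {"A": 35 / 110, "G": 7 / 110, "M": 0.0, "S": 28 / 110, "V": 40 / 110},
}


def _default_between_sd() -> dict[str, float]:
    return {
        "duration_ms": 6.0,
        "freq_hz": 280.0,
        "tail_mod_depth_hz": 90.0,
        "tail_mod_rate_hz": 130.0,
    }


def _default_within_sd() -> dict[str, float]:
    return {
        "duration_ms": 3.0,
        "freq_hz": 70.0,
        "tail_mod_depth_hz": 30.0,
        "tail_mod_rate_hz": 40.0,
    }


@dataclass(frozen=True)
class BirdProfile:
    """Latent identity of one bird: sex, age, parameter offsets, variant use."""

    bird_id: str
    sex: str  # 'M' or 'F'
    age: str  # 'HY' or 'AHY'
    param_offsets: dict  # additive identity effects per OFFSET_PARAMS entry
    variant_propensity: dict  # probability over VARIANT_CODES

    def __post_init__(self):
        total = sum(self.variant_propensity.get(v, 0.0) for v in VARIANT_CODES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"variant_propensity for {self.bird_id} sums to {total}, not 1"
            )


@dataclass(frozen=True)
class PopulationConfig:
    """Study-design and effect-size configuration for a synthetic population.

    Defaults mirror the reference study's composition: 36 birds (14 male /
    22 female, 25 hatch-year / 11 after-hatch-year), 5 calls per bird, mean
    call duration 72 ms for males and 66 ms for females (all realized
    durations clipped to 38-95 ms), call frequencies within 3.5-10.3 kHz,
    44.1 kHz sampling.  Between-bird standard deviations exceed within-bird
    ones so that calls carry an individual signature; age carries no effect.
    """

    n_birds: int = 36
    calls_per_bird: int | tuple[int, int] = 5
    sex_ratio: float = 14 / 36  # fraction male
    age_ratio: float = 25 / 36  # fraction hatch-year
    duration_mean_male: float = 72.0  # ms
    duration_mean_female: float = 66.0  # ms
    duration_sd_within: float = 3.0  # ms (alias of within_bird_sd['duration_ms'])
    duration_bounds: tuple[float, float] = (38.0, 95.0)  # ms
    freq_low_bound: float = 3500.0  # Hz
    freq_high_bound: float = 10300.0  # Hz
    sex_freq_offset_female: float = 400.0  # Hz; females call higher / narrower
    between_bird_sd: dict = field(default_factory=_default_between_sd)
    within_bird_sd: dict = field(default_factory=_default_within_sd)
    sex_variant_table: dict = field(
        default_factory=lambda: {
            s: dict(p) for s, p in DEFAULT_SEX_VARIANT_TABLE.items()
        }
    )
    snr_db: float = 20.0
    pad_ms: float = 5.0
    sample_rate: int = 44100
    seed: int = 0

    def __post_init__(self):
        if self.n_birds < 0:
            raise ValueError(f"n_birds must be non-negative, got {self.n_birds}")
        for name in ("sex_ratio", "age_ratio"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {r}")
        if not 0 < self.freq_low_bound < self.freq_high_bound < self.sample_rate / 2:
            raise ValueError(
                "frequency bounds must satisfy "
                "0 < freq_low_bound < freq_high_bound < Nyquist"
            )
        if isinstance(self.calls_per_bird, tuple):
            lo, hi = self.calls_per_bird
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid calls_per_bird range {self.calls_per_bird}")
        elif self.calls_per_bird < 0:
            raise ValueError("calls_per_bird must be non-negative")

    def replace(self, **kwargs) -> "PopulationConfig":
        return replace(self, **kwargs)


@dataclass
class CallClip:
    """One synthesized (or extracted) call with its metadata."""

    waveform: Waveform
    bird_id: str
    sex: str
    age: str
    variant: str
    realized: dict = field(default_factory=dict)  # realized latent parameters
    file: str | None = None  # source / destination WAV name


def _quota_labels(n: int, fraction: float, level_a: str, level_b: str, rng) -> list[str]:
    """Assign two levels at the exact rounded quota, in random order."""
    n_a = int(round(n * fraction))
    labels = np.array([level_a] * n_a + [level_b] * (n - n_a), dtype=object)
    rng.shuffle(labels)
    return list(labels)


def sample_population(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> list[BirdProfile]:
    """Draw the bird-level latent structure for one synthetic population.

    Sex and age are assigned at the exact rounded quota implied by the
    configured ratios (so the default 36-bird population is 14 M / 22 F and
    25 HY / 11 AHY), in seeded random order.  Identity offsets are drawn
    from centered normals with the configured between-bird SDs; variant
    propensities come from the per-sex table.
    """
    if config.n_birds < 1:
        raise ValueError("sample_population requires n_birds >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sexes = _quota_labels(config.n_birds, config.sex_ratio, "M", "F", rng)
    ages = _quota_labels(config.n_birds, config.age_ratio, "HY", "AHY", rng)
    profiles = []
    for i in range(config.n_birds):
        offsets = {
            p: float(rng.normal(0.0, config.between_bird_sd.get(p, 0.0)))
            for p in OFFSET_PARAMS
        }
        profiles.append(
            BirdProfile(
                bird_id=f"bird{i:03d}",
                sex=sexes[i],
                age=ages[i],
                param_offsets=offsets,
                variant_propensity=dict(config.sex_variant_table[sexes[i]]),
            )
        )
    return profiles


def _smooth_contour(freq: np.ndarray, half_width: int) -> np.ndarray:
    """Raised-cosine smoothing of the piecewise-linear contour."""
    if half_width < 1:
        return freq
    k = np.hanning(2 * half_width + 1)
    k /= k.sum()
    padded = np.concatenate(
        [np.full(half_width, freq[0]), freq, np.full(half_width, freq[-1])]
    )
    return np.convolve(padded, k, mode="valid")


def analytic_contour(
    template: VariantTemplate,
    n_samples: int,
    freq_offset: float = 0.0,
    tail_mod_depth: float | None = None,
    tail_mod_rate: float | None = None,
    sample_rate: int = 44100,
    freq_bounds: tuple[float, float] | None = None,
) -> np.ndarray:
    """Instantaneous-frequency contour (Hz per sample) for a template.

    Exposed so tests and feature validation can compare extracted contours
    against the exact synthesis target.
    """
    t_rel = np.arange(n_samples) / max(n_samples - 1, 1)
    f = np.interp(t_rel, template.breakpoint_times, template.breakpoint_freqs)
    half_width = int(round(template.inflection_sharpness * n_samples))
    f = _smooth_contour(f, half_width)
    f = f + freq_offset
    depth = template.tail_mod_depth if tail_mod_depth is None else tail_mod_depth
    rate = template.tail_mod_rate if tail_mod_rate is None else tail_mod_rate
    if template.tail_fraction > 0 and depth != 0.0:
        n_tail = int(round(template.tail_fraction * n_samples))
        if n_tail > 1:
            tt = np.arange(n_tail) / sample_rate
            ramp = np.minimum(1.0, np.arange(n_tail) / max(n_tail * 0.25, 1.0))
            f[-n_tail:] = f[-n_tail:] + depth * ramp * np.sin(2 * np.pi * rate * tt)
    if freq_bounds is not None:
        f = np.clip(f, freq_bounds[0], freq_bounds[1])
    return f


def synthesize_call(
    profile: BirdProfile,
    template: VariantTemplate,
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
) -> CallClip:
    """Render one call: sin(cumulative contour phase) x Tukey envelope + noise.

    The realized duration is the sex mean plus the bird's identity offset
    plus within-bird noise, clipped to the configured bounds; 5 ms of
    near-silent padding is added on both ends; the peak amplitude is <= 1.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sex_mean = (
        config.duration_mean_male if profile.sex == "M" else config.duration_mean_female
    )
    dur_ms = float(
        np.clip(
            sex_mean
            + profile.param_offsets.get("duration_ms", 0.0)
            + rng.normal(0.0, config.within_bird_sd.get("duration_ms", 0.0)),
            *config.duration_bounds,
        )
    )
    n = int(round(dur_ms * 1e-3 * config.sample_rate))
    freq_offset = (
        profile.param_offsets.get("freq_hz", 0.0)
        + (config.sex_freq_offset_female if profile.sex == "F" else 0.0)
        + rng.normal(0.0, config.within_bird_sd.get("freq_hz", 0.0))
    )
    depth = max(
        0.0,
        template.tail_mod_depth
        + profile.param_offsets.get("tail_mod_depth_hz", 0.0)
        + rng.normal(0.0, config.within_bird_sd.get("tail_mod_depth_hz", 0.0)),
    )
    rate = max(
        50.0,
        template.tail_mod_rate
        + profile.param_offsets.get("tail_mod_rate_hz", 0.0)
        + rng.normal(0.0, config.within_bird_sd.get("tail_mod_rate_hz", 0.0)),
    )
    peak_contour_freq = (
        template.breakpoint_freqs.max() + max(freq_offset, 0.0) + depth
    )
    if peak_contour_freq >= config.sample_rate / 2:
        raise ValueError(
            f"contour for {profile.bird_id}/{template.variant_code} reaches "
            f"{peak_contour_freq:.0f} Hz, at or above Nyquist "
            f"({config.sample_rate / 2:.0f} Hz)"
        )
    contour = analytic_contour(
        template,
        n,
        freq_offset=freq_offset,
        tail_mod_depth=depth,
        tail_mod_rate=rate,
        sample_rate=config.sample_rate,
        freq_bounds=(config.freq_low_bound, config.freq_high_bound),
    )
    phase = 2 * np.pi * np.cumsum(contour) / config.sample_rate
    body = np.sin(phase) * windows.tukey(n, alpha=0.25)
    pad = int(np.floor(config.pad_ms * 1e-3 * config.sample_rate + 0.5))
    signal = np.concatenate([np.zeros(pad), body, np.zeros(pad)])
    if np.isfinite(config.snr_db):
        rms_signal = np.sqrt(np.mean(body**2))
        noise_sd = rms_signal / 10 ** (config.snr_db / 20.0)
        signal = signal + rng.normal(0.0, noise_sd, signal.size)
    peak = np.max(np.abs(signal))
    if peak > 0:
        signal = signal * (0.95 / max(peak, 0.95))
    return CallClip(
        waveform=Waveform(signal, config.sample_rate),
        bird_id=profile.bird_id,
        sex=profile.sex,
        age=profile.age,
        variant=template.variant_code,
        realized={
            "duration_ms": dur_ms,
            "freq_offset_hz": freq_offset,
            "tail_mod_depth_hz": depth,
            "tail_mod_rate_hz": rate,
        },
    )


def generate_clips(
    config: PopulationConfig,
    templates: dict[str, VariantTemplate] | None = None,
) -> tuple[list[CallClip], pd.DataFrame]:
    """Generate a full population of call clips in memory with its manifest.

    The variant of each call is drawn per call from the bird's propensity
    (variant identity is treated as behavioural, not anatomical).
    """
    templates = DEFAULT_TEMPLATES if templates is None else templates
    # independent child streams for bird-level and call-level randomness
    pop_seed, call_seed = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(call_seed)
    profiles = (
        sample_population(config, np.random.default_rng(pop_seed))
        if config.n_birds >= 1
        else []
    )
    clips: list[CallClip] = []
    rows = []
    codes = list(VARIANT_CODES)
    for profile in profiles:
        if isinstance(config.calls_per_bird, tuple):
            lo, hi = config.calls_per_bird
            n_calls = int(rng.integers(lo, hi + 1))
        else:
            n_calls = int(config.calls_per_bird)
        probs = np.array([profile.variant_propensity.get(v, 0.0) for v in codes])
        for j in range(n_calls):
            variant = codes[int(rng.choice(len(codes), p=probs))]
            clip = synthesize_call(profile, templates[variant], config, rng)
            clip.file = f"{profile.bird_id}_{j:03d}.wav"
            clips.append(clip)
            rows.append(
                {
                    "file": f"{profile.bird_id}_{j:03d}.wav",
                    "bird_id": profile.bird_id,
                    "sex": profile.sex,
                    "age": profile.age,
                    "variant": variant,
                    **{f"realized_{k}": v for k, v in clip.realized.items()},
                }
            )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "file",
            "bird_id",
            "sex",
            "age",
            "variant",
            "realized_duration_ms",
            "realized_freq_offset_hz",
            "realized_tail_mod_depth_hz",
            "realized_tail_mod_rate_hz",
        ],
    )
    return clips, manifest


def generate_dataset(
    config: PopulationConfig,
    out_dir,
    templates: dict[str, VariantTemplate] | None = None,
    bit_depth: str = "float32",
) -> pd.DataFrame:
    """Write one WAV per call plus a `manifest.csv` metadata table.

    Returns the manifest (one row per call).  Deterministic for a fixed
    config seed, down to the WAV bytes.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    clips, manifest = generate_clips(config, templates)
    for clip, fname in zip(clips, manifest["file"]):
        write_wav(out_dir / fname, clip.waveform, bit_depth=bit_depth)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
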