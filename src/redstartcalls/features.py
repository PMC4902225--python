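"""Spectrogram energy-distribution measurements for flight-call clips.

Every call is summarised by 95 named measurements computed from three
marginal energy distributions of its power spectrogram ``P(t, f)``:

* the time envelope          ``e(t) = sum_f P(t, f)``
* the aggregate power spectrum ``s(f) = sum_t P(t, f)``
* the aggregate magnitude spectrum ``m(f) = sum_t sqrt(P(t, f))``

The measurement families are cumulative-energy percentiles (and the
durations, bandwidths, centers and asymmetries derived from them), energy
concentrations, half-maximum modewidths, Shannon entropies, the
peak-frequency contour over the 90%-energy time span, normalized
autocorrelation ("correlation envelope") summaries in time and frequency,
and peak/amplitude statistics.  They are designed to characterise the
regions of the spectrogram that hold the most energy, so that silent
padding around a clip barely moves them and rescaling the waveform leaves
all but the explicitly absolute power measurements untouched.

The registry below is the normative definition of each measurement for
this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "FeatureDef",
    "DEFAULT_SPEC",
    "METADATA_COLUMNS",
    "feature_columns",
    "compute_features",
    "batch_features",
    "prune_correlated",
    "subsample_calls",
    "subset_consistency",
    "load_feature_table",
]

#: Metadata columns that never enter statistics as features.
METADATA_COLUMNS = ("file", "bird_id", "sex", "age", "variant")

PERCENTILES = (2.5, 5.0, 25.0, 50.0, 75.0, 95.0, 97.5)


@dataclass(frozen=True)
class FeatureDef:
    name: str
    family: str  # time-percentile | freq-percentile | concentration |
    #              modewidth | entropy | contour | correlation-envelope | amplitude
    units: str
    scale_dependent: bool = False  # scales with waveform amplitude


def _build_spec() -> tuple[FeatureDef, ...]:
    defs: list[FeatureDef] = []

    def add(name, family, units, scale_dependent=False):
        defs.append(FeatureDef(name, family, units, scale_dependent))

    for p in PERCENTILES:
        add(f"t_pct_{p:g}", "time-percentile", "ms")
    for p in PERCENTILES:
        add(f"f_pow_pct_{p:g}", "freq-percentile", "Hz")
    for p in PERCENTILES:
        add(f"f_mag_pct_{p:g}", "freq-percentile", "Hz")
    for q in (95, 90, 50):
        add(f"dur_{q}", "time-percentile", "ms")
    add("t_center", "time-percentile", "ms")
    for q in (95, 90, 50):
        add(f"bw_pow_{q}", "freq-percentile", "Hz")
    for q in (95, 90, 50):
        add(f"bw_mag_{q}", "freq-percentile", "Hz")
    add("f_pow_center", "freq-percentile", "Hz")
    add("f_mag_center", "freq-percentile", "Hz")
    add("conc_time", "concentration", "ms")
    add("conc_pow", "concentration", "Hz")
    add("conc_mag", "concentration", "Hz")
    add("modew_time", "modewidth", "ms")
    add("modew_pow", "modewidth", "Hz")
    add("modew_mag", "modewidth", "Hz")
    add("mode_time", "modewidth", "ms")
    add("mode_f_pow", "modewidth", "Hz")
    add("mode_f_mag", "modewidth", "Hz")
    add("ent_time", "entropy", "bits")
    add("ent_pow", "entropy", "bits")
    add("ent_mag", "entropy", "bits")
    add("ent_gram", "entropy", "bits")
    add("ent_frame_mean", "entropy", "bits")
    add("ent_frame_max", "entropy", "bits")
    add("ent_frame_min", "entropy", "bits")
    for stat in (
        "median",
        "mean",
        "spread",
        "min",
        "max",
        "start",
        "end",
        "range",
    ):
        add(f"contour_{stat}", "contour", "Hz")
    add("contour_slope", "contour", "Hz/ms")
    add("contour_abs_slope_mean", "contour", "Hz/ms")
    add("contour_upsweep_frac", "contour", "1")
    add("contour_inflections", "contour", "count")
    add("contour_sd", "contour", "Hz")
    for stat in ("median", "spread", "halfwidth", "mean", "area"):
        add(f"tcorr_{stat}", "correlation-envelope", "ms" if stat != "mean" else "1")
    for stat in ("median", "spread", "halfwidth", "mean", "area"):
        add(f"fcorr_{stat}", "correlation-envelope", "Hz" if stat != "mean" else "1")
    add("peak_time", "amplitude", "ms")
    add("peak_freq", "amplitude", "Hz")
    add("peak_power_rel", "amplitude", "1")
    add("total_energy", "amplitude", "power", scale_dependent=True)
    add("mean_power", "amplitude", "power", scale_dependent=True)
    add("peak_power", "amplitude", "power", scale_dependent=True)
    add("crest_factor", "amplitude", "1")
    for dist in ("time", "pow", "mag"):
        add(f"skew_{dist}", "amplitude", "1")
        add(f"kurt_{dist}", "amplitude", "1")
    add("flat_time", "concentration", "1")
    add("flat_pow", "concentration", "1")
    add("flat_mag", "concentration", "1")
    for q in (1, 2, 3, 4):
        add(f"frac_t_q{q}", "time-percentile", "1")
    add("t_asym", "time-percentile", "ms")
    add("f_pow_asym", "freq-percentile", "Hz")
    add("f_mag_asym", "freq-percentile", "Hz")
    return tuple(defs)


DEFAULT_SPEC: tuple[FeatureDef, ...] = _build_spec()
assert len(DEFAULT_SPEC) == 95, len(DEFAULT_SPEC)
assert len({d.name for d in DEFAULT_SPEC}) == 95

SCALE_DEPENDENT_FEATURES = tuple(d.name for d in DEFAULT_SPEC if d.scale_dependent)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a feature table that are measurements, not metadata."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# distribution helpers


def _percentile_locations(w: np.ndarray, centers: np.ndarray, qs) -> np.ndarray:
    """Cumulative-energy percentile locations with within-bin interpolation."""
    step = centers[1] - centers[0] if centers.size > 1 else 1.0
    edges = np.concatenate([[centers[0] - step / 2], centers + step / 2])
    cum = np.concatenate([[0.0], np.cumsum(w)])
    cum = cum / cum[-1]
    return np.interp(np.asarray(qs, dtype=float) / 100.0, cum, edges)


def _concentration(w: np.ndarray, bin_width: float, fraction: float = 0.5) -> float:
    """Summed width of the fewest energy-sorted bins holding `fraction` energy."""
    order = np.sort(w)[::-1]
    cum = np.cumsum(order)
    k = int(np.searchsorted(cum, fraction * cum[-1]) + 1)
    return k * bin_width


def _modewidth(w: np.ndarray, bin_width: float) -> float:
    """Width of the maximal contiguous run around the mode with w >= mode/2."""
    mode = int(np.argmax(w))
    half = w[mode] / 2.0
    lo = mode
    while lo > 0 and w[lo - 1] >= half:
        lo -= 1
    hi = mode
    while hi < w.size - 1 and w[hi + 1] >= half:
        hi += 1
    return (hi - lo + 1) * bin_width


def _entropy(w: np.ndarray) -> float:
    total = w.sum()
    if total <= 0:
        return 0.0
    p = w[w > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _weighted_moments(w: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Skewness and excess-free kurtosis of a discrete energy distribution."""
    p = w / w.sum()
    mu = float(np.sum(p * x))
    var = float(np.sum(p * (x - mu) ** 2))
    sd = np.sqrt(var)
    if sd == 0:
        return 0.0, 0.0
    skew = float(np.sum(p * ((x - mu) / sd) ** 3))
    kurt = float(np.sum(p * ((x - mu) / sd) ** 4))
    return skew, kurt


def _flatness(w: np.ndarray) -> float:
    pos = w[w > 0]
    if pos.size == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(pos))) / np.mean(pos))


def _corr_envelope(w: np.ndarray, lag_step: float) -> dict[str, float]:
    """Normalized autocorrelation summaries of a non-negative envelope.

    The envelope's autocorrelation r(k) (k >= 0) is normalized to r(0) = 1.
    The 'median' is the area-median lag of the non-negative part (the lag
    below which half of the area lies), 'spread' the corresponding
    inter-quartile lag range, 'halfwidth' the interpolated first crossing
    of r = 1/2, 'mean' the average of r over lags, and 'area' the integral
    of the non-negative part (in lag units).
    """
    r = np.correlate(w, w, mode="full")[w.size - 1 :]
    r = r / r[0]
    rr = np.clip(r, 0.0, None)
    lags = np.arange(r.size) * lag_step
    cum = np.cumsum(rr)
    q25, q50, q75 = np.interp(
        [0.25 * cum[-1], 0.5 * cum[-1], 0.75 * cum[-1]], cum, lags
    )
    below = np.nonzero(r < 0.5)[0]
    if below.size == 0:
        halfwidth = lags[-1]
    else:
        i = below[0]
        if i == 0:
            halfwidth = 0.0
        else:
            frac = (r[i - 1] - 0.5) / (r[i - 1] - r[i])
            halfwidth = lags[i - 1] + frac * lag_step
    return {
        "median": float(q50),
        "spread": float(q75 - q25),
        "halfwidth": float(halfwidth),
        "mean": float(np.mean(r)),
        "area": float(np.sum(rr) * lag_step),
    }


# ---------------------------------------------------------------------------
# per-call feature computation


def compute_features(spectrogram, spec=DEFAULT_SPEC) -> pd.Series:
    """Compute the measurement registry for one spectrogram.

    Returns a Series with one finite value per registry entry, in registry
    order.  Raises ValueError("empty clip") on a zero-energy spectrogram.
    """
    P = spectrogram.power
    if P.sum() <= 0:
        raise ValueError("empty clip")
    times_ms = spectrogram.times * 1e3
    freqs = spectrogram.freqs
    dt = (times_ms[1] - times_ms[0]) if times_ms.size > 1 else 1.0
    df = freqs[1] - freqs[0]

    e = P.sum(axis=1)
    s = P.sum(axis=0)
    m = np.sqrt(P).sum(axis=0)

    out: dict[str, float] = {}

    tp = _percentile_locations(e, times_ms, PERCENTILES)
    fp = _percentile_locations(s, freqs, PERCENTILES)
    mp = _percentile_locations(m, freqs, PERCENTILES)
    for p, v in zip(PERCENTILES, tp):
        out[f"t_pct_{p:g}"] = v
    for p, v in zip(PERCENTILES, fp):
        out[f"f_pow_pct_{p:g}"] = v
    for p, v in zip(PERCENTILES, mp):
        out[f"f_mag_pct_{p:g}"] = v
    t = dict(zip(PERCENTILES, tp))
    f = dict(zip(PERCENTILES, fp))
    g = dict(zip(PERCENTILES, mp))
    out["dur_95"] = t[97.5] - t[2.5]
    out["dur_90"] = t[95.0] - t[5.0]
    out["dur_50"] = t[75.0] - t[25.0]
    out["t_center"] = t[50.0]
    out["bw_pow_95"] = f[97.5] - f[2.5]
    out["bw_pow_90"] = f[95.0] - f[5.0]
    out["bw_pow_50"] = f[75.0] - f[25.0]
    out["bw_mag_95"] = g[97.5] - g[2.5]
    out["bw_mag_90"] = g[95.0] - g[5.0]
    out["bw_mag_50"] = g[75.0] - g[25.0]
    out["f_pow_center"] = f[50.0]
    out["f_mag_center"] = g[50.0]

    out["conc_time"] = _concentration(e, dt)
    out["conc_pow"] = _concentration(s, df)
    out["conc_mag"] = _concentration(m, df)
    out["modew_time"] = _modewidth(e, dt)
    out["modew_pow"] = _modewidth(s, df)
    out["modew_mag"] = _modewidth(m, df)
    out["mode_time"] = times_ms[int(np.argmax(e))]
    out["mode_f_pow"] = freqs[int(np.argmax(s))]
    out["mode_f_mag"] = freqs[int(np.argmax(m))]

    out["ent_time"] = _entropy(e)
    out["ent_pow"] = _entropy(s)
    out["ent_mag"] = _entropy(m)
    out["ent_gram"] = _entropy(P.ravel())
    frame_ent = np.array([_entropy(row) for row in P])
    live = frame_ent[e > 0]
    out["ent_frame_mean"] = float(live.mean()) if live.size else 0.0
    out["ent_frame_max"] = float(live.max()) if live.size else 0.0
    out["ent_frame_min"] = float(live.min()) if live.size else 0.0

    # peak-frequency contour within the 90%-energy time span
    span = (times_ms >= t[5.0]) & (times_ms <= t[95.0])
    if not span.any():
        span = np.ones_like(times_ms, dtype=bool)
    contour = freqs[np.argmax(P[span], axis=1)]
    ct = times_ms[span]
    out["contour_median"] = float(np.median(contour))
    out["contour_mean"] = float(np.mean(contour))
    q1, q3 = np.percentile(contour, [25, 75])
    out["contour_spread"] = float(q3 - q1)
    out["contour_min"] = float(contour.min())
    out["contour_max"] = float(contour.max())
    out["contour_start"] = float(contour[0])
    out["contour_end"] = float(contour[-1])
    out["contour_range"] = float(contour.max() - contour.min())
    span_ms = ct[-1] - ct[0] if ct.size > 1 else dt
    out["contour_slope"] = float((contour[-1] - contour[0]) / span_ms)
    d = np.diff(contour)
    out["contour_abs_slope_mean"] = float(np.mean(np.abs(d)) / dt) if d.size else 0.0
    out["contour_upsweep_frac"] = float(np.mean(d > 0)) if d.size else 0.0
    # inflections: sign changes of the 3-frame-smoothed first difference
    if contour.size >= 4:
        sm = np.convolve(contour, np.ones(3) / 3.0, mode="valid")
        ds = np.sign(np.diff(sm))
        ds = ds[ds != 0]
        out["contour_inflections"] = float(np.sum(ds[1:] != ds[:-1])) if ds.size else 0.0
    else:
        out["contour_inflections"] = 0.0
    out["contour_sd"] = float(np.std(contour))

    for key, vals in (("tcorr", _corr_envelope(e, dt)), ("fcorr", _corr_envelope(s, df))):
        for stat, v in vals.items():
            out[f"{key}_{stat}"] = v

    i, j = np.unravel_index(int(np.argmax(P)), P.shape)
    out["peak_time"] = times_ms[i]
    out["peak_freq"] = freqs[j]
    total = P.sum()
    out["peak_power_rel"] = float(P[i, j] / total)
    out["total_energy"] = float(total)
    out["mean_power"] = float(P.mean())
    out["peak_power"] = float(P[i, j])
    out["crest_factor"] = float(P[i, j] / P.mean())

    for key, (w, x) in {
        "time": (e, times_ms),
        "pow": (s, freqs),
        "mag": (m, freqs),
    }.items():
        sk, ku = _weighted_moments(w, x)
        out[f"skew_{key}"] = sk
        out[f"kurt_{key}"] = ku
    out["flat_time"] = _flatness(e)
    out["flat_pow"] = _flatness(s)
    out["flat_mag"] = _flatness(m)

    # energy fractions per quarter of the 90%-energy span
    e_span = e[span]
    quarters = np.array_split(np.arange(e_span.size), 4)
    span_total = e_span.sum()
    for qi, idx in enumerate(quarters, start=1):
        out[f"frac_t_q{qi}"] = float(e_span[idx].sum() / span_total) if span_total else 0.0

    out["t_asym"] = (t[95.0] - t[50.0]) - (t[50.0] - t[5.0])
    out["f_pow_asym"] = (f[95.0] - f[50.0]) - (f[50.0] - f[5.0])
    out["f_mag_asym"] = (g[95.0] - g[50.0]) - (g[50.0] - g[5.0])

    values = pd.Series({d.name: out[d.name] for d in spec}, dtype=float)
    if not np.all(np.isfinite(values.to_numpy())):
        bad = values.index[~np.isfinite(values.to_numpy())].tolist()
        raise ValueError(f"non-finite feature values: {bad}")
    return values


def batch_features(clips, spec=DEFAULT_SPEC, compute_spectrogram=None):
    """Feature table for a list of CallClips: one row per clip.

    Clips whose feature computation fails are reported (not fatal); the
    return value is ``(table, errors)`` where errors is a list of
    ``(clip_index, message)``.
    """
    from .audio import compute_spectrogram as _default_sg

    sg = _default_sg if compute_spectrogram is None else compute_spectrogram
    rows = []
    errors: list[tuple[int, str]] = []
    for k, clip in enumerate(clips):
        try:
            vec = compute_features(sg(clip.waveform), spec)
        except Exception as exc:
            errors.append((k, str(exc)))
            continue
        meta = {
            "file": getattr(clip, "file", None) or f"clip{k:04d}",
            "bird_id": clip.bird_id,
            "sex": clip.sex,
            "age": clip.age,
            "variant": clip.variant,
        }
        rows.append({**meta, **vec.to_dict()})
    cols = list(METADATA_COLUMNS) + [d.name for d in spec]
    table = pd.DataFrame(rows, columns=cols)
    return table, errors


# ---------------------------------------------------------------------------
# table operations


def prune_correlated(table: pd.DataFrame, threshold: float = 0.95):
    """Drop one member of every feature pair with Pearson |r| >= threshold.

    Constant (zero-variance) columns are removed first.  Remaining pairs
    are visited in descending |r|; when both members of a flagged pair are
    still alive, the member with the larger mean |r| against the other
    surviving features is removed (ties break toward the later registry
    column).  Returns ``(pruned_table, report)`` where the report lists one
    row per removal with the triggering pair and its |r|.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    feats = feature_columns(table)
    if len(feats) < 2 or len(table) < 3:
        raise ValueError("pruning requires >= 2 feature columns and >= 3 rows")
    X = table[feats].to_numpy(dtype=float)
    report_rows = []
    keep = list(feats)
    constant = [c for c, v in zip(feats, X.std(axis=0)) if v == 0.0]
    for c in constant:
        keep.remove(c)
        report_rows.append(
            {"removed": c, "partner": "", "abs_r": np.nan, "reason": "constant"}
        )
    corr = np.abs(np.corrcoef(table[keep].to_numpy(dtype=float), rowvar=False))
    np.fill_diagonal(corr, 0.0)
    alive = {c: i for i, c in enumerate(keep)}
    iu = np.triu_indices(len(keep), k=1)
    order = np.argsort(corr[iu])[::-1]
    for k in order:
        r = corr[iu][k]
        if r < threshold:
            break
        a, b = keep[iu[0][k]], keep[iu[1][k]]
        if a not in alive or b not in alive:
            continue
        live_idx = [alive[c] for c in alive]
        mean_a = corr[alive[a], live_idx].mean()
        mean_b = corr[alive[b], live_idx].mean()
        # ties break toward the later registry column (b)
        victim = a if mean_a > mean_b else b
        partner = b if victim == a else a
        del alive[victim]
        report_rows.append(
            {"removed": victim, "partner": partner, "abs_r": float(r), "reason": "correlated"}
        )
    surviving = [c for c in keep if c in alive]
    meta = [c for c in table.columns if c in METADATA_COLUMNS]
    report = pd.DataFrame(report_rows, columns=["removed", "partner", "abs_r", "reason"])
    return table[meta + surviving].copy(), report


def subsample_calls(
    table: pd.DataFrame, n_per_bird: int = 5, min_calls: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Keep birds with >= min_calls calls and draw n_per_bird calls each.

    Selection is uniform without replacement and reproducible for a fixed
    seed.  Mirrors the reference study's per-bird subsampling (birds with
    five or more calls, five calls drawn per bird).
    """
    if n_per_bird > min_calls:
        raise ValueError(
            f"n_per_bird ({n_per_bird}) cannot exceed min_calls ({min_calls})"
        )
    if "bird_id" not in table.columns:
        raise ValueError("table has no bird_id metadata column")
    rng = np.random.default_rng(seed)
    parts = []
    for bird, grp in table.groupby("bird_id", sort=True):
        if len(grp) < min_calls:
            continue
        pick = rng.choice(len(grp), size=n_per_bird, replace=False)
        parts.append(grp.iloc[np.sort(pick)])
    if not parts:
        return table.iloc[0:0].copy()
    return pd.concat(parts).reset_index(drop=True)


def subset_consistency(full: pd.DataFrame, subset: pd.DataFrame, alpha: float = 0.05):
    """Check that subset feature means match the full dataset's.

    Per feature, a Welch two-sample t compares the subset against the rest
    of the full dataset (the complement, when subset rows are a subset of
    ``full``'s index — comparing against the full table itself would double
    count the shared rows and be badly conservative); an omnibus Fisher
    statistic (-2 sum log p ~ chi-square with 2k df) aggregates across
    features.  Individual features are flagged at the Bonferroni level.

    Returns a dict with the per-feature frame, omnibus statistic and
    p-value, and a boolean ``pass`` at level ``alpha``.
    """
    feats = feature_columns(full)
    if feats != feature_columns(subset):
        missing = set(feats) ^ set(feature_columns(subset))
        raise ValueError(f"feature columns differ between tables: {sorted(missing)}")
    if subset.index.isin(full.index).all() and len(subset) < len(full):
        reference = full.drop(index=subset.index)
    else:
        reference = full
    rows = []
    pvals = []
    for c in feats:
        a = subset[c].to_numpy(dtype=float)
        b = reference[c].to_numpy(dtype=float)
        diff = float(a.mean() - b.mean())
        if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = _stats.ttest_ind(a, b, equal_var=False)
            t_stat, p = float(t_stat), float(p)
            if not np.isfinite(p):
                p = 1.0
        rows.append({"feature": c, "mean_diff": diff, "t": t_stat, "p": p})
        pvals.append(p)
    per_feature = pd.DataFrame(rows)
    per_feature["flagged"] = per_feature["p"] < alpha / len(feats)
    pvals = np.clip(np.array(pvals), 1e-300, 1.0)
    omnibus = float(-2.0 * np.sum(np.log(pvals)))
    omnibus_p = float(_stats.chi2.sf(omnibus, df=2 * len(feats)))
    return {
        "per_feature": per_feature,
        "omnibus_statistic": omnibus,
        "omnibus_p": omnibus_p,
        "pass": omnibus_p > alpha,
    }


def load_feature_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Load a deposited per-call feature CSV into the package's layout.

    ``column_map`` renames external metadata headers onto the package's
    metadata columns (e.g. ``{"Band ID": "bird_id", "Sex": "sex"}``); all
    unmapped non-metadata columns are treated as features.  Tolerates any
    number of feature columns (a deposited table may carry the full or the
    pruned feature set).
    """
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in ("bird_id", "sex") if c not in table.columns]
    if missing:
        raise ValueError(
            f"feature CSV lacks metadata columns {missing}; provide a column_map"
        )
    for col in ("age", "variant"):
        if col not in table.columns:
            table[col] = "unknown"
    if "file" not in table.columns:
        table["file"] = [f"row{k:04d}" for k in range(len(table))]
    feats = feature_columns(table)
    table[feats] = table[feats].apply(pd.to_numeric)
    meta = [c for c in METADATA_COLUMNS if c in table.columns]
    return table[meta + feats]
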