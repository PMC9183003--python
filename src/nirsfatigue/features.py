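"""The 26 per-series window features and the 156-column design matrix.

Each 10-s chromophore window is summarised by 26 descriptors spanning four
groups: statistical (max, min, polarity, mean, variance, standard deviation,
kurtosis, skewness), temporal (mean of successive differences, total and
absolute energy, trapezoidal area under the curve, peak-to-peak distance,
Shannon entropy, least-squares slope, zero-crossing count), spectral
(fundamental, maximum and median frequency, 95%-power bandwidth, spectral
distance, spectral entropy) and fNIRS-tailored custom features (RMS, naive
slope, maximum/minimum variation of 1-s block means).  With 2 channels x 3
chromophores per window this yields 26 x 6 = 156 features per sample.

Conventions pinned for reproducibility:

* Spectrum: magnitude of the real FFT of the unmodified window (no detrend,
  no taper); at 1000 samples / 100 Hz the resolution is 0.1 Hz.
* Fundamental frequency: first local maximum above DC whose magnitude
  exceeds ``prominence_fraction`` (default 0.2) of the largest non-DC
  magnitude; 0 if none.
* Maximum / median frequency: smallest frequency where the cumulative power
  (squared magnitude, DC included) reaches 95% / 50% of the total.  Power
  bandwidth: span between the 2.5% and 97.5% cumulative-power frequencies.
* Spectral distance: sum of (cumulative magnitude spectrum minus its
  least-squares line over bin index).
* Temporal Shannon entropy: ``entropy_bins`` (default 10) equal-width bins
  over the window range, probabilities from counts, bits; 0 for a constant
  window.  Spectral entropy: entropy (bits) of the DC-excluded normalised
  power spectrum.
* Kurtosis is Fisher excess and skewness moment-based, both population
  (biased) estimators.
* Zero crossings: strict sign changes between consecutive samples, no mean
  centering.
* Polarity (max/min) returns 0 with a warning when the minimum is 0.
* Variation features: the window is split into 1-s blocks whose means
  b_1..b_10 are differenced; maximum variation = max(b_{i+1} - b_i),
  minimum variation = min(b_{i+1} - b_i).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recording import FeatureMatrix, LabeledWindow, RecordingValidationError, warn_degenerate

#: fixed feature order (grouped: statistical, temporal, spectral, custom)
FEATURE_NAMES: tuple[str, ...] = (
    "maximum",
    "minimum",
    "polarity",
    "mean",
    "variance",
    "std",
    "kurtosis",
    "skewness",
    "mean_diff",
    "total_energy",
    "auc",
    "abs_energy",
    "peak_to_peak",
    "entropy",
    "lin_reg_slope",
    "zero_cross",
    "fundamental_freq",
    "max_freq",
    "power_bandwidth",
    "spectral_distance",
    "median_freq",
    "spectral_entropy",
    "rms",
    "naive_slope",
    "max_variation",
    "min_variation",
)

FEATURE_DOMAINS: dict[str, str] = {
    **{f: "statistical" for f in FEATURE_NAMES[:8]},
    **{f: "temporal" for f in FEATURE_NAMES[8:16]},
    **{f: "spectral" for f in FEATURE_NAMES[16:22]},
    **{f: "custom" for f in FEATURE_NAMES[22:]},
}


@dataclass(frozen=True)
class FeatureDefinitionSet:
    """Tunable discretisation settings for the fixed 26-feature set."""

    entropy_bins: int = 10
    prominence_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if not 0 < self.prominence_fraction < 1:
            raise ValueError("prominence_fraction must be in (0, 1)")

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES


DEFAULT_FEATURES = FeatureDefinitionSet()


def _shannon_entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p))) if p.size else 0.0


def _histogram_entropy(x: np.ndarray, bins: int) -> float:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    return _shannon_entropy_bits(counts / x.size)


def _spectral_features(x: np.ndarray, rate: float, defs: FeatureDefinitionSet) -> dict[str, float]:
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    power = mag**2
    total = power.sum()
    out: dict[str, float] = {}

    # fundamental: first sufficiently high local max above DC
    out["fundamental_freq"] = 0.0
    if mag.size > 2:
        nondc = mag[1:]
        peak_floor = defs.prominence_fraction * float(nondc.max(initial=0.0))
        if peak_floor > 0:
            for i in range(1, mag.size - 1):
                if mag[i] > mag[i - 1] and mag[i] > mag[i + 1] and mag[i] > peak_floor:
                    out["fundamental_freq"] = float(freqs[i])
                    break

    if total <= 0:
        out.update(
            max_freq=0.0, median_freq=0.0, power_bandwidth=0.0,
            spectral_distance=0.0, spectral_entropy=0.0,
        )
        return out

    cum = np.cumsum(power) / total
    out["max_freq"] = float(freqs[np.searchsorted(cum, 0.95)])
    out["median_freq"] = float(freqs[np.searchsorted(cum, 0.50)])
    f_lo = freqs[np.searchsorted(cum, 0.025)]
    f_hi = freqs[np.searchsorted(cum, 0.975)]
    out["power_bandwidth"] = float(f_hi - f_lo)

    cmag = np.cumsum(mag)
    idx = np.arange(cmag.size, dtype=float)
    slope, intercept = np.polyfit(idx, cmag, 1)
    out["spectral_distance"] = float(np.sum(cmag - (slope * idx + intercept)))

    p_nondc = power[1:]
    s = p_nondc.sum()
    out["spectral_entropy"] = _shannon_entropy_bits(p_nondc / s) if s > 0 else 0.0
    return out


def extract_feature_vector(
    x: np.ndarray,
    rate: float,
    defs: FeatureDefinitionSet = DEFAULT_FEATURES,
) -> dict[str, float]:
    """Compute the 26 named features of a single window series.

    ``x`` must contain at least two full 1-s blocks (the custom variation
    features are block-mean differences).  Returns an ordered mapping
    feature name -> value, all finite.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    blocks_n = int(n // round(rate))
    if blocks_n < 2:
        raise RecordingValidationError(
            f"window of {n} samples at {rate} Hz cannot form two 1-s blocks"
        )
    if not np.all(np.isfinite(x)):
        raise RecordingValidationError("window contains non-finite samples")

    duration = n / rate
    t = np.arange(n) / rate
    out: dict[str, float] = {}

    xmax, xmin = float(np.max(x)), float(np.min(x))
    out["maximum"] = xmax
    out["minimum"] = xmin
    if xmin == 0.0:
        warn_degenerate("polarity undefined for zero minimum; returning 0")
        out["polarity"] = 0.0
    else:
        out["polarity"] = xmax / xmin
    out["mean"] = float(np.mean(x))
    out["variance"] = float(np.var(x))
    out["std"] = float(np.std(x))
    if out["std"] == 0.0:
        out["kurtosis"] = 0.0
        out["skewness"] = 0.0
    else:
        out["kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
        out["skewness"] = float(stats.skew(x, bias=True))

    out["mean_diff"] = float(np.mean(np.diff(x)))
    abs_energy = float(np.sum(x**2))
    out["total_energy"] = abs_energy / duration
    out["auc"] = float(np.trapezoid(x, dx=1.0 / rate))
    out["abs_energy"] = abs_energy
    out["peak_to_peak"] = xmax - xmin
    out["entropy"] = _histogram_entropy(x, defs.entropy_bins)
    # least-squares slope of value against time in seconds (mM/DPF per s)
    out["lin_reg_slope"] = float(np.polyfit(t, x, 1)[0])
    sign = np.sign(x)
    out["zero_cross"] = float(np.count_nonzero(sign[:-1] * sign[1:] < 0))

    out.update(_spectral_features(x, rate, defs))

    out["rms"] = float(np.sqrt(np.mean(x**2)))
    out["naive_slope"] = float(x[-1] - x[0])
    block = int(round(rate))
    means = x[: blocks_n * block].reshape(blocks_n, block).mean(axis=1)
    diffs = np.diff(means)
    out["max_variation"] = float(diffs.max())
    out["min_variation"] = float(diffs.min())

    return {name: out[name] for name in FEATURE_NAMES}


def feature_matrix_names(
    series_names: tuple[tuple[str, str], ...],
    defs: FeatureDefinitionSet = DEFAULT_FEATURES,
) -> tuple[str, ...]:
    """Column names <site>_<chromophore>_<feature> in deterministic order."""
    return tuple(
        f"{site}_{chrom}_{feat}" for site, chrom in series_names for feat in defs.names
    )


def build_feature_matrix(
    windows: list[LabeledWindow],
    defs: FeatureDefinitionSet = DEFAULT_FEATURES,
) -> FeatureMatrix:
    """Assemble the windows-by-156 design matrix with its label vector."""
    if not windows:
        raise RecordingValidationError("no windows to featurize")
    names = windows[0].series_names
    rate = windows[0].sampling_rate_hz
    n_samp = windows[0].n_samples
    for w in windows:
        if w.series_names != names or w.n_samples != n_samp or w.sampling_rate_hz != rate:
            raise RecordingValidationError("windows are not mutually consistent")

    columns = feature_matrix_names(names, defs)
    rows = np.empty((len(windows), len(columns)))
    for i, w in enumerate(windows):
        vals: list[float] = []
        for j in range(w.data.shape[0]):
            vals.extend(extract_feature_vector(w.data[j], rate, defs).values())
        rows[i] = vals
    labels = np.array([w.label for w in windows], dtype=int)
    return FeatureMatrix(rows, columns, labels, subject_id=windows[0].subject_id)


__all__ = [
    "FEATURE_NAMES",
    "FEATURE_DOMAINS",
    "FeatureDefinitionSet",
    "DEFAULT_FEATURES",
    "extract_feature_vector",
    "build_feature_matrix",
    "feature_matrix_names",
]
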