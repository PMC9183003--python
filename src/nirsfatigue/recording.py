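"""In-memory containers for raw fNIRS recordings and derived series.

A recording holds two optode channels (prefrontal sites F7 and F8), each
measured at two wavelengths, plus a table of annotated periods: a resting
baseline before the task block (``baseline_pre``, labelled *absence of
cognitive fatigue*), the task block itself, and a resting baseline after it
(``baseline_post``, labelled *cognitive fatigue*).  Period intervals are in
seconds from recording start and are half-open, ``[start_s, end_s)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PERIOD_ROLES = ("baseline_pre", "task", "baseline_post")

#: chromophore column order used everywhere downstream
CHROMOPHORES = ("HbO2", "Hb", "Hbt")

#: fatigue class encoding: pre-task baseline -> 0, post-task baseline -> 1
LABEL_ABSENCE = 0
LABEL_FATIGUE = 1

HBT_ATOL = 1e-12


class FormatError(ValueError):
    """A file or header does not conform to the recording dialect."""


class RecordingValidationError(ValueError):
    """A recording or derived object violates a structural invariant."""


@dataclass(frozen=True)
class Period:
    start_s: float
    end_s: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in PERIOD_ROLES:
            raise RecordingValidationError(
                f"unknown period role {self.role!r}; expected one of {PERIOD_ROLES}"
            )
        if not self.end_s > self.start_s:
            raise RecordingValidationError(
                f"period {self.role}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _check_periods(periods: tuple[Period, ...], duration_s: float) -> None:
    ordered = sorted(periods, key=lambda p: p.start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if nxt.start_s < prev.end_s - 1e-12:
            raise RecordingValidationError(
                f"periods {prev.role} and {nxt.role} overlap"
            )
    for p in periods:
        if p.start_s < -1e-12 or p.end_s > duration_s + 1e-9:
            raise RecordingValidationError(
                f"period {p.role} [{p.start_s}, {p.end_s}) lies outside the "
                f"{duration_s:.2f}-s recording"
            )


@dataclass
class ChannelIntensities:
    """Raw detected light intensity at both wavelengths for one optode site."""

    site: str
    intensity_l1: np.ndarray  # at lambda1 (660 nm), arbitrary positive units
    intensity_l2: np.ndarray  # at lambda2 (860 nm)

    def __post_init__(self) -> None:
        self.intensity_l1 = np.asarray(self.intensity_l1, dtype=float)
        self.intensity_l2 = np.asarray(self.intensity_l2, dtype=float)
        if self.intensity_l1.shape != self.intensity_l2.shape:
            raise RecordingValidationError(
                f"channel {self.site}: wavelength series lengths differ "
                f"({self.intensity_l1.size} vs {self.intensity_l2.size})"
            )
        for name, arr in (("l1", self.intensity_l1), ("l2", self.intensity_l2)):
            bad = np.flatnonzero(~(arr > 0))
            if bad.size:
                raise RecordingValidationError(
                    f"channel {self.site} wavelength {name}: non-positive "
                    f"intensity at sample index {bad[0]}"
                )


@dataclass
class IntensityRecording:
    """Dual-wavelength, two-channel raw intensity recording."""

    sampling_rate_hz: float
    channels: tuple[ChannelIntensities, ...]
    periods: tuple[Period, ...] = ()
    subject_id: str = "S"

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.periods = tuple(
            p if isinstance(p, Period) else Period(*p) for p in self.periods
        )
        if self.sampling_rate_hz <= 0:
            raise RecordingValidationError("sampling_rate_hz must be > 0")
        if not self.channels:
            raise RecordingValidationError("recording has no channels")
        n = self.channels[0].intensity_l1.size
        for ch in self.channels:
            if ch.intensity_l1.size != n:
                raise RecordingValidationError("channels have unequal lengths")
        _check_periods(self.periods, self.duration_s)

    @property
    def n_samples(self) -> int:
        return int(self.channels[0].intensity_l1.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(ch.site for ch in self.channels)

    def period(self, role: str) -> Period:
        matches = [p for p in self.periods if p.role == role]
        if len(matches) != 1:
            raise RecordingValidationError(
                f"expected exactly one {role!r} period, found {len(matches)}"
            )
        return matches[0]

    def has_period(self, role: str) -> bool:
        return any(p.role == role for p in self.periods)

    def period_slice(self, period: Period) -> slice:
        i0 = int(round(period.start_s * self.sampling_rate_hz))
        i1 = int(round(period.end_s * self.sampling_rate_hz))
        return slice(i0, min(i1, self.n_samples))


@dataclass
class ChromophoreSeries:
    """Per-channel haemoglobin concentration changes, in mM/DPF.

    ``data[site]`` maps chromophore name ("HbO2", "Hb", "Hbt") to a series of
    concentration changes relative to the reference (baseline) intensity.
    Total haemoglobin is the sample-wise sum of the other two.
    """

    sampling_rate_hz: float
    data: dict[str, dict[str, np.ndarray]]
    periods: tuple[Period, ...] = ()
    subject_id: str = "S"

    def __post_init__(self) -> None:
        self.periods = tuple(
            p if isinstance(p, Period) else Period(*p) for p in self.periods
        )
        n = None
        for site, chrom in self.data.items():
            missing = set(CHROMOPHORES) - set(chrom)
            if missing:
                raise RecordingValidationError(
                    f"channel {site} missing chromophores {sorted(missing)}"
                )
            for name in CHROMOPHORES:
                chrom[name] = np.asarray(chrom[name], dtype=float)
                if n is None:
                    n = chrom[name].size
                elif chrom[name].size != n:
                    raise RecordingValidationError("series lengths differ")
            if not np.allclose(
                chrom["Hbt"], chrom["HbO2"] + chrom["Hb"], rtol=0.0, atol=HBT_ATOL
            ):
                raise RecordingValidationError(
                    f"channel {site}: Hbt is not the sum of HbO2 and Hb"
                )
        _check_periods(self.periods, self.duration_s)

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(self.data)

    @property
    def n_samples(self) -> int:
        first = next(iter(self.data.values()))
        return int(first["HbO2"].size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def period(self, role: str) -> Period:
        matches = [p for p in self.periods if p.role == role]
        if len(matches) != 1:
            raise RecordingValidationError(
                f"expected exactly one {role!r} period, found {len(matches)}"
            )
        return matches[0]

    def has_period(self, role: str) -> bool:
        return any(p.role == role for p in self.periods)

    def series_names(self) -> list[tuple[str, str]]:
        """(site, chromophore) pairs in channel-major, fixed chromophore order."""
        return [(site, c) for site in self.data for c in CHROMOPHORES]

    def to_dataframe(self) -> pd.DataFrame:
        t = np.arange(self.n_samples) / self.sampling_rate_hz
        cols = {"time_s": t}
        for site, c in self.series_names():
            cols[f"{site}_{c}"] = self.data[site][c]
        return pd.DataFrame(cols)


@dataclass
class LabeledWindow:
    """One fixed-length window of all six chromophore series plus its label."""

    data: np.ndarray  # shape (6, n_samples), row order = series_names
    series_names: tuple[tuple[str, str], ...]
    label: int
    sampling_rate_hz: float
    subject_id: str = "S"
    window_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.series_names):
            raise RecordingValidationError(
                f"window data shape {self.data.shape} does not match "
                f"{len(self.series_names)} series"
            )
        if self.label not in (LABEL_ABSENCE, LABEL_FATIGUE):
            raise RecordingValidationError(f"label must be 0 or 1, got {self.label}")

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[1])


@dataclass
class FeatureMatrix:
    """Windows-by-features design matrix with a binary label vector."""

    values: np.ndarray  # (n_windows, n_features)
    feature_names: tuple[str, ...]
    labels: np.ndarray  # (n_windows,), {0, 1}
    subject_id: str = "S"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.feature_names = tuple(self.feature_names)
        if self.values.ndim != 2:
            raise RecordingValidationError("feature values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise RecordingValidationError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if self.values.shape[0] != self.labels.size:
            raise RecordingValidationError("label vector length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise RecordingValidationError("feature matrix contains non-finite values")
        if not np.isin(self.labels, (0, 1)).all():
            raise RecordingValidationError("labels must be binary")

    @property
    def n_windows(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        # 17 significant digits: exact text round trip for float64
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, subject_id: str = "S") -> "FeatureMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        if "label" not in df.columns:
            raise FormatError(f"{path}: feature CSV lacks a 'label' column")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), tuple(df.columns), labels, subject_id=subject_id)


def warn_degenerate(message: str) -> None:
    """Emit a degenerate-data warning (non-fatal guard conditions)."""
    warnings.warn(message, RuntimeWarning, stacklevel=3)
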