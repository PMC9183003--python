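"""Band-pass filtering and baseline segmentation/labelling.

The concentration-change series are filtered with a second-order Butterworth
band-pass (0.01-1 Hz by default) applied forward-backward (zero phase), which
retains the haemodynamically informative band while removing slow drift and
cardiac/electrical components.  Each annotated baseline period is then cut
into consecutive non-overlapping 10-s windows anchored at the period start;
the trailing partial window is dropped and, additionally, the last complete
window of every baseline is discarded so that no window can touch task
activity.  Windows from the pre-task baseline are labelled 0 (absence of
cognitive fatigue) and those from the post-task baseline 1 (cognitive
fatigue); task-period samples never enter a window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import (
    CHROMOPHORES,
    ChromophoreSeries,
    LABEL_ABSENCE,
    LABEL_FATIGUE,
    LabeledWindow,
    RecordingValidationError,
    warn_degenerate,
)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification (cut-offs in Hz)."""

    low_cut_hz: float = 0.01
    high_cut_hz: float = 1.0
    order: int = 2
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low_cut_hz < self.high_cut_hz):
            raise ValueError("need 0 < low_cut_hz < high_cut_hz")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, sampling_rate_hz: float):
        nyq = sampling_rate_hz / 2.0
        if not self.high_cut_hz < nyq:
            raise ValueError(
                f"high_cut_hz ({self.high_cut_hz}) must lie below the Nyquist "
                f"frequency ({nyq})"
            )
        return signal.butter(
            self.order,
            [self.low_cut_hz, self.high_cut_hz],
            btype="bandpass",
            fs=sampling_rate_hz,
            output="sos",
        )

    def magnitude_response(self, freqs_hz, sampling_rate_hz: float) -> np.ndarray:
        """Analytic digital magnitude response at the given frequencies,
        accounting for the forward-backward (squared) application."""
        sos = self.sos(sampling_rate_hz)
        _, h = signal.sosfreqz(
            sos, worN=np.atleast_1d(np.asarray(freqs_hz, dtype=float)),
            fs=sampling_rate_hz,
        )
        mag = np.abs(h)
        return mag ** 2 if self.zero_phase else mag


@dataclass(frozen=True)
class WindowingSpec:
    """Non-overlapping windowing with the discard-last-window rule."""

    window_s: float = 10.0
    overlap: float = 0.0
    discard_last_per_period: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.overlap != 0.0:
            raise ValueError("only non-overlapping windows are supported")


def bandpass(series: ChromophoreSeries, spec: FilterSpec = FilterSpec()) -> ChromophoreSeries:
    """Filter all six chromophore series identically.

    Hbt is recomputed as the sum of the filtered HbO2 and Hb series; by
    linearity of the filter this equals filtering Hbt directly (up to
    floating-point round-off) and keeps the sum invariant exact.
    """
    n = series.n_samples
    if n <= 3 * max(spec.order, 1) * 2:
        raise RecordingValidationError("series too short to filter stably")
    sos = spec.sos(series.sampling_rate_hz)

    def _apply(x: np.ndarray) -> np.ndarray:
        if spec.zero_phase:
            return signal.sosfiltfilt(sos, x)
        return signal.sosfilt(sos, x)

    data: dict[str, dict[str, np.ndarray]] = {}
    for site, chrom in series.data.items():
        hbo2 = _apply(chrom["HbO2"])
        hb = _apply(chrom["Hb"])
        data[site] = {"HbO2": hbo2, "Hb": hb, "Hbt": hbo2 + hb}
    return ChromophoreSeries(
        sampling_rate_hz=series.sampling_rate_hz,
        data=data,
        periods=series.periods,
        subject_id=series.subject_id,
    )


_PERIOD_LABELS = {"baseline_pre": LABEL_ABSENCE, "baseline_post": LABEL_FATIGUE}


def segment_and_label(
    series: ChromophoreSeries, spec: WindowingSpec = WindowingSpec()
) -> list[LabeledWindow]:
    """Cut both baseline periods into labelled fixed-length windows.

    Per period the number of emitted windows is
    ``floor(period_duration / window_s) - 1`` (complete windows, minus the
    discarded final one).  A period too short to yield any window produces
    none and a warning.
    """
    for role in ("baseline_pre", "baseline_post"):
        if not series.has_period(role):
            raise RecordingValidationError(f"recording lacks a {role} period")
    rate = series.sampling_rate_hz
    wlen = int(round(spec.window_s * rate))
    names = tuple(series.series_names())
    stacked = np.vstack([series.data[site][c] for site, c in names])

    windows: list[LabeledWindow] = []
    index = 0
    for role in ("baseline_pre", "baseline_post"):
        period = series.period(role)
        start = int(round(period.start_s * rate))
        stop = int(round(period.end_s * rate))
        n_complete = (stop - start) // wlen
        n_keep = n_complete - 1 if spec.discard_last_per_period else n_complete
        if n_keep <= 0:
            warn_degenerate(
                f"period {role} ({period.duration_s:.1f} s) too short for any "
                f"{spec.window_s:.0f}-s window after the discard-last rule"
            )
            continue
        for w in range(n_keep):
            lo = start + w * wlen
            windows.append(
                LabeledWindow(
                    data=stacked[:, lo : lo + wlen],
                    series_names=names,
                    label=_PERIOD_LABELS[role],
                    sampling_rate_hz=rate,
                    subject_id=series.subject_id,
                    window_index=index,
                )
            )
            index += 1
    return windows


__all__ = ["FilterSpec", "WindowingSpec", "bandpass", "segment_and_label", "CHROMOPHORES"]
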