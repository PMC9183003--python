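"""Synthetic dual-wavelength fNIRS generator with known ground truth.

Emulates the acquisition protocol: a ~2-min resting baseline (absence of
cognitive fatigue), a long task block, and a second ~2-min resting baseline
(cognitive fatigue).  Each channel's concentration-change series is a sum of

* a class-dependent sustained shift (HbO2 down, Hb up in the post baseline,
  consistent with reduced prefrontal oxygenation under fatigue),
* vasomotor (Mayer, ~0.1 Hz), respiratory (~0.3 Hz) and cardiac (~1.2 Hz)
  sinusoids with per-channel random phases — the Hb oscillations at half
  the HbO2 amplitudes,
* an optional linear drift and white sensor noise.

Because the pipeline's own 0.01 Hz high-pass removes a between-baseline DC
offset, the fatigue signature additionally scales the vasomotor/respiratory
oscillation amplitudes in the post baseline by ``fatigue_osc_gain``
(low-frequency oscillatory power changes under sustained mental load); this
is the component that remains observable after filtering.  Setting
``effect = 0`` in :func:`scaled` zeroes the shifts and the gain excess,
giving an exact null.

The generator then maps concentrations to detected intensities with the
exact mBLL forward model, so pushing a synthetic recording through the full
pipeline recovers the simulated series to numerical precision (before
filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import DEFAULT_CONSTANTS, OpticalConstants
from .hemodynamics import forward_intensities
from .recording import (
    ChannelIntensities,
    IntensityRecording,
    Period,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SubjectSimSpec:
    """Parameters of one simulated subject.

    Durations in seconds, amplitudes/shifts in mM/DPF, frequencies in Hz.
    The default oscillation frequencies (0.1, 0.3, 1.2 Hz) complete integer
    numbers of cycles over a 120-s baseline, so baseline block means reduce
    to shift + noise exactly.
    """

    seed: int = 0
    baseline_s: float = 120.0
    task_s: float = 600.0
    rate_hz: float = 100.0
    fatigue_hbo2_shift: float = -0.02
    fatigue_hb_shift: float = 0.01
    fatigue_osc_gain: float = 1.5
    mayer_amp: float = 0.008
    mayer_freq_hz: float = 0.1
    resp_amp: float = 0.004
    resp_freq_hz: float = 0.3
    cardiac_amp: float = 0.002
    cardiac_freq_hz: float = 1.2
    drift_slope: float = 0.0  # mM/DPF per second
    noise_sd: float = 0.002
    i_b_l1: float = 1.0
    i_b_l2: float = 1.0
    sites: tuple[str, str] = ("F7", "F8")

    def __post_init__(self) -> None:
        if self.baseline_s <= 0 or self.task_s < 0 or self.rate_hz <= 0:
            raise SimulationError("durations and rate must be positive")
        for amp in (self.mayer_amp, self.resp_amp, self.cardiac_amp, self.noise_sd):
            if amp < 0:
                raise SimulationError("amplitudes must be >= 0")
        nyq = self.rate_hz / 2
        for f in (self.mayer_freq_hz, self.resp_freq_hz, self.cardiac_freq_hz):
            if not 0 < f < nyq:
                raise SimulationError(f"oscillation frequency {f} outside (0, Nyquist)")
        if self.fatigue_osc_gain < 0:
            raise SimulationError("fatigue_osc_gain must be >= 0")
        if self.i_b_l1 <= 0 or self.i_b_l2 <= 0:
            raise SimulationError("reference intensities must be positive")

    @property
    def total_s(self) -> float:
        return 2 * self.baseline_s + self.task_s

    @property
    def n_samples(self) -> int:
        return int(round(self.total_s * self.rate_hz))

    def periods(self) -> tuple[Period, ...]:
        b, t = self.baseline_s, self.task_s
        return (
            Period(0.0, b, "baseline_pre"),
            Period(b, b + t, "task"),
            Period(b + t, 2 * b + t, "baseline_post"),
        )

    def scaled(self, effect: float) -> "SubjectSimSpec":
        """Return a spec whose fatigue signature is scaled by ``effect``:
        shifts multiplied by it, oscillation gain excess (gain - 1) too.
        ``effect = 0`` is the exact null; 1 the default strong effect."""
        return replace(
            self,
            fatigue_hbo2_shift=self.fatigue_hbo2_shift * effect,
            fatigue_hb_shift=self.fatigue_hb_shift * effect,
            fatigue_osc_gain=1.0 + (self.fatigue_osc_gain - 1.0) * effect,
        )


def simulate_concentrations(spec: SubjectSimSpec):
    """Simulate per-channel (dHbO2, dHb) series with their period table.

    Returns ``(data, periods)`` where ``data[site] = (delta_hbo2, delta_hb)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_samples
    t = np.arange(n) / spec.rate_hz
    periods = spec.periods()
    post = periods[2]
    post_mask = (t >= post.start_s).astype(float)
    osc_gain = 1.0 + (spec.fatigue_osc_gain - 1.0) * post_mask

    components = (
        (spec.mayer_amp, spec.mayer_freq_hz, True),
        (spec.resp_amp, spec.resp_freq_hz, True),
        (spec.cardiac_amp, spec.cardiac_freq_hz, False),
    )
    data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for site in spec.sites:
        series = []
        for shift, amp_scale in (
            (spec.fatigue_hbo2_shift, 1.0),
            (spec.fatigue_hb_shift, 0.5),
        ):
            x = shift * post_mask + spec.drift_slope * t
            for amp, freq, gained in components:
                phase = rng.uniform(0.0, 2.0 * np.pi)
                osc = amp_scale * amp * np.sin(2 * np.pi * freq * t + phase)
                x = x + (osc_gain * osc if gained else osc)
            x = x + rng.normal(0.0, spec.noise_sd, n)
            series.append(x)
        data[site] = (series[0], series[1])
    return data, periods


def generate_subject_recording(
    spec: SubjectSimSpec,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
    subject_id: str = "S",
) -> IntensityRecording:
    """Simulate concentrations and map them through the mBLL forward model."""
    data, periods = simulate_concentrations(spec)
    channels = []
    for site, (d_hbo2, d_hb) in data.items():
        i_l1, i_l2 = forward_intensities(d_hbo2, d_hb, spec.i_b_l1, spec.i_b_l2, constants)
        for arr in (i_l1, i_l2):
            if not (np.all(np.isfinite(arr)) and np.all(arr > 0)):
                raise SimulationError(
                    "simulated concentrations drove detector intensity to "
                    "zero or overflow; reduce amplitudes or shifts"
                )
        channels.append(ChannelIntensities(site, i_l1, i_l2))
    return IntensityRecording(
        sampling_rate_hz=spec.rate_hz,
        channels=tuple(channels),
        periods=periods,
        subject_id=subject_id,
    )


SUBJECT_IDS = tuple("ABCDEFGHIJ")


def generate_cohort(
    n_subjects: int = 10,
    base_seed: int = 0,
    effect_range=(1.0,),
    base_spec: SubjectSimSpec = SubjectSimSpec(),
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> list[tuple[IntensityRecording, SubjectSimSpec]]:
    """Generate independent subjects with per-subject effect sizes.

    ``effect_range``: a single value applies to every subject; a pair
    ``(lo, hi)`` draws each subject's effect uniformly from it, emulating
    inter-subject variability in fatigue response; a sequence of length
    ``n_subjects`` fixes each subject's effect explicitly.
    """
    if n_subjects < 1:
        raise SimulationError("n_subjects must be >= 1")
    effects = tuple(float(e) for e in np.atleast_1d(np.asarray(effect_range, dtype=float)))
    rng = np.random.default_rng(np.random.SeedSequence((base_seed, 0xC0F)))
    if len(effects) == 1:
        per_subject = [effects[0]] * n_subjects
    elif len(effects) == n_subjects:
        per_subject = list(effects)
    elif len(effects) == 2:
        per_subject = list(rng.uniform(effects[0], effects[1], n_subjects))
    else:
        raise SimulationError(
            "effect_range must have length 1, 2, or n_subjects"
        )

    out = []
    for i, effect in enumerate(per_subject):
        sid = SUBJECT_IDS[i] if i < len(SUBJECT_IDS) else f"S{i:02d}"
        sub_seed = int(np.random.SeedSequence((base_seed, i)).generate_state(1)[0] % 2**31)
        spec = replace(base_spec.scaled(effect), seed=sub_seed)
        out.append((generate_subject_recording(spec, constants, subject_id=sid), spec))
    return out


__all__ = [
    "SubjectSimSpec",
    "SimulationError",
    "simulate_concentrations",
    "generate_subject_recording",
    "generate_cohort",
    "SUBJECT_IDS",
]
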