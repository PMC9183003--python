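"""Modified Beer-Lambert law (mBLL) conversion for two-wavelength fNIRS.

The detected intensity I_t at each wavelength is compared against a
reference (baseline) intensity I_b; the optical-density change
``OD = log10(I_b / I_t)`` at the two wavelengths is inverted through the
2x2 extinction-coefficient system to yield concentration changes of
oxygenated (dHbO2) and deoxygenated (dHb) haemoglobin:

    dHbO2 = (OD_l1 * eps_Hb_l2   - OD_l2 * eps_Hb_l1)   / (d * DPF * det)
    dHb   = (OD_l2 * eps_HbO2_l1 - OD_l1 * eps_HbO2_l2) / (d * DPF * det)

with ``det = eps_HbO2_l1 * eps_Hb_l2 - eps_HbO2_l2 * eps_Hb_l1``.  The
decimal logarithm (optical-density convention) is used; the DPF is factored
out, so results carry units mM/DPF.  Total haemoglobin change is the sum
dHbt = dHbO2 + dHb.

``forward_intensities`` is the exact algebraic inverse and drives the
synthetic generator: given concentration-change series it produces the
intensities a detector would record, so that the full pipeline can be tested
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, OpticalConstants
from .recording import (
    CHROMOPHORES,
    ChromophoreSeries,
    IntensityRecording,
    RecordingValidationError,
)


@dataclass(frozen=True)
class ReferenceIntervalPolicy:
    """How the reference (baseline) intensity I_b is estimated.

    ``first_k_seconds``: mean intensity over the first ``k_s`` seconds of the
    pre-task baseline period (default, k_s = 10).  ``whole_pre_baseline``:
    mean over the entire pre-task baseline.  A fixed early reference keeps
    the two labelled baseline periods comparable.
    """

    mode: str = "first_k_seconds"
    k_s: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("first_k_seconds", "whole_pre_baseline"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.k_s <= 0:
            raise ValueError("k_s must be > 0")

    def interval(self, rec: IntensityRecording) -> slice:
        if rec.has_period("baseline_pre"):
            p = rec.period("baseline_pre")
            start = p.start_s
            end = p.end_s if self.mode == "whole_pre_baseline" else min(
                p.start_s + self.k_s, p.end_s
            )
        else:
            # no annotated baseline: fall back to the start of the recording
            start = 0.0
            end = rec.duration_s if self.mode == "whole_pre_baseline" else min(
                self.k_s, rec.duration_s
            )
        i0 = int(round(start * rec.sampling_rate_hz))
        i1 = int(round(end * rec.sampling_rate_hz))
        if i1 <= i0 or i0 < 0 or i1 > rec.n_samples:
            raise RecordingValidationError(
                f"reference interval [{start}, {end}) s is empty or outside "
                "the recording"
            )
        return slice(i0, i1)


def delta_concentrations(
    i_b_l1,
    i_t_l1,
    i_b_l2,
    i_t_l2,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
):
    """Invert the mBLL for one sample (or an array of samples).

    Parameters are the baseline and detected intensities at the two
    wavelengths; any positive units, only ratios matter.  Returns
    ``(delta_hbo2, delta_hb)`` in mM/DPF.
    """
    i_b_l1, i_t_l1, i_b_l2, i_t_l2 = (
        np.asarray(x, dtype=float) for x in (i_b_l1, i_t_l1, i_b_l2, i_t_l2)
    )
    for name, arr in (
        ("i_b_l1", i_b_l1),
        ("i_t_l1", i_t_l1),
        ("i_b_l2", i_b_l2),
        ("i_t_l2", i_t_l2),
    ):
        if np.any(~(arr > 0)):
            raise ValueError(f"{name} must be strictly positive")
    det = constants.determinant
    if det == 0:
        raise ValueError("degenerate optical constants: zero determinant")
    od_l1 = np.log10(i_b_l1 / i_t_l1)
    od_l2 = np.log10(i_b_l2 / i_t_l2)
    scale = constants.emitter_detector_distance_cm * constants.dpf * det
    delta_hbo2 = (od_l1 * constants.epsilon_hb_l2 - od_l2 * constants.epsilon_hb_l1) / scale
    delta_hb = (od_l2 * constants.epsilon_hbo2_l1 - od_l1 * constants.epsilon_hbo2_l2) / scale
    return delta_hbo2, delta_hb


def intensity_to_chromophores(
    rec: IntensityRecording,
    policy: ReferenceIntervalPolicy = ReferenceIntervalPolicy(),
    constants: OpticalConstants = DEFAULT_CONSTANTS,
) -> ChromophoreSeries:
    """Convert a raw intensity recording into concentration-change series.

    For each channel and wavelength the reference intensity I_b is the mean
    over the policy's reference interval; every sample is then inverted with
    :func:`delta_concentrations` and total haemoglobin appended.
    """
    ref = policy.interval(rec)
    data: dict[str, dict[str, np.ndarray]] = {}
    for ch in rec.channels:
        i_b_l1 = float(np.mean(ch.intensity_l1[ref]))
        i_b_l2 = float(np.mean(ch.intensity_l2[ref]))
        d_hbo2, d_hb = delta_concentrations(
            i_b_l1, ch.intensity_l1, i_b_l2, ch.intensity_l2, constants
        )
        data[ch.site] = {"HbO2": d_hbo2, "Hb": d_hb, "Hbt": d_hbo2 + d_hb}
    return ChromophoreSeries(
        sampling_rate_hz=rec.sampling_rate_hz,
        data=data,
        periods=rec.periods,
        subject_id=rec.subject_id,
    )


def forward_intensities(
    delta_hbo2,
    delta_hb,
    i_b_l1: float = 1.0,
    i_b_l2: float = 1.0,
    constants: OpticalConstants = DEFAULT_CONSTANTS,
):
    """Exact forward model: concentration changes -> detected intensities.

    ``I_t = I_b * 10**(-OD)`` with
    ``OD = (eps_HbO2 * dHbO2 + eps_Hb * dHb) * d * DPF`` per wavelength.
    Composing with :func:`delta_concentrations` is the identity.
    """
    if i_b_l1 <= 0 or i_b_l2 <= 0:
        raise ValueError("reference intensities must be strictly positive")
    delta_hbo2 = np.asarray(delta_hbo2, dtype=float)
    delta_hb = np.asarray(delta_hb, dtype=float)
    d_dpf = constants.emitter_detector_distance_cm * constants.dpf
    od_l1 = (constants.epsilon_hbo2_l1 * delta_hbo2 + constants.epsilon_hb_l1 * delta_hb) * d_dpf
    od_l2 = (constants.epsilon_hbo2_l2 * delta_hbo2 + constants.epsilon_hb_l2 * delta_hb) * d_dpf
    return i_b_l1 * 10.0 ** (-od_l1), i_b_l2 * 10.0 ** (-od_l2)


def chromophores_to_csv(series: ChromophoreSeries, path) -> None:
    """Write [time_s, <site>_<chromophore> ...] columns as CSV."""
    series.to_dataframe().to_csv(path, index=False)


__all__ = [
    "ReferenceIntervalPolicy",
    "delta_concentrations",
    "intensity_to_chromophores",
    "forward_intensities",
    "chromophores_to_csv",
    "CHROMOPHORES",
]
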