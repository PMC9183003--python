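"""Optical constants for dual-wavelength continuous-wave fNIRS.

The default extinction coefficients are the Matcher et al. compiled values
for deoxygenated (Hb) and oxygenated (HbO2) haemoglobin at the two emitter
wavelengths of the wearable sensor used here: 660 nm (red) and 860 nm
(infrared), in mM^-1 cm^-1.  The differential path-length factor (DPF) is
kept symbolic (set to 1) so that concentration changes carry units of
mM/DPF; only the product d*DPF enters the modified Beer-Lambert law.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class OpticalConstants:
    """Extinction coefficients and geometry for the two-wavelength probe.

    Attributes
    ----------
    epsilon_hb_l1, epsilon_hbo2_l1 : float
        Extinction coefficients (mM^-1 cm^-1) of Hb and HbO2 at ``lambda1_nm``.
    epsilon_hb_l2, epsilon_hbo2_l2 : float
        Same at ``lambda2_nm``.
    emitter_detector_distance_cm : float
        Source-detector separation d, in cm.
    dpf : float
        Differential path-length factor; 1.0 by convention here, so
        concentrations are expressed in mM/DPF.
    """

    epsilon_hb_l1: float = 3.4408
    epsilon_hbo2_l1: float = 0.3346
    epsilon_hb_l2: float = 0.7977
    epsilon_hbo2_l2: float = 1.2071
    emitter_detector_distance_cm: float = 2.0
    dpf: float = 1.0
    lambda1_nm: float = 660.0
    lambda2_nm: float = 860.0

    def __post_init__(self) -> None:
        for name in (
            "epsilon_hb_l1",
            "epsilon_hbo2_l1",
            "epsilon_hb_l2",
            "epsilon_hbo2_l2",
            "emitter_detector_distance_cm",
            "dpf",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.lambda1_nm < self.lambda2_nm:
            raise ValueError("lambda1_nm must be smaller than lambda2_nm")

    @property
    def determinant(self) -> float:
        """Determinant eps_HbO2^l1*eps_Hb^l2 - eps_HbO2^l2*eps_Hb^l1 of the
        2x2 extinction system; must be nonzero for the inversion to exist."""
        return (
            self.epsilon_hbo2_l1 * self.epsilon_hb_l2
            - self.epsilon_hbo2_l2 * self.epsilon_hb_l1
        )


DEFAULT_CONSTANTS = OpticalConstants()
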