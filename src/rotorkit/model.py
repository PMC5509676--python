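"""Phenomenological ionic model and its named calibration profile.

The tissue solver uses a three-current excitable model of the Fenton-Karma
family: a fast inward (depolarizing) current gated by ``v``, a slow inward
(plateau) current gated by ``w``, and an ungated slow outward
(repolarizing) current.  The membrane variable ``u`` is dimensionless;
``u = 0`` is the diastolic potential and ``u ~ 1`` the action-potential
peak.  Conversion to millivolts is an affine map supplied by
:class:`VoltageCalibration`.

The default profile, ``HESC_ATRIAL``, is a one-off calibration to the
electrophysiology of immature atrial-like cardiomyocyte monolayers: slow
upstrokes, action potential duration (APD90) near 200 ms, planar conduction
velocity near 5 cm/s, and re-entrant spiral waves with a cycle length close
to 300 ms on a 1-cm sheet.  ``scripts/calibrate_profile.py`` reproduces the
tuning measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["IonicParams", "VoltageCalibration", "HESC_ATRIAL"]


@dataclass(frozen=True)
class IonicParams:
    """Time constants (ms) and thresholds (dimensionless) of the 3-variable model.

    ``tau_d`` is the inverse of the fast-inward conductance ``g_fi``;
    ``tau_r`` and ``tau_0`` are inverses of the repolarizing conductance
    above/below threshold.  Scaling a conductance by ``s`` divides it into
    the corresponding tau (``tau / s``).
    """

    tau_d: float = 1.0        # fast inward; 1/g_fi
    tau_r: float = 70.0       # slow outward during the plateau; 1/g_rep
    tau_si: float = 85.0      # slow inward (plateau) magnitude
    tau_0: float = 30.0       # slow outward below threshold; diastolic decay
    tau_v_plus: float = 30.0  # v-gate inactivation during the AP
    tau_v1_minus: float = 250.0  # v-gate recovery, u_v < u < u_c
    tau_v2_minus: float = 140.0  # v-gate recovery, u < u_v
    tau_w_plus: float = 300.0    # w-gate inactivation during the AP
    tau_w_minus: float = 120.0   # w-gate recovery in diastole
    u_c: float = 0.13         # excitation threshold
    u_v: float = 0.04         # switch level between the two v recoveries
    u_csi: float = 0.6        # slow-inward activation midpoint
    k_si: float = 10.0        # slow-inward activation steepness

    def __post_init__(self) -> None:
        for name in ("tau_d", "tau_r", "tau_si", "tau_0", "tau_v_plus",
                     "tau_v1_minus", "tau_v2_minus", "tau_w_plus",
                     "tau_w_minus"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")

    def to_vector(self) -> np.ndarray:
        """Pack into the flat layout the compiled kernels expect."""
        return np.array([
            self.tau_d, self.tau_r, self.tau_si, self.tau_0,
            self.tau_v_plus, self.tau_v1_minus, self.tau_v2_minus,
            self.tau_w_plus, self.tau_w_minus,
            self.u_c, self.u_v, self.u_csi, self.k_si,
        ])

    def scaled(self, g_fi_scale: float = 1.0,
               g_rep_scale: float = 1.0) -> "IonicParams":
        """Return a copy with the fast-inward / repolarizing conductances scaled.

        Zero scalings are clipped to a tiny positive conductance so the
        corresponding tau stays finite.
        """
        g_fi = max(g_fi_scale, 1e-6)
        g_rep = max(g_rep_scale, 1e-6)
        return replace(self, tau_d=self.tau_d / g_fi,
                       tau_r=self.tau_r / g_rep,
                       tau_0=self.tau_0 / g_rep)


@dataclass(frozen=True)
class VoltageCalibration:
    """Affine map from model units to mV: ``V = dmp + apa * u``.

    Defaults match whole-cell recordings from atrial-like cardiomyocytes of
    the immature phenotype (diastolic potential -56 mV, amplitude 80 mV).
    """

    dmp: float = -56.0
    apa: float = 80.0

    def to_mv(self, u: np.ndarray) -> np.ndarray:
        return self.dmp + self.apa * np.asarray(u)

    def to_model(self, v_mv: np.ndarray) -> np.ndarray:
        return (np.asarray(v_mv) - self.dmp) / self.apa


#: Calibration profile for immature atrial-like monolayers (see module docstring).
HESC_ATRIAL = IonicParams()
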