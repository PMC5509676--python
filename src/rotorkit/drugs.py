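"""Antiarrhythmic drug models: conductance scalings, use-dependent
sodium-channel block, and voltage-dependent Na availability.

Use-dependent block follows a guarded-receptor picture: drug reaches the
channel only during the activated phase of each action potential (duration
``d`` ms), where the blocked fraction relaxes toward an equilibrium level
``b_eq`` with rate ``k_block``; between beats the block unbinds with the
diastolic recovery constant ``tau_rec``.  Per beat, starting from block
``b`` at end-diastole::

    b_activated = b_eq - (b_eq - b) * exp(-k_block * d)
    b_next      = b_activated * exp(-(CL - d) / tau_rec)

The steady state of this map has the closed form implemented by
:func:`steady_state_block`; it is strictly decreasing in the cycle length,
which is the hallmark of use dependence (more block at faster rates).

Na-channel availability as a function of the holding/diastolic potential is
the usual Boltzmann inactivation curve ``h = 1 / (1 + exp((V - V_half)/k))``.
It links a depolarized diastolic membrane potential to a loss of fast
inward current, which is how a repolarization-blocking drug can slow the
upstroke without touching the sodium conductance itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import ProtocolError, ConfigurationError

__all__ = [
    "UseDependentBlock", "Boltzmann", "DrugModel",
    "steady_state_block", "na_availability", "availability_reduction",
    "calibrate_use_dependent", "calibrate_v_half",
    "flecainide_like", "dofetilide_like",
]

#: Diastolic membrane potential (mV) of the atrial-like phenotype; reference
#: point for availability-mediated effects of a diastolic depolarization.
DMP_BASELINE_MV = -56.0


@dataclass(frozen=True)
class UseDependentBlock:
    """Kinetic parameters of rate-dependent channel block.

    ``k_block`` (1/ms) acts during the activated phase of duration ``d`` per
    beat; ``tau_rec`` (ms) is the diastolic unbinding constant; ``b_eq`` is
    the within-AP equilibrium blocked fraction (1 = every accessible channel
    eventually blocks, the classical no-unbinding limit).
    """

    k_block: float
    tau_rec: float
    b_eq: float = 1.0

    def __post_init__(self):
        if self.tau_rec <= 0:
            raise ConfigurationError("tau_rec must be positive")
        if self.k_block < 0 or not (0.0 <= self.b_eq <= 1.0):
            raise ConfigurationError("invalid block kinetics")


@dataclass(frozen=True)
class Boltzmann:
    """Steady-state inactivation curve parameters (mV)."""

    v_half: float
    k_slope: float

    def __post_init__(self):
        if self.k_slope <= 0:
            raise ConfigurationError("k_slope must be positive")


@dataclass(frozen=True)
class DrugModel:
    """Composite drug action applied to the tissue model.

    ``g_fi_scale`` and ``g_rep_scale`` scale the fast-inward and
    repolarizing conductances (1 = no block).  ``use_dependent`` adds
    rate-dependent fast-inward block on top; ``dmp_shift`` (mV) depolarizes
    the diastolic potential, which indirectly reduces the fast inward via
    ``na_availability``.
    """

    name: str = "drug"
    g_fi_scale: float = 1.0
    g_rep_scale: float = 1.0
    use_dependent: UseDependentBlock | None = None
    na_boltzmann: Boltzmann | None = None
    dmp_shift: float = 0.0
    ap_duration: float = 250.0  # d in the use-dependent recurrence, ms

    def __post_init__(self):
        if not (0.0 <= self.g_fi_scale <= 1.0 and 0.0 <= self.g_rep_scale <= 1.0):
            raise ConfigurationError("conductance scales must lie in [0, 1]")

    def effective_g_fi(self, cycle_length: float | None = None) -> float:
        """Fast-inward scaling including use-dependent block at the given rate
        and any availability loss from a diastolic depolarization."""
        g = self.g_fi_scale
        if self.use_dependent is not None and cycle_length is not None:
            b = steady_state_block(cycle_length, self.ap_duration,
                                   self.use_dependent.k_block,
                                   self.use_dependent.tau_rec,
                                   self.use_dependent.b_eq)
            g *= 1.0 - b
        if self.dmp_shift != 0.0 and self.na_boltzmann is not None:
            g *= (na_availability(DMP_BASELINE_MV + self.dmp_shift, self.na_boltzmann)
                  / na_availability(DMP_BASELINE_MV, self.na_boltzmann))
        return g


def steady_state_block(cycle_length: float, ap_duration: float,
                       k_block: float, tau_rec: float,
                       b_eq: float = 1.0) -> float:
    """Fixed point of the per-beat block recurrence, evaluated end-diastole.

    Closed form::

        E = exp(-k_block * d);  G = exp(-(CL - d) / tau_rec)
        B = b_eq * (1 - E) * G / (1 - E * G)

    Parameters are as in :class:`UseDependentBlock`; ``cycle_length`` and
    ``ap_duration`` in ms.  Raises :class:`ProtocolError` unless
    ``CL > d > 0``.
    """
    if not (cycle_length > ap_duration > 0):
        raise ProtocolError("need cycle_length > ap_duration > 0")
    if tau_rec <= 0:
        raise ProtocolError("tau_rec must be positive")
    e = math.exp(-k_block * ap_duration)
    g = math.exp(-(cycle_length - ap_duration) / tau_rec)
    return b_eq * (1.0 - e) * g / (1.0 - e * g)


def na_availability(v_hold: float, boltz: Boltzmann) -> float:
    """Fraction of sodium channels available at a holding potential (mV)."""
    return 1.0 / (1.0 + math.exp((v_hold - boltz.v_half) / boltz.k_slope))


def availability_reduction(boltz: Boltzmann, v_test: float = -58.0,
                           v_ref: float = -80.0) -> float:
    """Fractional loss of availability at ``v_test`` relative to ``v_ref``."""
    return 1.0 - na_availability(v_test, boltz) / na_availability(v_ref, boltz)


def calibrate_use_dependent(
        points=((2000.0, 0.506), (330.0, 0.858)),
        ap_duration: float = 250.0,
        k_block: float = 0.05) -> UseDependentBlock:
    """Solve (b_eq, tau_rec) so the steady-state block hits two operating points.

    ``points`` are (cycle length ms, blocked fraction) pairs, slow rate
    first.  ``k_block`` is held at a value that saturates within one action
    potential (k_block * d >> 1), leaving a two-unknown root-finding problem
    with, in the saturating limit, the closed-form solution::

        tau_rec = (CL_slow - CL_fast) / log(B_fast / B_slow)
        b_eq    = B_fast * exp((CL_fast - d) / tau_rec)

    which seeds a bisection on the exact fixed point.
    """
    (cl_s, b_s), (cl_f, b_f) = points
    if not (cl_s > cl_f > ap_duration and 0 < b_s < b_f < 1):
        raise ConfigurationError("operating points must satisfy "
                                 "CL_slow > CL_fast > d and B_slow < B_fast")
    tau0 = (cl_s - cl_f) / math.log(b_f / b_s)

    def resid(tau):
        beq = min(1.0, b_f / steady_state_block(cl_f, ap_duration, k_block, tau))
        return steady_state_block(cl_s, ap_duration, k_block, tau, beq) - b_s

    tau = brentq(resid, 0.2 * tau0, 5.0 * tau0, xtol=1e-10, rtol=1e-14)
    b_eq = b_f / steady_state_block(cl_f, ap_duration, k_block, tau)
    return UseDependentBlock(k_block=k_block, tau_rec=tau, b_eq=b_eq)


def calibrate_v_half(reduction: float = 0.4043, k_slope: float = 5.5,
                     v_test: float = -58.0, v_ref: float = -80.0) -> Boltzmann:
    """Find ``V_half`` so the availability drop between ``v_ref`` and
    ``v_test`` equals ``reduction`` (AP-clamp style measurement)."""

    def resid(vh):
        return availability_reduction(Boltzmann(vh, k_slope), v_test, v_ref) - reduction

    v_half = brentq(resid, -120.0, 20.0, xtol=1e-12)
    return Boltzmann(v_half=v_half, k_slope=k_slope)


def flecainide_like(g_fi_scale: float = 0.7) -> DrugModel:
    """Class Ic profile: use-dependent fast-inward block, no direct effect on
    repolarization.

    The kinetics are calibrated to voltage-clamp block measurements at cycle
    lengths of 2 s and 330 ms.  ``g_fi_scale`` sets the conductance scaling
    used in sheet-level experiments; the phenomenological model loses
    propagation entirely at the full clamp-measured block fraction, so sheet
    runs use a moderate dose by default (see the methods note).
    """
    return DrugModel(name="flecainide-like", g_fi_scale=g_fi_scale,
                     use_dependent=calibrate_use_dependent())


def dofetilide_like(g_rep_scale: float = 0.8, dmp_shift: float = 4.0) -> DrugModel:
    """Class III profile: repolarizing-current block plus a small diastolic
    depolarization that reduces Na availability (and hence upstroke velocity)."""
    return DrugModel(name="dofetilide-like", g_rep_scale=g_rep_scale,
                     dmp_shift=dmp_shift, na_boltzmann=calibrate_v_half())
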