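"""Reproduce the tuning measurements behind the "hESC-atrial" profile.

The profile targets the emergent electrophysiology of immature atrial-like
monolayers: single-cell APD90 ~ 200-250 ms, planar conduction velocity
~ 5-6 cm/s, spiral-wave (rotor) cycle length ~ 300 ms on a 1-cm sheet, and
sustained reentry under cross-field induction.  Run:

    python scripts/calibrate_profile.py

It prints the measured values for the shipped profile; edit IonicParams
fields to explore alternatives.
"""

import time

import numpy as np

import rotorkit as rk


def apd90_single_cell(ionic=rk.HESC_ATRIAL, cl=769.0):
    t, u = rk.simulate_cell(ionic, cycle_length=cl, n_beats=4)
    sel = t >= 3 * cl - 50
    x, tt = u[sel], t[sel]
    peak, rest = x.max(), x.min()
    i_up = int(np.argmax(np.diff(x)))
    lev = peak - 0.9 * (peak - rest)
    below = np.nonzero(x[i_up:] < lev)[0]
    return tt[i_up + below[0]] - tt[i_up]


def planar_cv(ionic=rk.HESC_ATRIAL, cl=800.0, **kw):
    t, u = rk.simulate_cable(ionic, cycle_length=cl, n_beats=4, **kw)
    return rk.cable_conduction_velocity(t, u, dx=0.1,
                                        beat_start=3 * cl - 5)


def main():
    t0 = time.time()
    print(f"single-cell APD90 at CL 769 ms: {apd90_single_cell():.1f} ms")
    print(f"planar (cable) CV at CL 800 ms: {planar_cv():.2f} cm/s")
    for cl in (800, 500, 400, 350, 300):
        print(f"  CV restitution CL {cl:4d} ms: {planar_cv(cl=float(cl)):.2f} cm/s")
    ind = rk.induce_rotor(rk.TissueConfig(), seed=0)
    print(f"rotor induction: success={ind.success} "
          f"S2={ind.s2_delay} ms CL={ind.rotor_cl:.0f} ms "
          f"rotations={ind.n_rotations:.1f}")
    print(f"[{time.time() - t0:.0f} s]")


if __name__ == "__main__":
    main()
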