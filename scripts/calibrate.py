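"""One-time calibration of the effective I_KATP conductance.

The source formulation prints the K_ATP channel conductance on a
channel-density scale (195e-6/Nichols_area nS/cm^2) that has no unique
mapping onto the per-capacitance units (nS/pF) of the cell model.  The
package therefore fixes the effective maximal conductance by requiring the
documented hypoxic behaviour of the modified model: APD90 = 50 ms for a
single cell with [ATP]i = 3 mM and all other parameters healthy, paced at
1 Hz.  This script reproduces that bisection; the result is frozen as
``KatpConstants.g_katp_max``.

Run:  python scripts/calibrate.py
"""

from cardiomaze.activity_metrics import measure_apd90
from cardiomaze.ionic_model import IschemiaParams, KatpConstants, run_single_cell

TARGET_APD_MS = 50.0
HYPOXIC = IschemiaParams(atp_i=3.0)


def apd_for(g: float) -> float:
    t, v = run_single_cell(HYPOXIC, consts=KatpConstants(g_katp_max=g),
                           sample_every=0.2)
    apd = measure_apd90(t, v)
    assert apd is not None
    return apd


def main() -> None:
    lo, hi = 2.0, 20.0
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if apd_for(mid) > TARGET_APD_MS:
            lo = mid
        else:
            hi = mid
    g = 0.5 * (lo + hi)
    print(f"g_katp_max = {g:.4f} nS/pF  (APD90 at 3 mM = {apd_for(g):.1f} ms)")


if __name__ == "__main__":
    main()
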