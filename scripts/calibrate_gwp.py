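"""One-off calibration of the metric-side IRF parameters.

Two of the compact model's parameters are not fixed by the AR5-style
defaults: the climate-carbon feedback gain (Pg C yr-1 released per K
of warming) and the net stratospheric-O3 multiplier on direct N2O
forcing. This script solves for the pair that makes the model's own
GWP100 metrics (feedback on, consistently in numerator and
denominator) equal 34 for CH4 and 267 for N2O, and prints the values
to freeze as `IRFParams` defaults.

The solve is sequential and exact: GWP(CH4) is independent of
f_stratO3, so gamma is found first from the CH4 target, then f_stratO3
from the N2O target at that gamma.

Run from the repository root:

    python scripts/calibrate_gwp.py
"""

from dataclasses import replace

from scipy.optimize import brentq

from grassflux.rf import IRFParams, gwp

TARGET_CH4 = 34.0
TARGET_N2O = 267.0


def main() -> None:
    base = IRFParams(gamma_feedback=0.0, f_stratO3=0.0)

    print(f"GWP100(CH4) without feedback: {gwp('ch4', params=base, with_feedback=False):.3f}")
    print(f"GWP100(N2O) without feedback, no stratO3: {gwp('n2o', params=base, with_feedback=False):.3f}")

    def ch4_residual(gamma: float) -> float:
        p = replace(base, gamma_feedback=gamma)
        return gwp("ch4", params=p, with_feedback=True) - TARGET_CH4

    gamma = brentq(ch4_residual, 0.0, 20.0, xtol=1e-10)
    print(f"calibrated gamma_feedback = {gamma:.6f} PgC/yr/K")

    def n2o_residual(f: float) -> float:
        p = replace(base, gamma_feedback=gamma, f_stratO3=f)
        return gwp("n2o", params=p, with_feedback=True) - TARGET_N2O

    f_strato3 = brentq(n2o_residual, -0.9, 0.9, xtol=1e-12)
    print(f"calibrated f_stratO3 = {f_strato3:.6f}")

    final = replace(base, gamma_feedback=gamma, f_stratO3=f_strato3)
    print(f"check GWP100(CH4) = {gwp('ch4', params=final):.4f}")
    print(f"check GWP100(N2O) = {gwp('n2o', params=final):.4f}")


if __name__ == "__main__":
    main()
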