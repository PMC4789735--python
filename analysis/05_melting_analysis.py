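#!/usr/bin/env python
"""Junction melting: distance-based alpha(T), van't Hoff thermodynamics,
absorbance analysis, and Debye screening.

Runs the full melting pipeline end to end on synthetic data: frame
ensembles drawn from the two-state tetramolecular model are reduced to
alpha(T) with the 10 A / more-than-half-broken criterion, fitted with
the van't Hoff relation in the 0.1 < alpha < 0.9 window, and checked
against the generating thermodynamics and the alpha(T_M) = 1/2
identity.  A noiseless absorbance melt with sloping baselines closes
the loop on the experimental route, and the Debye screening length
table shows why the melting temperature plateaus at high salt.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from junctionlab import io
from junctionlab.melting import (
    MeltingCriteria,
    absorbance_to_alpha,
    debye_length,
    enthalpy_entropy_identity,
    fit_vant_hoff,
    melting_curve_from_frames,
    melting_temperature,
)
from junctionlab.synthetic import (
    MeltingGroundTruth,
    simulate_absorbance,
    simulate_melting_frames,
)
from junctionlab.topology import build_topology, synthetic_junction_sequences

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 516
DH, TM, C_TOTAL = 120.0, 330.0, 6.0e-7  # kcal/mol, K, mol/L (150 nM junction)
FRAMES_PER_T = 200


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    topo = build_topology(synthetic_junction_sequences(17), 17)
    truth = MeltingGroundTruth.from_tm(DH, TM, C_TOTAL, np.arange(310.0, 350.5, 1.0))
    print(f"ground truth: dH = {truth.dh:.1f} kcal/mol, dS = {truth.ds:.5f} kcal/(mol K), "
          f"T_M = {truth.tm:.2f} K at C = {C_TOTAL:.1e} M")

    frames = simulate_melting_frames(truth, topo, FRAMES_PER_T, seed=SEED)
    curve = melting_curve_from_frames(frames, topo, MeltingCriteria(), c_total=C_TOTAL)
    io.write_melting_csv(RESULTS / "melting_curve.csv", curve)
    tm_obs = melting_temperature(curve)
    print(f"\ndistance pipeline ({FRAMES_PER_T} frames/T, 10 A pair cutoff, "
          f">1/2 broken rule): T_M = {tm_obs:.2f} K")

    fit = fit_vant_hoff(curve)
    print(f"van't Hoff fit (0.1 < alpha < 0.9, {fit.n_used} points): "
          f"dH = {fit.dh:.1f} kcal/mol, dS = {fit.ds:.5f} kcal/(mol K), T_M = {fit.tm:.2f} K")
    dh_identity = enthalpy_entropy_identity(fit.ds, fit.tm, C_TOTAL)
    print(f"enthalpy-entropy identity check: dH(fit) - dH(identity) = "
          f"{fit.dh - dh_identity:+.2e} kcal/mol")
    io.write_json(RESULTS / "vant_hoff_fit.json", fit.as_dict(), seed=SEED)

    # absorbance melts span a much wider range so the baseline windows
    # sit clear of the transition
    truth_wide = MeltingGroundTruth.from_tm(DH, TM, C_TOTAL, np.arange(280.0, 370.5, 1.0))
    ab = simulate_absorbance(truth_wide)
    io.write_absorbance_csv(RESULTS / "absorbance_melt.csv", ab)
    rec = absorbance_to_alpha(ab, c_total=C_TOTAL)
    fit_ab = fit_vant_hoff(rec)
    print(f"\nabsorbance route (fitted linear baselines): dH = {fit_ab.dh:.1f} kcal/mol, "
          f"T_M = {fit_ab.tm:.2f} K")

    salts_mm = np.array([10, 25, 50, 100, 200, 300, 500])
    rows = [
        {
            "salt_mM": s,
            "debye_fixed_A": debye_length(300.0, s / 1000.0, "fixed"),
            "debye_empirical_A": debye_length(300.0, s / 1000.0, "empirical"),
        }
        for s in salts_mm
    ]
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "debye_lengths.csv", index=False)
    print("\nDebye screening length at 300 K (A):")
    print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
    print("screening below ~6 A at [Na+] >= 300 mM makes electrostatic repulsion "
          "insignificant, matching the T_M plateau at high salt")
    print(f"\nwrote melting tables to {RESULTS}")


if __name__ == "__main__":
    main()
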