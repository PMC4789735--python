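#!/usr/bin/env python
"""Coordinate-level validation of the core-distance conformer classifier.

Renders a small trajectory ensemble (switching model + idealized
geometries + 1 A site noise + random rigid motions), classifies every
frame from raw coordinates, and compares the recovered labels with the
generator's ground truth.  Also writes the pooled core-distance
distributions whose bimodal structure (minimum near 12 A) motivates the
classification cutoff.
"""

from pathlib import Path

import numpy as np

from junctionlab import io
from junctionlab.conformers import classify_trajectory, distance_distribution
from junctionlab.geometry import default_templates
from junctionlab.kinetics import KineticModel
from junctionlab.synthetic import simulate_ensemble
from junctionlab.topology import build_topology, synthetic_junction_sequences

RESULTS = Path(__file__).resolve().parent.parent / "results"
MASTER_SEED = 314
N_MEMBERS, DURATION_NS, SIGMA = 6, 400.0, 1.0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    topo = build_topology(synthetic_junction_sequences(17), 17)
    templates = default_templates(topo)
    model = KineticModel()
    pi = model.stationary_distribution()
    trajs, truth = simulate_ensemble(
        model, templates, N_MEMBERS, DURATION_NS, 1.0, SIGMA,
        initial_distribution=tuple(pi), master_seed=MASTER_SEED,
    )

    agree = total = 0
    for traj, series in zip(trajs, truth):
        labels = classify_trajectory(traj, topo).states
        agree += int((labels == series.states).sum())
        total += len(labels)
    print(f"{N_MEMBERS} members x {DURATION_NS:.0f} ns rendered at sigma = {SIGMA} A")
    print(f"frame labels recovered from coordinates: {agree}/{total} "
          f"({100 * agree / total:.2f} %)")

    for which, fname in (("AG", "distance_distribution_ag.csv"),
                         ("TTCC", "distance_distribution_ttcc.csv")):
        hist = distance_distribution(trajs, topo, which=which, bin_width=0.5)
        io.write_histogram_csv(RESULTS / fname, hist)
        centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
        inner = (centers > 6) & (centers < 20)
        trough = centers[inner][np.argmin(hist.density[inner])]
        print(f"P(d_{which}): {hist.mode_count()} modes, minimum between peaks near "
              f"{trough:.1f} A (classification cutoff: 12 A)")
    print(f"wrote distance distributions to {RESULTS}")


if __name__ == "__main__":
    main()
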