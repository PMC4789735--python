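"""Synthetic trajectory ensembles and melting data.

This module stands in for the coarse-grained MD engine at desk scale:
conformer dynamics come from the exact three-state Markov chain of
:mod:`junctionlab.kinetics`, geometry from the idealized templates of
:mod:`junctionlab.geometry`, and melting ensembles from the two-state
tetramolecular mass-action model.  The generators reproduce exactly the
statistical structure the analysis consumes -- populations, transition
statistics, core distances, inter-duplex angles, single-strand
fractions -- without any force field.

All randomness flows from explicit seeds; ensemble members draw their
streams from ``numpy`` seed sequences spawned off one master seed, so
identical seeds give identical output and member streams never collide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .conformers import ConformerState
from .geometry import GeometryTemplate
from .kinetics import KineticModel, StateSeries, simulate_state_series
from .melting import R_KCAL, vant_hoff_alpha
from .topology import JunctionTopology
from .trajectory import Trajectory


def render_trajectory(
    series: StateSeries,
    templates: dict[ConformerState, GeometryTemplate],
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
    rigid_motion: bool = True,
    metadata: dict | None = None,
) -> Trajectory:
    """Turn a state series into site coordinates.

    Each frame is the template of that frame's state plus isotropic
    Gaussian site noise of standard deviation ``sigma`` (Angstrom, per
    axis) plus a random rigid motion of the whole frame.  With
    ``sigma=0`` every inter-site distance equals the template's.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    occurring = {ConformerState(int(s)) for s in np.unique(series.states)}
    missing = occurring - set(templates)
    if missing:
        raise KeyError(f"no template for occurring state(s): {sorted(s.label for s in missing)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sites = len(next(iter(templates.values())).coordinates)
    coords = np.empty((len(series.states), n_sites, 3))
    for f, s in enumerate(series.states):
        frame = templates[ConformerState(int(s))].coordinates.copy()
        if sigma > 0:
            frame = frame + rng.normal(0.0, sigma, size=frame.shape)
        if rigid_motion:
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(0.0, 10.0, size=3)
            frame = frame @ rot.T + shift
        coords[f] = frame
    md = dict(metadata or {})
    md.setdefault("member_id", series.member_id)
    md.setdefault("sigma_A", sigma)
    return Trajectory(coords=coords, times_ns=series.times_ns.copy(), metadata=md)


def simulate_ensemble(
    model: KineticModel,
    templates: dict[ConformerState, GeometryTemplate],
    n_members: int,
    duration_ns: float,
    dt_ns: float = 1.0,
    sigma: float = 1.0,
    initial_distribution=(1.0, 0.0, 0.0),
    master_seed: int = 0,
    metadata: dict | None = None,
) -> tuple[list[Trajectory], list[StateSeries]]:
    """Independent rendered members plus their ground-truth state series.

    ``initial_distribution`` is (open, iso-I, iso-II).  Stage 1 of the
    two-stage protocol uses the all-open default; stage 2 passes the
    population estimate from stage 1.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    p = np.asarray(initial_distribution, dtype=float)
    if p.shape != (3,) or p.min() < 0 or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("initial distribution must be 3 non-negative values summing to 1")
    trajectories: list[Trajectory] = []
    series_list: list[StateSeries] = []
    for m, child in enumerate(np.random.SeedSequence(master_seed).spawn(n_members)):
        state_rng, render_rng = (np.random.default_rng(s) for s in child.spawn(2))
        s0 = int(state_rng.choice(3, p=p / p.sum()))
        series = simulate_state_series(model, duration_ns, dt_ns, s0, seed=state_rng, member_id=m)
        md = dict(metadata or {})
        md["member_id"] = m
        md["master_seed"] = master_seed
        trajectories.append(render_trajectory(series, templates, sigma, seed=render_rng, metadata=md))
        series_list.append(series)
    return trajectories, series_list


@dataclass(frozen=True)
class MeltingGroundTruth:
    """Two-state tetramolecular melting parameters used to generate data.

    dH and dS are in the melting direction (intact junction -> four
    single strands), in kcal/mol and kcal/(mol K); C is the total
    strand concentration in mol/L (each strand at C/4).  The defaults
    describe a junction melting near 330 K at the 150 nM junction
    concentration of the absorbance measurements.
    """

    dh: float = 120.0
    ds: float = 0.0
    c_total: float = 6.0e-7
    temperatures: np.ndarray = field(default_factory=lambda: np.arange(300.0, 360.5, 1.0))

    def __post_init__(self) -> None:
        if self.ds == 0.0:
            # default dS: place T_M at 330 K via the alpha = 1/2 identity
            object.__setattr__(self, "ds", self.ds_for_tm(330.0))
        if self.dh <= 0 or self.ds <= 0 or self.c_total <= 0:
            raise ValueError("dH, dS and C must be positive")
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.diff(t).min() <= 0:
            raise ValueError("temperature grid must be strictly increasing")
        object.__setattr__(self, "temperatures", t)

    def ds_for_tm(self, tm: float) -> float:
        """The dS that puts alpha(T_M) = 1/2 for this dH and C."""
        ln_k_half = 3.0 * np.log(self.c_total / 4.0) - np.log(8.0)
        return self.dh / tm + R_KCAL * ln_k_half

    @property
    def tm(self) -> float:
        """Melting temperature implied by the alpha = 1/2 identity."""
        ln_k_half = 3.0 * np.log(self.c_total / 4.0) - np.log(8.0)
        return self.dh / (self.ds - R_KCAL * ln_k_half)

    def alpha(self, temperature) -> np.ndarray:
        """Model single-strand fraction on an array of temperatures."""
        t = np.atleast_1d(np.asarray(temperature, dtype=float))
        out = np.array([vant_hoff_alpha(ti, self.dh, self.ds, self.c_total) for ti in t])
        return out if np.ndim(temperature) else out

    @classmethod
    def from_tm(cls, dh: float, tm: float, c_total: float, temperatures=None) -> "MeltingGroundTruth":
        ln_k_half = 3.0 * np.log(c_total / 4.0) - np.log(8.0)
        ds = dh / tm + R_KCAL * ln_k_half
        kwargs = {} if temperatures is None else {"temperatures": np.asarray(temperatures, dtype=float)}
        return cls(dh=dh, ds=ds, c_total=c_total, **kwargs)


# distance draws straddling the 10 A base-pair criterion
_INTACT_RANGE = (4.0, 8.0)
_MELTED_RANGE = (12.0, 30.0)


@dataclass
class MeltingFrameSet:
    """Per-temperature frame ensembles for the distance-based estimator."""

    temperatures: np.ndarray
    frames: list[np.ndarray]  # one (n_frames, n_sites, 3) array per temperature
    alpha_true: np.ndarray
    seed: int


def simulate_melting_frames(
    truth: MeltingGroundTruth,
    topology: JunctionTopology,
    frames_per_t: int = 100,
    seed: int = 0,
    per_pair: bool = False,
) -> MeltingFrameSet:
    """Draw per-temperature frames whose base-pair separations encode melting.

    At each grid temperature the model alpha is computed from the
    mass-action relation; each frame is then drawn melted (all
    base-pair separations uniform in 12-30 A) with probability alpha,
    or intact (4-8 A) otherwise.  With ``per_pair=True`` every base
    pair melts independently with probability alpha, which exercises
    the more-than-half-broken strand rule on partially melted
    junctions.
    """
    if frames_per_t < 1:
        raise ValueError("frames_per_t must be >= 1")
    rng = np.random.default_rng(seed)
    pair_idx = topology.base_pair_indices()
    n_pairs = len(pair_idx)
    alphas = truth.alpha(truth.temperatures)
    frames: list[np.ndarray] = []
    for a in alphas:
        block = np.zeros((frames_per_t, topology.n_sites, 3))
        if per_pair:
            melted = rng.random((frames_per_t, n_pairs)) < a
        else:
            melted = np.broadcast_to(
                (rng.random(frames_per_t) < a)[:, None], (frames_per_t, n_pairs)
            )
        d = np.where(
            melted,
            rng.uniform(*_MELTED_RANGE, size=(frames_per_t, n_pairs)),
            rng.uniform(*_INTACT_RANGE, size=(frames_per_t, n_pairs)),
        )
        # lay pairs out on a line, far apart, with the drawn separation;
        # only pair distances matter to the melting estimator
        base_x = 100.0 * np.arange(n_pairs)
        block[:, pair_idx[:, 0], 0] = base_x
        block[:, pair_idx[:, 1], 0] = base_x + d
        frames.append(block)
    return MeltingFrameSet(
        temperatures=truth.temperatures.copy(), frames=frames, alpha_true=alphas, seed=seed
    )


@dataclass(frozen=True)
class LinearBaselines:
    """Lower/upper absorbance baselines A = a0 + a1 * T (T in K)."""

    lower: tuple[float, float] = (0.30, 0.0004)
    upper: tuple[float, float] = (0.50, 0.0006)

    def low(self, t):
        return self.lower[0] + self.lower[1] * np.asarray(t, dtype=float)

    def high(self, t):
        return self.upper[0] + self.upper[1] * np.asarray(t, dtype=float)


def simulate_absorbance(
    truth: MeltingGroundTruth,
    baselines: LinearBaselines = LinearBaselines(),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic UV melting curve A(T) with linear sloping baselines.

    A(T) = A_low(T) + alpha(T) * (A_up(T) - A_low(T)) + Gaussian noise.
    Raises if the baselines cross anywhere on the temperature grid.
    """
    from .melting import AbsorbanceCurve

    t = truth.temperatures
    low, high = baselines.low(t), baselines.high(t)
    if np.any(high <= low):
        raise ValueError("upper baseline must exceed the lower baseline over the grid")
    alpha = truth.alpha(t)
    a = low + alpha * (high - low)
    if noise_sd > 0:
        a = a + np.random.default_rng(seed).normal(0.0, noise_sd, size=a.shape)
    span = t[-1] - t[0]
    return AbsorbanceCurve(
        temperature=t.copy(),
        absorbance=a,
        lower_window=(float(t[0]), float(t[0] + 0.15 * span)),
        upper_window=(float(t[-1] - 0.15 * span), float(t[-1])),
    )
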