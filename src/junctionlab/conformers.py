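"""Conformer classification and ensemble statistics for four-way junctions.

Frames are assigned to one of three conformers -- open, iso-I or iso-II
-- from the four inter-base distances at the junction core.  The two
stacked conformers each have a signature pair family that collapses
below a single distance cutoff (default 12 A, the minimum between the
stacked and open peaks of the pooled distance distributions): the X/H
marker pairs for iso-I, the R/B (AG) pairs for iso-II.  Frames in which
both families are short carry conflicting signatures and are labelled
ambiguous rather than silently assigned; frames in which neither family
is short are open.

On top of the per-frame labels the module computes ensemble population
fractions with member-level standard errors (the junctions interconvert
slowly enough that single trajectories are not ergodic, so members are
averaged with equal weight), empirical transition matrices, pooled
core-distance distributions, and the inter-duplex angle (IDA) between
two arms at the junction vertex.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .topology import ARM_ALIASES, JunctionTopology, core_marker_index_pairs


class ConformerState(enum.IntEnum):
    OPEN = 0
    ISO_I = 1
    ISO_II = 2
    AMBIGUOUS = 3

    @property
    def label(self) -> str:
        return _STATE_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "ConformerState":
        try:
            return _LABEL_STATES[label.replace("-", "_")]
        except KeyError:
            raise ValueError(f"unknown conformer label {label!r}") from None


_STATE_LABELS = {
    ConformerState.OPEN: "open",
    ConformerState.ISO_I: "iso_I",
    ConformerState.ISO_II: "iso_II",
    ConformerState.AMBIGUOUS: "ambiguous",
}
_LABEL_STATES = {v: k for k, v in _STATE_LABELS.items()}
_LABEL_STATES.update({"iso_i": ConformerState.ISO_I, "iso_ii": ConformerState.ISO_II})

#: row/column order of transition matrices and population vectors
STATE_ORDER = (ConformerState.OPEN, ConformerState.ISO_I, ConformerState.ISO_II)


@dataclass(frozen=True)
class CoreDistances:
    """The four core marker-pair separations, in Angstrom."""

    d_tt: float
    d_cc: float
    d_ag1: float
    d_ag2: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"d_tt": self.d_tt, "d_cc": self.d_cc, "d_ag1": self.d_ag1, "d_ag2": self.d_ag2}

    def as_array(self) -> np.ndarray:
        return np.array([self.d_tt, self.d_cc, self.d_ag1, self.d_ag2])


@dataclass(frozen=True)
class ClassificationConfig:
    """Distance cutoff separating stacked from open signatures."""

    cutoff: float = 12.0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")


def core_distances(frame: np.ndarray, marker_index_pairs: dict[str, tuple[int, int]]) -> CoreDistances:
    """Euclidean marker-pair distances for one frame of site coordinates."""
    frame = np.asarray(frame, dtype=float)
    d = {}
    for label, (i, j) in marker_index_pairs.items():
        if i >= len(frame) or j >= len(frame):
            raise IndexError(f"marker pair {label} refers to a site missing from the frame")
        d[label] = float(np.linalg.norm(frame[i] - frame[j]))
    return CoreDistances(d_tt=d["TT"], d_cc=d["CC"], d_ag1=d["AG1"], d_ag2=d["AG2"])


def classify_frame(d: CoreDistances, cfg: ClassificationConfig = ClassificationConfig()) -> ConformerState:
    """Assign one frame's core distances to a conformer.

    Both distances of a signature family must fall below the cutoff for
    the family to count (max-aggregation); this is the conservative rule
    -- a core-based criterion can only understate the stacked fraction.
    """
    sig_i = max(d.d_tt, d.d_cc) < cfg.cutoff
    sig_ii = max(d.d_ag1, d.d_ag2) < cfg.cutoff
    if sig_i and sig_ii:
        return ConformerState.AMBIGUOUS
    if sig_i:
        return ConformerState.ISO_I
    if sig_ii:
        return ConformerState.ISO_II
    return ConformerState.OPEN


def _classify_coords(
    coords: np.ndarray, marker_index_pairs: dict[str, tuple[int, int]], cutoff: float
) -> np.ndarray:
    """Vectorized classification of a (n_frames, n_sites, 3) stack."""
    dists = {
        label: np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1)
        for label, (i, j) in marker_index_pairs.items()
    }
    sig_i = np.maximum(dists["TT"], dists["CC"]) < cutoff
    sig_ii = np.maximum(dists["AG1"], dists["AG2"]) < cutoff
    out = np.full(len(coords), int(ConformerState.OPEN), dtype=np.int8)
    out[sig_i & ~sig_ii] = int(ConformerState.ISO_I)
    out[sig_ii & ~sig_i] = int(ConformerState.ISO_II)
    out[sig_i & sig_ii] = int(ConformerState.AMBIGUOUS)
    return out


def classify_trajectory(trajectory, topology: JunctionTopology, cfg: ClassificationConfig = ClassificationConfig()):
    """Per-frame conformer labels for a trajectory; preserves frame times."""
    from .kinetics import StateSeries  # local import to avoid a cycle

    if len(trajectory.coords) == 0:
        raise ValueError("trajectory is empty")
    pairs = core_marker_index_pairs(topology)
    states = _classify_coords(np.asarray(trajectory.coords, dtype=float), pairs, cfg.cutoff)
    return StateSeries(
        times_ns=np.asarray(trajectory.times_ns, dtype=float),
        states=states,
        member_id=trajectory.metadata.get("member_id"),
        initial_state=int(states[0]),
    )


@dataclass
class Histogram:
    bin_edges: np.ndarray
    density: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def mode_count(self, min_prominence: float = 0.05) -> int:
        """Number of local maxima with prominence above a fraction of the peak."""
        from scipy.signal import find_peaks

        peak = self.density.max()
        idx, _ = find_peaks(self.density, prominence=min_prominence * peak)
        # an edge bin can hold a mode that find_peaks misses
        n = len(idx)
        if len(self.density) > 1 and self.density[0] > self.density[1] + min_prominence * peak:
            n += 1
        if len(self.density) > 1 and self.density[-1] > self.density[-2] + min_prominence * peak:
            n += 1
        return n


def distance_distribution(
    trajectories,
    topology: JunctionTopology,
    which: str = "AG",
    bin_width: float = 0.5,
) -> Histogram:
    """Pooled, normalized core-distance distribution over an ensemble.

    ``which='AG'`` pools both R/B marker distances; ``which='TTCC'``
    pools the two X/H distances into a single density.
    """
    pairs = core_marker_index_pairs(topology)
    if which.upper() in ("AG", "D_AG"):
        labels = ("AG1", "AG2")
    elif which.upper() in ("TTCC", "TT_CC", "TTUCC"):
        labels = ("TT", "CC")
    else:
        raise ValueError(f"which must be 'AG' or 'TTCC', got {which!r}")
    values = []
    for traj in trajectories:
        coords = np.asarray(traj.coords, dtype=float)
        for label in labels:
            i, j = pairs[label]
            values.append(np.linalg.norm(coords[:, i, :] - coords[:, j, :], axis=1))
    if not values:
        raise ValueError("no frames supplied")
    pooled = np.concatenate(values)
    lo = 0.0
    hi = float(np.ceil(pooled.max() / bin_width) * bin_width) + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(pooled, bins=edges, density=True)
    return Histogram(bin_edges=edges, density=density)


@dataclass
class PopulationEstimate:
    """Ensemble conformer fractions with member-level uncertainty.

    ``fractions`` is the equal-weight mean of per-member fractions in
    the order (open, iso-I, iso-II, ambiguous); ``se`` is the
    member-to-member standard deviation divided by sqrt(m).
    """

    fractions: np.ndarray
    se: np.ndarray
    per_member: np.ndarray
    n_members: int

    def as_dict(self) -> dict[str, float]:
        keys = ("open", "iso_I", "iso_II", "ambiguous")
        return {k: float(v) for k, v in zip(keys, self.fractions)}


def population_fractions(series_list, equilibration_ns: float = 0.0) -> PopulationEstimate:
    """Equal-weight ensemble populations; an optional initial equilibration
    window is discarded from every member (useful when all members start
    from the same non-stationary state)."""
    if len(series_list) == 0:
        raise ValueError("no members supplied")
    per_member = np.zeros((len(series_list), 4))
    for m, series in enumerate(series_list):
        states = np.asarray(series.states)
        if equilibration_ns > 0:
            states = states[np.asarray(series.times_ns) >= equilibration_ns]
        if states.size == 0:
            raise ValueError(f"member {m} has no frames")
        counts = np.bincount(states, minlength=4)
        per_member[m] = counts / states.size
    fractions = per_member.mean(axis=0)
    if len(series_list) > 1:
        se = per_member.std(axis=0, ddof=1) / np.sqrt(len(series_list))
    else:
        se = np.zeros(4)
    return PopulationEstimate(
        fractions=fractions, se=se, per_member=per_member, n_members=len(series_list)
    )


@dataclass
class TransitionMatrix:
    """Empirical lag-``lag`` transition statistics over (open, iso-I, iso-II).

    ``probabilities[i, j]`` is the fraction of frame pairs that start in
    state i and end in state j after ``lag`` frames, pooled over members
    without crossing member boundaries.  Rows with no observations are
    NaN and listed in ``undefined_rows``.  Frame pairs touching an
    ambiguous frame are excluded and counted in ``n_excluded``.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    lag: int
    n_transitions: int
    n_excluded: int
    undefined_rows: tuple[int, ...] = field(default_factory=tuple)


def transition_matrix(series_list, lag: int = 1) -> TransitionMatrix:
    if lag < 1:
        raise ValueError("lag must be >= 1")
    counts = np.zeros((3, 3), dtype=np.int64)
    excluded = 0
    for series in series_list:
        states = np.asarray(series.states)
        if states.size <= lag:
            raise ValueError("every member must be longer than the lag")
        a, b = states[:-lag], states[lag:]
        ok = (a != ConformerState.AMBIGUOUS) & (b != ConformerState.AMBIGUOUS)
        excluded += int((~ok).sum())
        np.add.at(counts, (a[ok], b[ok]), 1)
    row_sums = counts.sum(axis=1)
    if (row_sums == 0).all():
        raise ValueError("no transitions observed in any row")
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts / row_sums[:, None]
    probs[row_sums == 0] = np.nan
    return TransitionMatrix(
        counts=counts,
        probabilities=probs,
        lag=lag,
        n_transitions=int(row_sums.sum()),
        n_excluded=excluded,
        undefined_rows=tuple(int(i) for i in np.flatnonzero(row_sums == 0)),
    )


def _arm_tip(frame: np.ndarray, topology: JunctionTopology, arm_name: str) -> np.ndarray:
    arm = topology.arms[ARM_ALIASES[arm_name.upper()]]
    a, b = arm.terminal_pair
    return 0.5 * (frame[topology.index_of(a)] + frame[topology.index_of(b)])


def junction_vertex(frame: np.ndarray, topology: JunctionTopology) -> np.ndarray:
    """Centroid of the eight core-marker base sites."""
    idx = [topology.index_of(s) for s in topology.core_markers.values()]
    return np.asarray(frame, dtype=float)[idx].mean(axis=0)


def inter_duplex_angle(
    frame: np.ndarray,
    topology: JunctionTopology,
    arms: tuple[str, str] = ("XR", "HX"),
) -> float:
    """Angle (degrees) between two arms at the junction vertex.

    The vertex is the centroid of the eight core markers; each arm
    direction is the unit vector from the vertex to the centroid of the
    arm's terminal base pair.
    """
    frame = np.asarray(frame, dtype=float)
    v = junction_vertex(frame, topology)
    vecs = []
    for name in arms:
        w = _arm_tip(frame, topology, name) - v
        norm = np.linalg.norm(w)
        if norm < 1e-9:
            raise ValueError(f"degenerate (zero-length) arm vector for arm {name}")
        vecs.append(w / norm)
    cosang = float(np.clip(np.dot(vecs[0], vecs[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class ConformerStructureStats:
    """Per-conformer IDA statistics: mean/SD in degrees plus a histogram."""

    mean: dict[ConformerState, float]
    sd: dict[ConformerState, float]
    n: dict[ConformerState, int]
    histograms: dict[ConformerState, Histogram]


def conformer_structure_stats(
    trajectory,
    states,
    topology: JunctionTopology,
    arms: tuple[str, str] = ("XR", "HX"),
    equilibration_ns: float = 0.0,
    bin_width_deg: float = 2.0,
) -> ConformerStructureStats:
    """IDA mean, SD and histogram per conformer label.

    ``states`` must align one-to-one with the trajectory frames.  An
    optional initial equilibration window is discarded.  States with no
    frames are absent from the result, not reported as zero.
    """
    coords = np.asarray(trajectory.coords, dtype=float)
    labels = np.asarray(states.states)
    if len(labels) != len(coords):
        raise ValueError("state series does not align with trajectory frames")
    keep = np.asarray(trajectory.times_ns, dtype=float) >= equilibration_ns
    coords, labels = coords[keep], labels[keep]
    angles = np.array([inter_duplex_angle(f, topology, arms) for f in coords])
    mean: dict[ConformerState, float] = {}
    sd: dict[ConformerState, float] = {}
    n: dict[ConformerState, int] = {}
    histograms: dict[ConformerState, Histogram] = {}
    for state in ConformerState:
        mask = labels == state
        if not mask.any():
            continue
        vals = angles[mask]
        mean[state] = float(vals.mean())
        sd[state] = float(vals.std(ddof=0))
        n[state] = int(mask.sum())
        edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
        density, edges = np.histogram(vals, bins=edges, density=True)
        histograms[state] = Histogram(bin_edges=edges, density=density)
    return ConformerStructureStats(mean=mean, sd=sd, n=n, histograms=histograms)


def dwell_sequence(states: np.ndarray) -> np.ndarray:
    """Collapse a frame-level state series to its sequence of distinct dwells."""
    states = np.asarray(states)
    if states.size == 0:
        return states
    keep = np.ones(states.size, dtype=bool)
    keep[1:] = states[1:] != states[:-1]
    return states[keep]
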