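"""Continuous-time Markov model of conformer switching.

The three conformers (open, iso-I, iso-II) interconvert with the open
state as the obligatory intermediate: the direct iso-I <-> iso-II rates
are fixed at zero, so at the event level every interconversion passes
through an open dwell.  Trajectory surrogates are produced by exact
Gillespie sampling of the chain (exponential dwell times) discretized
onto a uniform frame grid; apparent direct stacked-to-stacked frame
transitions can then arise only from two jumps falling inside one frame
interval and vanish as the frame spacing goes to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conformers import ConformerState

_O, _I, _II = int(ConformerState.OPEN), int(ConformerState.ISO_I), int(ConformerState.ISO_II)


@dataclass(frozen=True)
class KineticModel:
    """Switching rates in 1/ns; the direct iso-I <-> iso-II rate is zero.

    The defaults give stationary fractions of about 6% open, 36% iso-I
    and 58% iso-II -- the high-salt conformer populations -- with mean
    stacked dwells of a few hundred ns and short-lived open dwells, so
    that a 2000 ns member shows a handful of interconversions.
    """

    k_i_to_o: float = 0.005
    k_o_to_i: float = 0.030
    k_ii_to_o: float = 0.005
    k_o_to_ii: float = 0.29 / 6.0  # = k_ii_to_o * (0.58 / 0.06)

    def __post_init__(self) -> None:
        for name, v in self.rates().items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")

    def rates(self) -> dict[str, float]:
        return {
            "k_i_to_o": self.k_i_to_o,
            "k_o_to_i": self.k_o_to_i,
            "k_ii_to_o": self.k_ii_to_o,
            "k_o_to_ii": self.k_o_to_ii,
        }

    def generator(self) -> np.ndarray:
        """3x3 generator matrix Q in (open, iso-I, iso-II) order; rows sum to 0."""
        q = np.zeros((3, 3))
        q[_O, _I] = self.k_o_to_i
        q[_O, _II] = self.k_o_to_ii
        q[_I, _O] = self.k_i_to_o
        q[_II, _O] = self.k_ii_to_o
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Closed-form stationary distribution (open, iso-I, iso-II).

        The chain is a star around the open state, so detailed balance
        gives pi_I / pi_O = k(O->I)/k(I->O) and likewise for iso-II.
        States whose return rate is zero but entry rate is positive are
        absorbing; the stationary weight then concentrates there.
        """
        w = np.zeros(3)
        w[_O] = 1.0
        for s, k_in, k_out in ((_I, self.k_o_to_i, self.k_i_to_o), (_II, self.k_o_to_ii, self.k_ii_to_o)):
            if k_out > 0:
                w[s] = k_in / k_out
            elif k_in > 0:
                # absorbing stacked state
                w = np.zeros(3)
                w[s] = 1.0
                return w
        return w / w.sum()

    @classmethod
    def from_stationary(
        cls,
        fractions: tuple[float, float, float],
        k_i_to_o: float = 0.005,
        k_ii_to_o: float = 0.005,
    ) -> "KineticModel":
        """Build rates realizing given (open, iso-I, iso-II) stationary fractions."""
        p = np.asarray(fractions, dtype=float)
        if p.min() <= 0 or not np.isclose(p.sum(), 1.0):
            raise ValueError("fractions must be positive and sum to 1")
        return cls(
            k_i_to_o=k_i_to_o,
            k_o_to_i=k_i_to_o * p[_I] / p[_O],
            k_ii_to_o=k_ii_to_o,
            k_o_to_ii=k_ii_to_o * p[_II] / p[_O],
        )


@dataclass
class StateSeries:
    """Frame-level conformer labels on a uniform time grid.

    When produced by :func:`simulate_state_series` the exact event path
    of the underlying chain is kept in ``jump_times``/``jump_states``;
    series obtained by classifying rendered trajectories carry only the
    frame-level labels.
    """

    times_ns: np.ndarray
    states: np.ndarray  # int8 ConformerState codes
    member_id: int | None = None
    initial_state: int | None = None
    jump_times: np.ndarray | None = None
    jump_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.times_ns.shape != self.states.shape:
            raise ValueError("times and states must have the same length")
        if len(self.times_ns) > 1:
            dt = np.diff(self.times_ns)
            if dt.min() <= 0 or not np.allclose(dt, dt[0]):
                raise ValueError("frame times must be uniformly spaced and increasing")

    @property
    def dt_ns(self) -> float:
        if len(self.times_ns) < 2:
            return float("nan")
        return float(self.times_ns[1] - self.times_ns[0])

    def state_labels(self) -> list[str]:
        return [ConformerState(int(s)).label for s in self.states]


def _as_state(state) -> int:
    if isinstance(state, str):
        return int(ConformerState.from_label(state))
    return int(ConformerState(int(state)))


def simulate_state_series(
    model: KineticModel,
    duration_ns: float,
    dt_ns: float = 1.0,
    initial_state=ConformerState.OPEN,
    seed: int | np.random.Generator = 0,
    member_id: int | None = None,
) -> StateSeries:
    """Exact CTMC sample discretized at ``dt_ns``.

    Dwell times are exponential in the state's total exit rate; a state
    with zero exit rate yields a constant series for the remaining
    duration.  Identical seeds give identical series.
    """
    if dt_ns <= 0:
        raise ValueError("dt_ns must be positive")
    if duration_ns < dt_ns:
        raise ValueError("duration must be at least one frame interval")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s0 = _as_state(initial_state)
    if s0 == ConformerState.AMBIGUOUS:
        raise ValueError("initial state must be open, iso_I or iso_II")

    exit_rates = {
        _O: model.k_o_to_i + model.k_o_to_ii,
        _I: model.k_i_to_o,
        _II: model.k_ii_to_o,
    }
    jump_times = [0.0]
    jump_states = [s0]
    t, s = 0.0, s0
    while True:
        rate = exit_rates[s]
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t > duration_ns:
            break
        if s == _O:
            p_i = model.k_o_to_i / rate
            s = _I if rng.random() < p_i else _II
        else:
            s = _O
        jump_times.append(t)
        jump_states.append(s)

    jump_times_a = np.asarray(jump_times)
    jump_states_a = np.asarray(jump_states, dtype=np.int8)
    n_frames = int(np.floor(duration_ns / dt_ns)) + 1
    frame_times = np.arange(n_frames) * dt_ns
    idx = np.searchsorted(jump_times_a, frame_times, side="right") - 1
    return StateSeries(
        times_ns=frame_times,
        states=jump_states_a[idx],
        member_id=member_id,
        initial_state=s0,
        jump_times=jump_times_a,
        jump_states=jump_states_a,
    )


def simulate_state_ensemble(
    model: KineticModel,
    n_members: int,
    duration_ns: float,
    dt_ns: float = 1.0,
    initial_distribution=(1.0, 0.0, 0.0),
    master_seed: int = 0,
) -> list[StateSeries]:
    """Independent CTMC members with seeds spawned from one master seed.

    ``initial_distribution`` is (open, iso-I, iso-II); the two-stage
    protocol of the source analysis corresponds to an all-open first
    stage followed by a stage seeded from the estimated populations.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    p = np.asarray(initial_distribution, dtype=float)
    if p.shape != (3,) or p.min() < 0 or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("initial distribution must be 3 non-negative values summing to 1")
    children = np.random.SeedSequence(master_seed).spawn(n_members)
    out = []
    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        s0 = int(rng.choice(3, p=p / p.sum()))
        out.append(
            simulate_state_series(model, duration_ns, dt_ns, s0, seed=rng, member_id=m)
        )
    return out
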