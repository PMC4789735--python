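"""Idealized conformer geometries for a four-way junction.

Templates are geometric scaffolds, not energy-minimized structures:
straight helical-axis proxies radiate from a common vertex, with the
two sites of each base pair offset laterally from the axis.  Four
conformers are supported:

``open_planar``
    four arms at 90 degrees in a plane (the square open form seen at
    low salt);
``open_tetrahedral``
    arms along tetrahedron vertex directions (109.47 degrees), the
    open sub-state implicated as the transition intermediate at high
    salt;
``iso_I`` / ``iso_II``
    the two antiparallel stacked conformers, built as two pseudo-duplex
    axes crossing at the vertex with the inter-duplex angle between the
    XR and HX arms set to the nominal IDA.

Core-marker placement is what distinguishes the conformers for the
distance classifier: in a stacked template the conformer's signature
marker pairs sit within 5 A of each other while the complementary
family is pushed beyond 18 A, leaving at least a 6 A margin on either
side of the 12 A classification cutoff; in the open templates all four
marker-pair distances are equal (14-19 A, above the cutoff).  The exact
standoffs and lateral offsets are recorded in ``GeometryTemplate.params``.

Stacked templates are calibrated so that the *measured* IDA (core
centroid vertex, terminal-base-pair arm tips) equals the requested
nominal value, absorbing the small bias introduced by the asymmetric
core-marker placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .conformers import ConformerState, inter_duplex_angle
from .topology import ARM_SCHEME, JunctionTopology, Site

TEMPLATE_CONFORMERS = ("open_planar", "open_tetrahedral", "iso_I", "iso_II")

TETRAHEDRAL_ANGLE = float(np.degrees(np.arccos(-1.0 / 3.0)))

DEFAULT_NOMINAL_IDA = {
    "open_planar": 90.0,
    "open_tetrahedral": TETRAHEDRAL_ANGLE,
    # stacked defaults follow the high-salt coarse-grained means:
    # iso-I near 140 deg, iso-II near 90 deg
    "iso_I": 140.0,
    "iso_II": 90.0,
}

#: map from template conformer to the classifier state it should produce
TEMPLATE_STATE = {
    "open_planar": ConformerState.OPEN,
    "open_tetrahedral": ConformerState.OPEN,
    "iso_I": ConformerState.ISO_I,
    "iso_II": ConformerState.ISO_II,
}

# construction constants (Angstrom)
_ARM_OFFSET = 14.0      # axial start of the regular base-pair lattice
_BASE_LAT = 5.0         # lateral offset of base sites from the arm axis
_SUGAR_LAT = 8.0
_PHOSPHATE_LAT = 9.5
_CORE_NEAR_AXIAL = 2.5  # stacked: signature-family marker standoff
_CORE_NEAR_LAT = 1.5
_CORE_FAR_AXIAL = 11.0  # stacked: complementary-family marker standoff
_CORE_FAR_LAT = 9.0
_CORE_OPEN_AXIAL = {"open_planar": 13.0, "open_tetrahedral": 11.5}
_CORE_OPEN_SPLIT = 1.0  # common-direction split of the two core bases per arm


@dataclass
class GeometryTemplate:
    """Site coordinates of one idealized conformer."""

    conformer: str
    coordinates: np.ndarray  # (n_sites, 3), Angstrom
    nominal_ida: float
    rise: float
    params: dict = field(default_factory=dict)

    @property
    def state(self) -> ConformerState:
        return TEMPLATE_STATE[self.conformer]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _arm_frames(conformer: str, axis_angle_deg: float) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Arm name -> (direction u, lateral normal n) for each conformer."""
    z = np.array([0.0, 0.0, 1.0])
    y = np.array([0.0, 1.0, 0.0])
    x = np.array([1.0, 0.0, 0.0])
    if conformer == "open_planar":
        dirs = {"XR": x, "RB": y, "BH": -x, "HX": -y}
        return {a: (u, z.copy()) for a, u in dirs.items()}
    if conformer == "open_tetrahedral":
        t = 1.0 / np.sqrt(3.0)
        dirs = {
            "XR": np.array([t, t, t]),
            "RB": np.array([t, -t, -t]),
            "BH": np.array([-t, t, -t]),
            "HX": np.array([-t, -t, t]),
        }
        return {a: (u, _unit(z - (z @ u) * u)) for a, u in dirs.items()}
    if conformer in ("iso_I", "iso_II"):
        th = np.radians(axis_angle_deg)
        b = np.array([np.sin(th), 0.0, np.cos(th)])
        dirs = {"HX": z, "BH": -z, "XR": b, "RB": -b}
        # y is perpendicular to both axes for every axis angle
        return {a: (u, y.copy()) for a, u in dirs.items()}
    raise ValueError(f"unknown conformer {conformer!r}; expected one of {TEMPLATE_CONFORMERS}")


def _build_coords(topology: JunctionTopology, conformer: str, rise: float, axis_angle_deg: float) -> np.ndarray:
    L = topology.arm_length
    coords = np.zeros((topology.n_sites, 3))
    frames = _arm_frames(conformer, axis_angle_deg)

    for arm_name, (s1, s2) in ARM_SCHEME.items():
        u, n = frames[arm_name]
        for j in range(L):
            s_ax = _ARM_OFFSET + j * rise
            axis_pt = s_ax * u
            for label, nt, side in ((s1, L + j, +1.0), (s2, L - 1 - j, -1.0)):
                coords[topology.site_index[Site(label, nt, "base")]] = axis_pt + side * _BASE_LAT * n
                coords[topology.site_index[Site(label, nt, "sugar")]] = axis_pt + side * _SUGAR_LAT * n
                ph = Site(label, nt, "phosphate")
                if ph in topology.site_index:
                    coords[topology.site_index[ph]] = (
                        (s_ax - 0.5 * rise) * u + side * _PHOSPHATE_LAT * n
                    )

    # override the eight core-marker base sites (the j = 0 bases of each arm)
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    if conformer in ("open_planar", "open_tetrahedral"):
        r0 = _CORE_OPEN_AXIAL[conformer]
        split = _CORE_OPEN_SPLIT * z
        for arm_name, (s1, s2) in ARM_SCHEME.items():
            u, _ = frames[arm_name]
            coords[topology.site_index[Site(s1, L, "base")]] = r0 * u + split
            coords[topology.site_index[Site(s2, L - 1, "base")]] = r0 * u - split
    else:
        near_strands = {"iso_I": ("X", "H"), "iso_II": ("R", "B")}[conformer]
        for arm_name, (s1, s2) in ARM_SCHEME.items():
            u, _ = frames[arm_name]
            for label, nt, role in ((s1, L, "A"), (s2, L - 1, "B")):
                if label in near_strands:
                    lat = _CORE_NEAR_LAT if role == "B" else -_CORE_NEAR_LAT
                    pos = _CORE_NEAR_AXIAL * u + lat * y
                else:
                    lat = _CORE_FAR_LAT if label in ("X", "R") else -_CORE_FAR_LAT
                    pos = _CORE_FAR_AXIAL * u + lat * y
                coords[topology.site_index[Site(label, nt, "base")]] = pos
    return coords


def idealized_geometry(
    topology: JunctionTopology,
    conformer: str,
    rise: float = 3.4,
    nominal_ida: float | None = None,
) -> GeometryTemplate:
    """Build the idealized scaffold of one conformer.

    Parameters
    ----------
    topology:
        Junction topology the coordinates must cover.
    conformer:
        One of ``open_planar``, ``open_tetrahedral``, ``iso_I``,
        ``iso_II`` (hyphen/case variants accepted).
    rise:
        Axial rise per base pair along each arm, Angstrom.
    nominal_ida:
        Requested XR/HX inter-duplex angle in degrees, only meaningful
        for the stacked conformers (the open geometries fix their own
        angle).  Defaults per conformer.
    """
    key = conformer.replace("-", "_")
    if key in ("open", "open_square"):
        key = "open_planar"
    if key.lower() in ("iso_i", "isoi"):
        key = "iso_I"
    if key.lower() in ("iso_ii", "isoii"):
        key = "iso_II"
    if key not in TEMPLATE_CONFORMERS:
        raise ValueError(f"unknown conformer {conformer!r}; expected one of {TEMPLATE_CONFORMERS}")
    if rise <= 0:
        raise ValueError("rise must be positive")
    if nominal_ida is None:
        nominal_ida = DEFAULT_NOMINAL_IDA[key]
    if not 0.0 < nominal_ida <= 180.0:
        raise ValueError("nominal IDA must lie in (0, 180] degrees")

    params = {
        "arm_offset": _ARM_OFFSET,
        "base_lateral": _BASE_LAT,
        "sugar_lateral": _SUGAR_LAT,
        "phosphate_lateral": _PHOSPHATE_LAT,
    }
    if key.startswith("open"):
        coords = _build_coords(topology, key, rise, axis_angle_deg=nominal_ida)
        measured = inter_duplex_angle(coords, topology)
        params.update(core_axial=_CORE_OPEN_AXIAL[key], core_split=_CORE_OPEN_SPLIT)
        return GeometryTemplate(key, coords, nominal_ida=measured, rise=rise, params=params)

    # stacked: calibrate the inter-axis angle so the measured IDA matches
    def mismatch(axis_angle: float) -> float:
        c = _build_coords(topology, key, rise, axis_angle)
        return inter_duplex_angle(c, topology) - nominal_ida

    lo, hi = 0.5, 179.9
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo * f_hi > 0:
        raise ValueError(f"nominal IDA {nominal_ida} deg is outside the constructible range")
    axis_angle = brentq(mismatch, lo, hi, xtol=1e-10)
    coords = _build_coords(topology, key, rise, axis_angle)
    params.update(
        axis_angle=axis_angle,
        core_near_axial=_CORE_NEAR_AXIAL,
        core_near_lateral=_CORE_NEAR_LAT,
        core_far_axial=_CORE_FAR_AXIAL,
        core_far_lateral=_CORE_FAR_LAT,
    )
    return GeometryTemplate(key, coords, nominal_ida=nominal_ida, rise=rise, params=params)


def default_templates(
    topology: JunctionTopology,
    rise: float = 3.4,
    ida: dict[str, float] | None = None,
    open_variant: str = "open_tetrahedral",
) -> dict[ConformerState, GeometryTemplate]:
    """One template per classifier state, keyed by :class:`ConformerState`.

    The open state is represented by ``open_variant`` (tetrahedral by
    default, matching the open sub-state that dominates at high salt).
    """
    ida = ida or {}
    return {
        ConformerState.OPEN: idealized_geometry(
            topology, open_variant, rise, ida.get(open_variant)
        ),
        ConformerState.ISO_I: idealized_geometry(topology, "iso_I", rise, ida.get("iso_I")),
        ConformerState.ISO_II: idealized_geometry(topology, "iso_II", rise, ida.get("iso_II")),
    }
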