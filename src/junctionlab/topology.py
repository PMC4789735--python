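"""Three-site-per-nucleotide representation of a DNA four-way junction.

A four-way (Holliday) junction is built from four strands, labelled X, R,
B and H after the Lilley convention, each of length ``2 * arm_length``.
Adjacent strand halves pair into four double-helical arms (XR, RB, BH,
HX) that meet at the branch point.  Every nucleotide is represented by
three coarse-grained sites -- sugar, phosphate and base -- except that
5' termini carry no phosphate, so a strand of ``n`` nucleotides
contributes ``3 n - 1`` sites.

The eight bases immediately flanking the branch point (the innermost
nucleotide of each strand half) are the *core markers*; the distances
between selected non-complementary marker pairs distinguish the stacked
conformers from the open one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

STRAND_LABELS = ("X", "R", "B", "H")

#: arm name -> (strand whose 3' half forms the arm, strand whose 5' half does)
ARM_SCHEME = {
    "XR": ("X", "R"),
    "RB": ("R", "B"),
    "BH": ("B", "H"),
    "HX": ("H", "X"),
}

ARM_ALIASES = {
    "XR": "XR", "RX": "XR",
    "RB": "RB", "BR": "RB",
    "BH": "BH", "HB": "BH",
    "HX": "HX", "XH": "HX",
    # the arm pair used for the inter-duplex angle is often written "RH"
    # in the FRET literature; it maps onto the HX arm of this cycle
    "RH": "HX",
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SITE_KINDS = ("phosphate", "sugar", "base")
SITE_TAGS = {"phosphate": "P", "sugar": "S", "base": "B"}


class Site(NamedTuple):
    """One coarse-grained site: (strand label, 0-based nucleotide, kind)."""

    strand: str
    nucleotide: int
    kind: str


@dataclass(frozen=True)
class Strand:
    label: str
    sequence: str

    def __post_init__(self) -> None:
        if self.label not in STRAND_LABELS:
            raise ValueError(f"strand label must be one of {STRAND_LABELS}, got {self.label!r}")
        if len(self.sequence) < 2:
            raise ValueError(f"strand {self.label}: length must be >= 2")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"strand {self.label}: invalid bases {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_sites(self) -> int:
        # no 5'-terminal phosphate
        return 3 * self.length - 1


@dataclass(frozen=True)
class Arm:
    """One double-helical arm: two flanking strand labels and its base pairs.

    ``pairs[0]`` is the innermost base pair (at the branch point),
    ``pairs[-1]`` the terminal one.
    """

    name: str
    strand_3p: str  # strand whose 3' half forms the arm
    strand_5p: str
    pairs: tuple[tuple[Site, Site], ...]

    @property
    def terminal_pair(self) -> tuple[Site, Site]:
        return self.pairs[-1]


@dataclass
class JunctionTopology:
    strands: dict[str, Strand]
    arm_length: int
    sites: list[Site]
    site_index: dict[Site, int]
    arms: dict[str, Arm]
    base_pairs: list[tuple[Site, Site]]
    #: (strand label, half) -> base Site; half 0 = innermost of 5' half
    #: (nucleotide L-1), half 1 = innermost of 3' half (nucleotide L)
    core_markers: dict[tuple[str, int], Site] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def index_of(self, site: Site) -> int:
        try:
            return self.site_index[site]
        except KeyError:
            raise KeyError(f"site {site} not in topology") from None

    def base_pair_indices(self) -> np.ndarray:
        """(n_pairs, 2) array of site indices, one row per base pair."""
        return np.array(
            [(self.site_index[a], self.site_index[b]) for a, b in self.base_pairs],
            dtype=np.intp,
        )

    def strand_pair_indices(self, label: str) -> np.ndarray:
        """Index pairs of every base pair involving strand ``label``."""
        if label not in self.strands:
            raise KeyError(f"unknown strand {label!r}; have {sorted(self.strands)}")
        rows = [
            (self.site_index[a], self.site_index[b])
            for a, b in self.base_pairs
            if a.strand == label or b.strand == label
        ]
        return np.array(rows, dtype=np.intp)

    def partner(self, site: Site) -> Site:
        """Watson-Crick partner of a base site."""
        for a, b in self.base_pairs:
            if a == site:
                return b
            if b == site:
                return a
        raise KeyError(f"{site} is not a paired base site")


def complement(base: str) -> str:
    return COMPLEMENT[base]


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _strand_sites(strand: Strand) -> list[Site]:
    sites: list[Site] = []
    for i in range(strand.length):
        if i > 0:
            sites.append(Site(strand.label, i, "phosphate"))
        sites.append(Site(strand.label, i, "sugar"))
        sites.append(Site(strand.label, i, "base"))
    return sites


def build_topology(
    sequences: dict[str, str],
    arm_length: int,
    core_marker_indices: dict[str, tuple[int, int]] | None = None,
) -> JunctionTopology:
    """Assemble the junction topology from four labelled sequences.

    Parameters
    ----------
    sequences:
        Mapping from strand label (X, R, B, H) to a base string of length
        ``2 * arm_length``, written 5' to 3'.
    arm_length:
        Number of base pairs per arm.
    core_marker_indices:
        Optional override of the two core-marker nucleotide indices per
        strand (defaults to the innermost nucleotide of each half,
        ``(arm_length - 1, arm_length)``).

    Raises
    ------
    ValueError
        On a length mismatch or the first non-complementary position of
        any arm.
    """
    if set(sequences) != set(STRAND_LABELS):
        raise ValueError(f"need exactly strands {STRAND_LABELS}, got {sorted(sequences)}")
    if arm_length < 1:
        raise ValueError("arm_length must be >= 1")
    L = arm_length
    strands = {}
    for label in STRAND_LABELS:
        seq = sequences[label].upper()
        if len(seq) != 2 * L:
            raise ValueError(
                f"strand {label}: length {len(seq)} != 2 * arm_length = {2 * L}"
            )
        strands[label] = Strand(label, seq)

    # complementarity of each arm: 3' half of s1 against 5' half of s2,
    # antiparallel: s1[L + j] pairs s2[L - 1 - j]
    for arm_name, (s1, s2) in ARM_SCHEME.items():
        q1, q2 = strands[s1].sequence, strands[s2].sequence
        for j in range(L):
            b1, b2 = q1[L + j], q2[L - 1 - j]
            if COMPLEMENT[b1] != b2:
                raise ValueError(
                    f"arm {arm_name}: non-complementary pair at arm position {j}: "
                    f"{s1}[{L + j}]={b1} vs {s2}[{L - 1 - j}]={b2}"
                )

    sites: list[Site] = []
    for label in STRAND_LABELS:
        sites.extend(_strand_sites(strands[label]))
    site_index = {s: i for i, s in enumerate(sites)}

    arms: dict[str, Arm] = {}
    base_pairs: list[tuple[Site, Site]] = []
    for arm_name, (s1, s2) in ARM_SCHEME.items():
        pairs = tuple(
            (Site(s1, L + j, "base"), Site(s2, L - 1 - j, "base")) for j in range(L)
        )
        arms[arm_name] = Arm(arm_name, s1, s2, pairs)
        base_pairs.extend(pairs)

    if core_marker_indices is None:
        core_marker_indices = {label: (L - 1, L) for label in STRAND_LABELS}
    core_markers: dict[tuple[str, int], Site] = {}
    for label in STRAND_LABELS:
        i5, i3 = core_marker_indices[label]
        for half, idx in ((0, i5), (1, i3)):
            site = Site(label, idx, "base")
            if site not in site_index:
                raise ValueError(f"core marker {site} does not exist")
            core_markers[(label, half)] = site

    return JunctionTopology(
        strands=strands,
        arm_length=L,
        sites=sites,
        site_index=site_index,
        arms=arms,
        base_pairs=base_pairs,
        core_markers=core_markers,
    )


def core_marker_pairs(topology: JunctionTopology) -> dict[str, tuple[Site, Site]]:
    """The four labelled non-complementary marker pairs at the junction core.

    ``TT`` and ``CC`` span strands X and H; ``AG1`` and ``AG2`` span the
    R and B strands.  The labels are strand-role names inherited from
    the J3 junction core; classification uses only the geometry, so the
    actual base identities at the marker slots are not constrained.
    """
    cm = topology.core_markers
    if not cm:
        raise ValueError("topology lacks core-marker annotation")
    return {
        "TT": (cm[("X", 0)], cm[("H", 0)]),
        "CC": (cm[("X", 1)], cm[("H", 1)]),
        "AG1": (cm[("R", 0)], cm[("B", 0)]),
        "AG2": (cm[("R", 1)], cm[("B", 1)]),
    }


def core_marker_index_pairs(topology: JunctionTopology) -> dict[str, tuple[int, int]]:
    """Site-index version of :func:`core_marker_pairs`."""
    return {
        label: (topology.site_index[a], topology.site_index[b])
        for label, (a, b) in core_marker_pairs(topology).items()
    }


def synthetic_junction_sequences(
    arm_length: int = 17, seed: int = 20160314
) -> dict[str, str]:
    """Four mutually complementary strand sequences for a J34-sized junction.

    The published J34 sequence is only available as a figure, so this is
    a synthetic stand-in: the 3' half of each strand is drawn from a
    seeded RNG and the 5' halves are the reverse complements dictated by
    the arm pairing scheme.  The statistical analyses downstream depend
    only on the topology, never on base identity.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    halves3 = {
        label: "".join(rng.choice(bases, size=arm_length))
        for label in STRAND_LABELS
    }
    # arm s1-s2 pairs s1's 3' half with s2's 5' half
    halves5 = {}
    for _arm, (s1, s2) in ARM_SCHEME.items():
        halves5[s2] = reverse_complement(halves3[s1])
    return {label: halves5[label] + halves3[label] for label in STRAND_LABELS}


def site_species(topology: JunctionTopology) -> list[str]:
    """Per-site element tag (S/P/B) in topology site order."""
    return [SITE_TAGS[s.kind] for s in topology.sites]
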