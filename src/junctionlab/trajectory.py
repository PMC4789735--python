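"""In-memory trajectory container shared by the generators and the I/O layer."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Time-ordered site coordinates with run metadata.

    ``coords`` has shape (n_frames, n_sites, 3) in Angstrom; metadata
    records at least the temperature (K), salt (mM), seed and member id
    when produced by the synthetic generators.
    """

    coords: np.ndarray
    times_ns: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_sites, 3)")
        if len(self.times_ns) != len(self.coords):
            raise ValueError("times and frames must have the same length")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]
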