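"""File I/O: extended-XYZ and LAMMPS-dump trajectories, CSV curves,
JSON reports, junction/run configuration, and output provenance.

Extended-XYZ is the native trajectory format (human readable, site
tags S/P/B, per-frame ``key=value`` metadata on the comment line);
LAMMPS dump files are read-only support for trajectories produced by
MD engines and go through the MDAnalysis reader.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import StateSeries
from .melting import AbsorbanceCurve, MeltingCurve
from .topology import JunctionTopology, build_topology, site_species
from .trajectory import Trajectory

_XYZ_FMT = "%.6f"


def _format_comment(meta: dict) -> str:
    parts = ["Properties=species:S:1:pos:R:3"]
    for k, v in meta.items():
        if v is None:
            continue
        if isinstance(v, str) and (" " in v or "=" in v):
            parts.append(f'{k}="{v}"')
        else:
            parts.append(f"{k}={v}")
    return " ".join(parts)


def _parse_comment(line: str) -> dict:
    meta: dict = {}
    for token in line.split():
        if "=" not in token:
            continue
        k, v = token.split("=", 1)
        v = v.strip('"')
        try:
            meta[k] = int(v)
        except ValueError:
            try:
                meta[k] = float(v)
            except ValueError:
                meta[k] = v
    return meta


def write_trajectory_xyz(path, trajectory: Trajectory, topology: JunctionTopology | None = None) -> None:
    """Write all frames as extended-XYZ with per-frame metadata."""
    species = site_species(topology) if topology is not None else ["B"] * trajectory.n_sites
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            meta = dict(trajectory.metadata)
            meta["time_ns"] = float(trajectory.times_ns[f])
            fh.write(f"{trajectory.n_sites}\n{_format_comment(meta)}\n")
            for tag, xyz in zip(species, trajectory.coords[f]):
                fh.write(f"{tag} " + " ".join(_XYZ_FMT % x for x in xyz) + "\n")


def write_template_xyz(path, template, topology: JunctionTopology) -> None:
    """Export one geometry template as a single-frame extended-XYZ file."""
    traj = Trajectory(
        coords=template.coordinates[None],
        times_ns=np.array([0.0]),
        metadata={"conformer": template.conformer, "nominal_ida": template.nominal_ida},
    )
    write_trajectory_xyz(path, traj, topology)


def read_trajectory_xyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory; a truncated final frame is dropped."""
    lines = Path(path).read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"empty trajectory file: {path}")
    frames, times, species, metas = [], [], None, []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected an atom count at line {i + 1}") from exc
        if i + 2 + n > len(lines):
            warnings.warn(f"{path}: dropping truncated final frame", RuntimeWarning, stacklevel=2)
            break
        meta = _parse_comment(lines[i + 1])
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            warnings.warn(f"{path}: dropping truncated final frame", RuntimeWarning, stacklevel=2)
            break
        tags, xyz = [], np.empty((n, 3))
        ok = True
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                ok = False
                break
            tags.append(parts[0])
            xyz[j] = [float(p) for p in parts[1:4]]
        if not ok:
            warnings.warn(f"{path}: dropping truncated final frame", RuntimeWarning, stacklevel=2)
            break
        if species is None:
            species = tags
        if len(tags) != len(species):
            raise ValueError(f"{path}: site count changes at frame {len(frames)}")
        frames.append(xyz)
        times.append(float(meta.get("time_ns", len(frames) - 1)))
        metas.append(meta)
        i += 2 + n
    if not frames:
        raise ValueError(f"no complete frames in {path}")
    meta0 = dict(metas[0])
    meta0.pop("time_ns", None)
    meta0["species"] = species
    return Trajectory(coords=np.array(frames), times_ns=np.array(times), metadata=meta0)


def read_trajectory_lammps(path, length_scale: float = 1.0, dt_ns: float = 1.0) -> Trajectory:
    """Read a LAMMPS dump via MDAnalysis; frames re-sorted by atom id.

    ``length_scale`` converts dump length units to Angstrom; frame
    times are ``dt_ns`` times the frame index.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="LAMMPSDUMP")
        order = np.argsort(u.atoms.ids)
        frames = []
        for _ts in u.trajectory:
            frames.append(u.atoms.positions[order].astype(float) * length_scale)
    coords = np.array(frames)
    return Trajectory(
        coords=coords,
        times_ns=np.arange(len(coords)) * dt_ns,
        metadata={"source": str(path), "dialect": "lammps-dump"},
    )


def read_trajectory(
    path,
    dialect: str = "auto",
    topology: JunctionTopology | None = None,
    length_scale: float = 1.0,
    dt_ns: float = 1.0,
) -> Trajectory:
    """Read a trajectory, sniffing the dialect from the header if needed.

    If a topology is supplied the per-frame site count is checked
    against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        head = ""
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    head = line.strip()
                    break
        if head.startswith("ITEM:"):
            dialect = "lammps-dump"
        else:
            dialect = "xyz"
    if dialect in ("xyz", "extxyz", "extended-xyz"):
        traj = read_trajectory_xyz(path)
    elif dialect in ("lammps-dump", "lammps"):
        traj = read_trajectory_lammps(path, length_scale=length_scale, dt_ns=dt_ns)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if topology is not None and traj.n_sites != topology.n_sites:
        raise ValueError(
            f"{path}: {traj.n_sites} sites per frame but topology has {topology.n_sites}"
        )
    return traj


# --- curves and series -----------------------------------------------------


def write_melting_csv(path, curve: MeltingCurve) -> None:
    df = pd.DataFrame({"temperature_K": curve.temperature, "alpha": curve.alpha})
    if curve.n_frames is not None:
        df["n_frames"] = curve.n_frames
    df.to_csv(path, index=False)


def read_melting_csv(path, c_total: float = 6.0e-7) -> MeltingCurve:
    df = pd.read_csv(path)
    return MeltingCurve(
        temperature=df["temperature_K"].to_numpy(),
        alpha=df["alpha"].to_numpy(),
        c_total=c_total,
        n_frames=df["n_frames"].to_numpy() if "n_frames" in df else None,
    )


def write_absorbance_csv(path, curve: AbsorbanceCurve) -> None:
    pd.DataFrame({"temperature_K": curve.temperature, "A260": curve.absorbance}).to_csv(
        path, index=False
    )


def read_absorbance_csv(path, lower_window=None, upper_window=None) -> AbsorbanceCurve:
    """Read an absorbance melt; a ``temperature_C`` column is converted to K."""
    df = pd.read_csv(path)
    if "temperature_K" in df:
        t = df["temperature_K"].to_numpy(dtype=float)
    elif "temperature_C" in df:
        t = df["temperature_C"].to_numpy(dtype=float) + 273.15
    else:
        raise ValueError("absorbance CSV needs a temperature_K or temperature_C column")
    a = df["A260"].to_numpy(dtype=float)
    span = t[-1] - t[0]
    if lower_window is None:
        lower_window = (float(t[0]), float(t[0] + 0.15 * span))
    if upper_window is None:
        upper_window = (float(t[-1] - 0.15 * span), float(t[-1]))
    return AbsorbanceCurve(t, a, tuple(lower_window), tuple(upper_window))


def write_state_series_csv(path, series: StateSeries) -> None:
    pd.DataFrame({"time_ns": series.times_ns, "state": series.state_labels()}).to_csv(
        path, index=False
    )


def read_state_series_csv(path) -> StateSeries:
    from .conformers import ConformerState

    df = pd.read_csv(path)
    states = np.array([int(ConformerState.from_label(s)) for s in df["state"]], dtype=np.int8)
    return StateSeries(times_ns=df["time_ns"].to_numpy(dtype=float), states=states)


def write_histogram_csv(path, histogram) -> None:
    pd.DataFrame(
        {
            "bin_left": histogram.bin_edges[:-1],
            "bin_right": histogram.bin_edges[1:],
            "density": histogram.density,
        }
    ).to_csv(path, index=False)


# --- configuration and provenance ------------------------------------------


def load_junction(path) -> JunctionTopology:
    """Build a topology from a YAML junction definition.

    Schema: ``arm_length``, ``strands: {X: seq, R: seq, B: seq, H: seq}``
    and optional ``core_markers: {X: [i, j], ...}``.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    core = cfg.get("core_markers")
    if core is not None:
        core = {k: tuple(v) for k, v in core.items()}
    return build_topology(cfg["strands"], int(cfg["arm_length"]), core)


def load_run_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_json(path, payload: dict, config: dict | None = None, seed: int | None = None) -> None:
    """Write a JSON report with an embedded provenance block."""
    out = dict(payload)
    out["provenance"] = {
        "package": "junctionlab",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
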