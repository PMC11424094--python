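"""File I/O: trajectories (XYZ, LAMMPS-dump text, HDF5), curves (CSV),
measurements (JSON), parameter/config files (TOML/YAML/JSON), and
provenance records."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any

import numpy as np

from .continuum import RecoveryCurve
from .simulate import Trajectory

__all__ = [
    "write_xyz",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_trajectory_h5",
    "read_trajectory_h5",
    "write_field_npz",
    "read_field_npz",
    "write_curve_csv",
    "read_curve_csv",
    "load_config",
    "config_hash",
    "write_provenance",
]

_TYPE_NAMES = {0: "A", 1: "B"}


def write_xyz(path: str | Path, traj: Trajectory) -> None:
    """Plain XYZ with element = sticker type; wrapped coordinates."""
    with open(path, "w") as fh:
        for fidx in range(traj.n_frames):
            pos = traj.positions[fidx]
            pos = pos - np.floor(pos / traj.box) * traj.box
            fh.write(f"{len(pos)}\n")
            fh.write(f"t={traj.times[fidx]:.6g}\n")
            for i, (x, y, z) in enumerate(pos):
                fh.write(
                    f"{_TYPE_NAMES[int(traj.types[i])]} {x:.5f} {y:.5f} {z:.5f}\n"
                )


def write_lammps_dump(path: str | Path, traj: Trajectory) -> None:
    """LAMMPS-dump-style text: id type mol x y z, atoms sorted by id."""
    with open(path, "w") as fh:
        for fidx in range(traj.n_frames):
            pos = traj.positions[fidx]
            pos = pos - np.floor(pos / traj.box) * traj.box
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{traj.times[fidx]:.10g}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(pos)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for k in range(3):
                fh.write(f"0.0 {traj.box[k]:.10g}\n")
            fh.write("ITEM: ATOMS id type mol x y z\n")
            for i in range(len(pos)):
                fh.write(
                    f"{i + 1} {int(traj.types[i]) + 1} {int(traj.mol[i]) + 1} "
                    f"{pos[i, 0]:.6f} {pos[i, 1]:.6f} {pos[i, 2]:.6f}\n"
                )


def read_lammps_dump(path: str | Path) -> Trajectory:
    """Read a dump file written by :func:`write_lammps_dump`.

    Raises a parse error with the offending line number on malformed
    input.  Chain bonds are reconstructed from consecutive atom ids
    sharing a molecule.
    """
    times, frames = [], []
    types = mol = box = None
    lines = Path(path).read_text().splitlines()
    i = 0
    try:
        while i < len(lines):
            if lines[i].strip() != "ITEM: TIMESTEP":
                raise ValueError("expected ITEM: TIMESTEP")
            times.append(float(lines[i + 1]))
            if lines[i + 2].strip() != "ITEM: NUMBER OF ATOMS":
                raise ValueError("expected ITEM: NUMBER OF ATOMS")
            n = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise ValueError("expected ITEM: BOX BOUNDS")
            b = []
            for k in range(3):
                lo, hi = map(float, lines[i + 5 + k].split())
                b.append(hi - lo)
            box = np.asarray(b)
            if not lines[i + 8].startswith("ITEM: ATOMS"):
                raise ValueError("expected ITEM: ATOMS")
            pos = np.empty((n, 3))
            tp = np.empty(n, dtype=np.int8)
            ml = np.empty(n, dtype=np.int64)
            for k in range(n):
                parts = lines[i + 9 + k].split()
                idx = int(parts[0]) - 1
                tp[idx] = int(parts[1]) - 1
                ml[idx] = int(parts[2]) - 1
                pos[idx] = [float(parts[3]), float(parts[4]), float(parts[5])]
            frames.append(pos)
            types, mol = tp, ml
            i += 9 + n
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed dump file near line {i + 1}: {exc}") from exc
    bonds = []
    for a in range(len(mol) - 1):
        if mol[a] == mol[a + 1]:
            bonds.append((a, a + 1))
    return Trajectory(
        times=np.asarray(times),
        positions=np.asarray(frames),
        types=types,
        mol=mol,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        box=box,
    )


def write_trajectory_h5(path: str | Path, traj: Trajectory) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("positions", data=traj.positions)
        h5.create_dataset("types", data=traj.types)
        h5.create_dataset("mol", data=traj.mol)
        h5.create_dataset("bonds", data=traj.bonds)
        h5.create_dataset("box", data=traj.box)
        h5.attrs["sequence"] = traj.sequence
        if traj.potential_energy is not None:
            h5.create_dataset("potential_energy", data=traj.potential_energy)
        if traj.kinetic_energy is not None:
            h5.create_dataset("kinetic_energy", data=traj.kinetic_energy)


def read_trajectory_h5(path: str | Path) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        return Trajectory(
            times=h5["times"][:],
            positions=h5["positions"][:],
            types=h5["types"][:],
            mol=h5["mol"][:],
            bonds=h5["bonds"][:],
            box=h5["box"][:],
            sequence=str(h5.attrs.get("sequence", "")),
            potential_energy=(
                h5["potential_energy"][:] if "potential_energy" in h5 else None
            ),
            kinetic_energy=(
                h5["kinetic_energy"][:] if "kinetic_energy" in h5 else None
            ),
        )


def write_field_npz(path: str | Path, field) -> None:
    """Save a radial concentration field c(r, t) as NPZ."""
    np.savez(
        path,
        r_grid=field.r_grid,
        times=field.times,
        values=field.values,
        faces=field.faces,
        domain=np.array(field.domain),
    )


def read_field_npz(path: str | Path):
    from .continuum import RadialField

    with np.load(path, allow_pickle=False) as z:
        return RadialField(
            r_grid=z["r_grid"],
            times=z["times"],
            values=z["values"],
            faces=z["faces"],
            domain=str(z["domain"]),
            params=None,
        )


def write_curve_csv(
    path: str | Path, curve: RecoveryCurve, *, meta: dict[str, Any] | None = None
) -> None:
    """CSV with '# key: value' metadata header followed by time,f rows."""
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        if curve.fit_A is not None:
            fh.write(f"# fit_A: {curve.fit_A!r}\n")
        if curve.fit_tau is not None:
            fh.write(f"# fit_tau: {curve.fit_tau!r}\n")
        fh.write("time,f\n")
        for t, f in zip(curve.times, curve.f):
            fh.write(f"{t:.10g},{f:.10g}\n")


def read_curve_csv(path: str | Path) -> RecoveryCurve:
    meta: dict[str, str] = {}
    times, fs = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif line.startswith("time"):
            continue
        else:
            try:
                t, f = line.split(",")
                times.append(float(t))
                fs.append(float(f))
            except ValueError as exc:
                raise ValueError(f"malformed CSV at line {lineno}: {line!r}") from exc
    curve = RecoveryCurve(np.asarray(times), np.asarray(fs))
    if "fit_A" in meta:
        curve.fit_A = float(meta["fit_A"])
    if "fit_tau" in meta:
        curve.fit_tau = float(meta["fit_tau"])
    return curve


def load_config(path: str | Path) -> dict[str, Any]:
    """Parse a TOML / YAML / JSON config by file extension."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".toml":
        import tomllib

        return tomllib.loads(text)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    if path.suffix == ".json":
        return json.loads(text)
    raise ValueError(f"unrecognized config format: {path.suffix}")


def _canonical(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _canonical(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_hash(config: dict[str, Any]) -> str:
    """Stable hash of a config dict: changes iff any parameter changes."""
    payload = json.dumps(_canonical(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(
    out_path: str | Path, config: dict[str, Any], seed: int | None = None
) -> Path:
    """Write a provenance sidecar (config, seed, package version) next to
    an output file."""
    from . import __version__

    side = Path(str(out_path) + ".provenance.json")
    side.write_text(
        json.dumps(
            {
                "config": _canonical(config),
                "config_hash": config_hash(config),
                "seed": seed,
                "package_version": __version__,
            },
            indent=2,
        )
    )
    return side
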