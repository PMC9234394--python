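"""Structure and trajectory I/O plus superposition RMSD.

Single structures are read through MDAnalysis (GRO in nm, PDB in Angstrom);
only the Calpha positions are kept, matched positionally to the distogram
(first CA <-> residue 1).  Multi-frame input comes either from multi-MODEL
PDB files or from a plain XYZ dialect with coordinates in nm and an optional
``t= <ps>`` tag on the comment line.  All coordinates are nm internally.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cv import Conformation

__all__ = [
    "Trajectory", "read_calpha", "calpha_serials", "read_trajectory",
    "kabsch_rmsd", "write_gro", "write_pdb", "write_xyz",
]


@dataclasses.dataclass
class Trajectory:
    """Ordered frames of one system with strictly increasing times (ps)."""

    frames: list[Conformation]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.frames = list(self.frames)
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n
        if any(f.n != n for f in self.frames):
            raise ValueError("all frames must share the same residue count")
        times = np.asarray(self.times, dtype=float)
        if times.shape != (len(self.frames),):
            raise ValueError("times length must equal frame count")
        if len(times) > 1 and not (np.diff(times) > 0).all():
            raise ValueError("frame times must be strictly increasing")
        self.times = times

    def __len__(self) -> int:
        return len(self.frames)


def _load_universe(path: Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def _infer_format(path: Path, fmt: str | None) -> str:
    fmt = (fmt or path.suffix.lstrip(".")).upper()
    if not fmt:
        raise ValueError(f"cannot infer format of {path}")
    return fmt


def _calpha_group(universe):
    """One CA atom per residue, in file order; errors name the residue."""
    cas = []
    for res in universe.residues:
        ca = res.atoms[res.atoms.names == "CA"]
        if len(ca) == 0:
            raise ValueError(f"residue {res.resname}{res.resid} has no CA atom")
        if len(ca) > 1:
            warnings.warn(
                f"residue {res.resname}{res.resid} has {len(ca)} CA records; "
                "taking the first",
                stacklevel=3,
            )
        cas.append(ca[0])
    import MDAnalysis as mda

    return mda.AtomGroup(cas)


def read_calpha(path, fmt: str | None = None) -> Conformation:
    """Read the Calpha trace of a GRO or PDB file as a :class:`Conformation`.

    MDAnalysis reports positions in Angstrom regardless of the on-disk unit;
    they are converted to nm here.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in {"GRO", "PDB"}:
        raise ValueError(f"unsupported structure format {fmt!r} (use GRO or PDB)")
    u = _load_universe(path)
    coords = _calpha_group(u).positions / 10.0
    return Conformation(coords)


def calpha_serials(path, fmt: str | None = None) -> tuple[int, ...]:
    """Atom serial numbers (as written in the file) of the CA trace."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt not in {"GRO", "PDB"}:
        raise ValueError(f"unsupported structure format {fmt!r} (use GRO or PDB)")
    u = _load_universe(path)
    return tuple(int(i) for i in _calpha_group(u).ids)


def _read_xyz(path: Path, dt: float) -> Trajectory:
    frames: list[Conformation] = []
    times: list[float] = []
    lines = path.read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected an atom count at line {pos + 1}") from exc
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        t = None
        if "t=" in comment:
            t = float(comment.split("t=")[1].split()[0])
        body = lines[pos + 2 : pos + 2 + natoms]
        if len(body) < natoms:
            raise ValueError(f"{path}: truncated frame at line {pos + 1}")
        coords = []
        for ln in body:
            parts = ln.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}: malformed XYZ atom line {ln!r}")
            coords.append([float(x) for x in parts[-3:]])
        coords = np.asarray(coords)
        if not np.isfinite(coords).all():
            raise ValueError(f"{path}: non-finite coordinate in frame {len(frames)}")
        frames.append(Conformation(coords))
        times.append(t)
        pos += 2 + natoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    if any(t is None for t in times):
        times = [k * dt for k in range(len(frames))]
    return Trajectory(frames, np.asarray(times, dtype=float))


def read_trajectory(path, fmt: str | None = None, dt: float = 1.0) -> Trajectory:
    """Read a multi-frame PDB (CA trace) or XYZ (all points, nm) trajectory.

    ``dt`` (ps) spaces the frames when the file itself carries no times.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "XYZ":
        return _read_xyz(path, dt)
    if fmt != "PDB":
        raise ValueError(f"unsupported trajectory format {fmt!r} (use PDB or XYZ)")
    u = _load_universe(path)
    group = _calpha_group(u)
    frames, times = [], []
    for k, _ in enumerate(u.trajectory):
        coords = group.positions / 10.0
        if not np.isfinite(coords).all():
            raise ValueError(f"{path}: non-finite coordinate in frame {k}")
        frames.append(Conformation(coords))
        times.append(k * dt)
    return Trajectory(frames, np.asarray(times))


def kabsch_rmsd(a: Conformation, b: Conformation) -> float:
    """Minimum RMSD (nm) over rigid superpositions of ``a`` onto ``b``.

    Centering plus the optimal proper rotation; reflections are disallowed
    (standard for chiral molecules).  Symmetric in its arguments.
    """
    if a.n != b.n:
        raise ValueError(f"conformations differ in size ({a.n} vs {b.n})")
    if a.n < 3:
        raise ValueError("superposition needs at least 3 points")
    pa = a.coords - a.coords.mean(axis=0)
    pb = b.coords - b.coords.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        _, rssd = Rotation.align_vectors(pb, pa)
    return float(rssd / np.sqrt(a.n))


# ---------------------------------------------------------------------------
# Writers (used by the fixtures and the demo workspace).
# ---------------------------------------------------------------------------

def write_gro(conf: Conformation, path, title: str = "afcv toy structure",
              resname: str = "ALA") -> Path:
    """Write a CA-only GRO file (nm, fixed columns, 10 nm cubic box)."""
    path = Path(path)
    lines = [title, f"{conf.n:5d}"]
    for i, (x, y, z) in enumerate(conf.coords, start=1):
        lines.append(f"{i:5d}{resname:<5s}{'CA':>5s}{i:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{10.0:10.5f}{10.0:10.5f}{10.0:10.5f}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pdb(conf: Conformation, path, resname: str = "ALA") -> Path:
    """Write a CA-only single-model PDB file (Angstrom)."""
    path = Path(path)
    lines = []
    for i, (x, y, z) in enumerate(conf.coords * 10.0, start=1):
        lines.append(
            f"ATOM  {i:5d}  CA  {resname:<3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_xyz(traj: Trajectory, path, symbol: str = "CA") -> Path:
    """Write the XYZ-with-time trajectory dialect (coordinates in nm)."""
    path = Path(path)
    chunks = []
    for conf, t in zip(traj.frames, traj.times):
        lines = [str(conf.n), f"t= {format(t, '.17g')}"]
        for x, y, z in conf.coords:
            lines.append(
                f"{symbol} {format(x, '.17g')} {format(y, '.17g')} {format(z, '.17g')}"
            )
        chunks.append("\n".join(lines))
    path.write_text("\n".join(chunks) + "\n")
    return path
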