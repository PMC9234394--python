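"""Plumed-dialect input generation and HILLS / COLVAR column files.

The collective variable cannot be expressed as a practical combination of
stock Plumed actions, so the exported input uses a bespoke ``ALPHAFOLD_CV``
action with a documented keyword set (ATOMS, LAMBDA, EPSILON, NBINS,
BINS_LOWER, BINS_UPPER, PROBFILE, plus MIN_SEPARATION and SUBSET); the
per-pair probability table lives in a human-readable sidecar file in the
tabular distogram format.  This package's own evaluator consumes the same
dialect, so a written input is executable end to end without Plumed.

All numeric fields are printed with 17 significant digits, which makes every
write -> parse -> write cycle byte-identical.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cv import CVParams
from .distogram import BinGeometry


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


@dataclasses.dataclass(frozen=True)
class Hill:
    """One deposited Gaussian: time (ps), per-CV centers and widths (CV
    units), height (kJ/mol) and, for well-tempered runs, the bias factor."""

    time: float
    centers: tuple[float, ...]
    widths: tuple[float, ...]
    height: float
    bias_factor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", tuple(float(c) for c in np.atleast_1d(self.centers)))
        object.__setattr__(self, "widths", tuple(float(w) for w in np.atleast_1d(self.widths)))
        if len(self.centers) != len(self.widths):
            raise ValueError("centers and widths must have the same length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("hill widths must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")
        if self.bias_factor is not None and not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")


@dataclasses.dataclass(frozen=True)
class MetadOptions:
    """METAD block parameters: hill height w0 (kJ/mol), per-CV sigma, the
    well-tempered bias factor gamma, deposition pace (steps) and optional
    thermostat temperature (K)."""

    height: float = 0.5
    sigma: tuple[float, ...] = (0.1,)
    bias_factor: float | None = 8.0
    pace: int = 500
    temp: float | None = None
    label: str = "metad"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", tuple(float(s) for s in np.atleast_1d(self.sigma)))
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma values must be positive")
        if self.height < 0:
            raise ValueError("hill height must be non-negative")
        if self.bias_factor is not None and not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")


@dataclasses.dataclass
class PlumedInput:
    """Parsed form of one exported input document."""

    atoms: tuple[int, ...]                 # CA atom serials, 1-based
    params: CVParams
    geometry: BinGeometry
    probfile: str
    label: str = "afcv"
    metad: MetadOptions | None = None
    print_stride: int = 500
    print_file: str = "COLVAR"

    def __post_init__(self) -> None:
        self.atoms = tuple(int(a) for a in self.atoms)
        if len(self.atoms) < 2:
            raise ValueError("need at least two CA atoms")


def write_plumed_input(doc: PlumedInput) -> str:
    """Render the canonical text form of a :class:`PlumedInput`."""
    g = doc.geometry
    cv = (
        f"ALPHAFOLD_CV LABEL={doc.label}"
        f" ATOMS={','.join(str(a) for a in doc.atoms)}"
        f" LAMBDA={_fmt(doc.params.lam)}"
        f" EPSILON={_fmt(doc.params.eps)}"
        f" NBINS={g.m}"
        f" BINS_LOWER={_fmt(g.lower)}"
        f" BINS_UPPER={_fmt(g.upper)}"
        f" PROBFILE={doc.probfile}"
        f" MIN_SEPARATION={doc.params.min_separation}"
    )
    if doc.params.subset is not None:
        members = ",".join(str(i + 1) for i in sorted(doc.params.subset))
        cv += f" SUBSET={members}"
    lines = ["# AlphaFold-based collective variable input (afcv dialect)", cv]
    if doc.metad is not None:
        m = doc.metad
        metad = (
            f"METAD LABEL={m.label} ARG={doc.label}"
            f" SIGMA={','.join(_fmt(s) for s in m.sigma)}"
            f" HEIGHT={_fmt(m.height)}"
            f" PACE={m.pace}"
        )
        if m.bias_factor is not None:
            metad += f" BIASFACTOR={_fmt(m.bias_factor)}"
        if m.temp is not None:
            metad += f" TEMP={_fmt(m.temp)}"
        lines.append(metad)
    lines.append(f"PRINT ARG={doc.label} STRIDE={doc.print_stride} FILE={doc.print_file}")
    return "\n".join(lines) + "\n"


def _keyvals(tokens: list[str], lineno: int, line: str) -> dict[str, str]:
    out = {}
    for tok in tokens:
        if "=" not in tok:
            raise ValueError(f"malformed token {tok!r} on line {lineno}: {line!r}")
        key, val = tok.split("=", 1)
        out[key] = val
    return out


def parse_plumed_input(text: str) -> PlumedInput:
    """Parse a document written by :func:`write_plumed_input` (or hand-written
    in the same dialect) back into a :class:`PlumedInput`."""
    cv_kw = metad_kw = print_kw = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        action, *tokens = line.split()
        kw = _keyvals(tokens, lineno, raw)
        if action == "ALPHAFOLD_CV":
            cv_kw = kw
        elif action == "METAD":
            metad_kw = kw
        elif action == "PRINT":
            print_kw = kw
        else:
            raise ValueError(f"unknown directive on line {lineno}: {raw!r}")
    if cv_kw is None:
        raise ValueError("document contains no ALPHAFOLD_CV block")
    for key in ("ATOMS", "LAMBDA", "EPSILON", "NBINS", "BINS_LOWER", "BINS_UPPER", "PROBFILE"):
        if key not in cv_kw:
            raise ValueError(f"ALPHAFOLD_CV block is missing the {key} keyword")
    subset = None
    if "SUBSET" in cv_kw:
        subset = frozenset(int(i) - 1 for i in cv_kw["SUBSET"].split(","))
    params = CVParams(
        lam=float(cv_kw["LAMBDA"]),
        eps=float(cv_kw["EPSILON"]),
        min_separation=int(cv_kw.get("MIN_SEPARATION", 1)),
        subset=subset,
    )
    geometry = BinGeometry(
        int(cv_kw["NBINS"]), float(cv_kw["BINS_LOWER"]), float(cv_kw["BINS_UPPER"])
    )
    label = cv_kw.get("LABEL", "afcv")
    metad = None
    if metad_kw is not None:
        sigma = tuple(float(s) for s in metad_kw["SIGMA"].split(","))
        args = metad_kw.get("ARG", label).split(",")
        if len(sigma) != len(args):
            raise ValueError(
                f"METAD SIGMA lists {len(sigma)} widths for {len(args)} CV argument(s)"
            )
        metad = MetadOptions(
            height=float(metad_kw["HEIGHT"]),
            sigma=sigma,
            bias_factor=float(metad_kw["BIASFACTOR"]) if "BIASFACTOR" in metad_kw else None,
            pace=int(metad_kw["PACE"]),
            temp=float(metad_kw["TEMP"]) if "TEMP" in metad_kw else None,
            label=metad_kw.get("LABEL", "metad"),
        )
    print_stride, print_file = 500, "COLVAR"
    if print_kw is not None:
        print_stride = int(print_kw.get("STRIDE", print_stride))
        print_file = print_kw.get("FILE", print_file)
    return PlumedInput(
        atoms=tuple(int(a) for a in cv_kw["ATOMS"].split(",")),
        params=params,
        geometry=geometry,
        probfile=cv_kw["PROBFILE"],
        label=label,
        metad=metad,
        print_stride=print_stride,
        print_file=print_file,
    )


# ---------------------------------------------------------------------------
# HILLS and COLVAR column files ("#! FIELDS ..." headers).
# ---------------------------------------------------------------------------

def _read_fields_header(path: Path) -> tuple[list[str], list[str]]:
    lines = path.read_text().splitlines()
    data = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    headers = [ln for ln in lines if ln.lstrip().startswith("#!")]
    if not headers:
        raise ValueError(f"{path}: missing '#! FIELDS' header")
    tokens = headers[0].split()
    if tokens[:2] != ["#!", "FIELDS"]:
        raise ValueError(f"{path}: malformed header {headers[0]!r}")
    return tokens[2:], data


def write_hills(hills: Sequence[Hill], path, cv_names: Sequence[str] = ("afcv",)) -> Path:
    """Write hills in the standard column layout
    ``time <cv...> sigma_<cv...> height [biasf]``."""
    path = Path(path)
    cv_names = list(cv_names)
    ncv = len(cv_names)
    if any(len(h.centers) != ncv for h in hills):
        raise ValueError(f"every hill must carry {ncv} center(s)")
    tempered = [h.bias_factor is not None for h in hills]
    if any(tempered) and not all(tempered):
        raise ValueError("hills mix well-tempered and plain entries")
    with_biasf = bool(hills) and all(tempered)
    fields = ["time", *cv_names, *[f"sigma_{c}" for c in cv_names], "height"]
    if with_biasf:
        fields.append("biasf")
    lines = ["#! FIELDS " + " ".join(fields)]
    for h in hills:
        row = [h.time, *h.centers, *h.widths, h.height]
        if with_biasf:
            row.append(h.bias_factor)
        lines.append(" ".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_hills(path) -> list[Hill]:
    """Parse a HILLS file into :class:`Hill` records (times nondecreasing)."""
    path = Path(path)
    fields, data = _read_fields_header(path)
    if not fields or fields[0] != "time":
        raise ValueError(f"{path}: first field must be 'time', got {fields[:1]}")
    with_biasf = fields[-1] == "biasf"
    core = fields[1 : -1 if with_biasf else len(fields)]
    if not core or core[-1] != "height":
        raise ValueError(f"{path}: expected a 'height' column, got fields {fields}")
    core = core[:-1]
    ncv, rem = divmod(len(core), 2)
    names, sigmas = core[:ncv], core[ncv:]
    if rem or ncv == 0 or sigmas != [f"sigma_{n}" for n in names]:
        raise ValueError(f"{path}: header does not match 'time <cv> sigma_<cv> height': {fields}")
    hills: list[Hill] = []
    prev_t = -np.inf
    for ln in data:
        parts = ln.split()
        if len(parts) != len(fields):
            raise ValueError(f"{path}: row has {len(parts)} columns, header has {len(fields)}")
        vals = [float(x) for x in parts]
        t = vals[0]
        if t < prev_t:
            raise ValueError(f"{path}: decreasing time {t} after {prev_t}")
        prev_t = t
        hills.append(
            Hill(
                time=t,
                centers=tuple(vals[1 : 1 + ncv]),
                widths=tuple(vals[1 + ncv : 1 + 2 * ncv]),
                height=vals[1 + 2 * ncv],
                bias_factor=vals[-1] if with_biasf else None,
            )
        )
    return hills


def write_colvar(table: pd.DataFrame, path) -> Path:
    """Write a COLVAR-style table: ``#! FIELDS <cols>`` then one row per
    record, 17 significant digits."""
    path = Path(path)
    lines = ["#! FIELDS " + " ".join(str(c) for c in table.columns)]
    for row in table.itertuples(index=False):
        lines.append(" ".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def parse_colvar(path) -> pd.DataFrame:
    """Parse a COLVAR file into a DataFrame with named columns; when a
    ``time`` column exists it must be nondecreasing."""
    path = Path(path)
    fields, data = _read_fields_header(path)
    rows = []
    for ln in data:
        parts = ln.split()
        if len(parts) != len(fields):
            raise ValueError(f"{path}: row has {len(parts)} columns, header has {len(fields)}")
        rows.append([float(x) for x in parts])
    table = pd.DataFrame(rows, columns=fields)
    if "time" in table.columns and len(table) > 1:
        if (np.diff(table["time"].to_numpy()) < 0).any():
            raise ValueError(f"{path}: decreasing time values")
    return table
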