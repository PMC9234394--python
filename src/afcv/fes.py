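"""Free-energy surfaces from hills, state populations, melting estimates and
conformational clustering.

The well-tempered estimator follows the Metadynminer convention: the bias
summed on a grid is rescaled by gamma / (gamma - 1) and negated,

    F(s) = -(gamma / (gamma - 1)) V(s),

then shifted so the visited minimum sits at zero.  Populations on either
side of a CV threshold are Boltzmann integrals exp(-F / kB T) with
trapezoidal grid weights; the melting temperature is the 0.5 crossing of a
folded-fraction-vs-temperature curve.  Clustering is the iterative
largest-neighborhood algorithm of Daura and co-workers under a pairwise
superposition-RMSD cutoff.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import KB
from .cv import Conformation
from .plumed import Hill
from .structures import Trajectory, kabsch_rmsd

__all__ = [
    "FreeEnergySurface", "MeltingCurve", "MeltingEstimate",
    "fes_from_hills", "fes_time_average", "folded_fraction", "melting_temperature",
    "melting_curve_from_surfaces", "daura_cluster", "cumulative_clusters",
    "write_fes", "write_melting_curve",
]

#: Nodes further than this many hill widths from every hill center are
#: treated as unvisited and excluded from Boltzmann integrals.
UNVISITED_SIGMA = 5.0


@dataclasses.dataclass
class FreeEnergySurface:
    """Free energy (kJ/mol) on a regular 1-D or 2-D CV grid.

    ``values`` is NaN on unvisited nodes; over visited nodes the minimum is
    zero after normalization.
    """

    axes: tuple[np.ndarray, ...]
    values: np.ndarray
    visited: np.ndarray
    temperature: float | None = None
    bias_factor: float | None = None

    def __post_init__(self) -> None:
        self.axes = tuple(np.asarray(a, dtype=float) for a in self.axes)
        shape = tuple(len(a) for a in self.axes)
        self.values = np.asarray(self.values, dtype=float)
        self.visited = np.asarray(self.visited, dtype=bool)
        if self.values.shape != shape or self.visited.shape != shape:
            raise ValueError("values/visited shape must match the grid axes")

    @property
    def ndim(self) -> int:
        return len(self.axes)


def _grid_axes(grid) -> tuple[np.ndarray, ...]:
    spec = [grid] if np.isscalar(grid[0]) else list(grid)
    axes = []
    for lo, hi, npts in spec:
        if npts < 2 or not lo < hi:
            raise ValueError(f"bad grid spec ({lo}, {hi}, {npts})")
        axes.append(np.linspace(lo, hi, int(npts)))
    if len(axes) not in (1, 2):
        raise ValueError("only 1-D and 2-D grids are supported")
    return tuple(axes)


def fes_from_hills(hills: Sequence[Hill], grid, temperature: float | None = None,
                   normalize: bool = True) -> FreeEnergySurface:
    """Reconstruct the free-energy surface from deposited hills.

    ``grid`` is ``(min, max, points)`` or a sequence of such per CV axis.
    All hills must share one bias factor (or all carry none, in which case
    the plain estimator F = -V applies).  With ``normalize`` the visited
    minimum is shifted to zero and unvisited nodes become NaN; without it the
    raw estimator is returned (useful for linearity checks).
    """
    axes = _grid_axes(grid)
    gammas = {h.bias_factor for h in hills}
    if len(gammas) > 1:
        raise ValueError(f"hills carry mixed bias factors {sorted(gammas, key=str)}")
    gamma = gammas.pop() if gammas else None
    if hills and len(hills[0].centers) != len(axes):
        raise ValueError(
            f"hills have {len(hills[0].centers)} CV component(s) but the grid has {len(axes)}"
        )
    shape = tuple(len(a) for a in axes)
    v = np.zeros(shape)
    visited = np.zeros(shape, dtype=bool) if hills else np.ones(shape, dtype=bool)
    if len(axes) == 1:
        x = axes[0]
        for h in hills:
            z = (x - h.centers[0]) / h.widths[0]
            v += h.height * np.exp(-0.5 * z * z)
            visited |= np.abs(z) <= UNVISITED_SIGMA
    else:
        x, y = axes
        for h in hills:
            zx = (x - h.centers[0]) / h.widths[0]
            zy = (y - h.centers[1]) / h.widths[1]
            v += h.height * np.outer(np.exp(-0.5 * zx * zx), np.exp(-0.5 * zy * zy))
            visited |= np.outer(np.abs(zx) <= UNVISITED_SIGMA, np.abs(zy) <= UNVISITED_SIGMA)
    scale = gamma / (gamma - 1.0) if gamma is not None else 1.0
    f = -scale * v
    if normalize:
        if visited.any():
            f = f - f[visited].min()
        f = np.where(visited, f, np.nan)
    return FreeEnergySurface(axes, f, visited, temperature=temperature, bias_factor=gamma)


def fes_time_average(hills: Sequence[Hill], grid, fraction: float = 0.5,
                     n_checkpoints: int = 20,
                     temperature: float | None = None) -> FreeEnergySurface:
    """Tail-averaged free-energy estimator.

    The instantaneous well-tempered estimate keeps fluctuating as hills are
    added even after the bias has converged on average; averaging the
    estimator over the last ``fraction`` of the depositions (sampled at
    ``n_checkpoints`` hill counts) suppresses that residual variance without
    biasing the profile.  Visited-region flags come from the full hill set.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not hills:
        return fes_from_hills(hills, grid, temperature=temperature)
    n = len(hills)
    start = max(int(round(n * (1.0 - fraction))), 1)
    counts = np.unique(np.linspace(start, n, min(n_checkpoints, n - start + 1)
                                   ).astype(int))
    acc = None
    for k in counts:
        f = fes_from_hills(hills[:k], grid, normalize=False).values
        acc = f if acc is None else acc + f
    full = fes_from_hills(hills, grid, temperature=temperature)
    values = acc / len(counts)
    if full.visited.any():
        values = values - values[full.visited].min()
    values = np.where(full.visited, values, np.nan)
    return FreeEnergySurface(full.axes, values, full.visited,
                             temperature=temperature,
                             bias_factor=full.bias_factor)


def folded_fraction(fes: FreeEnergySurface, temperature: float, threshold: float,
                    folded_side: str = "above") -> float:
    """Boltzmann population of the folded side of a CV threshold.

    p = sum_{s on folded side} w(s) exp(-F(s)/kB T) / sum_all, with
    trapezoidal node weights w on the (uniform) grid and unvisited nodes
    excluded.  The two sides sum to one by construction.
    """
    if fes.ndim != 1:
        raise ValueError("folded_fraction requires a 1-D surface")
    if folded_side not in ("above", "below"):
        raise ValueError(f"folded_side must be 'above' or 'below', got {folded_side!r}")
    x = fes.axes[0]
    if not x[0] <= threshold <= x[-1]:
        raise ValueError(f"threshold {threshold} outside grid range [{x[0]}, {x[-1]}]")
    h = x[1] - x[0]
    w = np.full(x.shape, h)
    w[0] = w[-1] = 0.5 * h
    w = np.where(fes.visited, w, 0.0)
    f = np.where(fes.visited, fes.values, np.inf)
    fmin = f[fes.visited].min() if fes.visited.any() else 0.0
    boltz = np.exp(-(f - fmin) / (KB * temperature))
    above = x > threshold
    num_above = float((w * boltz)[above].sum())
    num_below = float((w * boltz)[~above].sum())
    if num_above == 0.0 or num_below == 0.0:
        side = "above" if num_above == 0.0 else "below"
        raise ValueError(f"no visited nodes {side} the threshold {threshold}")
    total = num_above + num_below
    return num_above / total if folded_side == "above" else num_below / total


@dataclasses.dataclass
class MeltingCurve:
    """Folded fraction versus temperature (ascending K, fractions in [0, 1])."""

    temperatures: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.temperatures.shape != self.fractions.shape or self.temperatures.ndim != 1:
            raise ValueError("temperatures and fractions must be matching 1-D arrays")
        if self.temperatures.size == 0:
            raise ValueError("melting curve is empty")
        if self.temperatures.size > 1 and not (np.diff(self.temperatures) > 0).all():
            raise ValueError("temperatures must be strictly increasing")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class MeltingEstimate:
    """Estimated melting temperature; ``crossed`` is False when the curve
    never actually crosses one half (the returned value is then the nearest
    ladder end)."""

    temperature: float
    crossed: bool = True

    def __float__(self) -> float:
        return self.temperature


def melting_temperature(curve: MeltingCurve) -> MeltingEstimate:
    """Temperature at which the folded fraction crosses 0.5.

    Linear interpolation between the bracketing ladder points.  If the curve
    starts below 0.5 the lowest temperature is returned flagged; if it never
    drops below 0.5 the highest is returned flagged.  Multiple crossings use
    the first, with a warning.
    """
    t, f = curve.temperatures, curve.fractions
    if len(t) < 2:
        raise ValueError("need at least 2 temperatures to locate a melting point")
    if f[0] < 0.5:
        warnings.warn("folded fraction already below 0.5 at the lowest temperature")
        return MeltingEstimate(float(t[0]), crossed=False)
    down = np.flatnonzero((f[:-1] >= 0.5) & (f[1:] < 0.5))
    hits = np.flatnonzero(f == 0.5)
    if down.size == 0 and hits.size == 0:
        warnings.warn("folded fraction never falls below 0.5")
        return MeltingEstimate(float(t[-1]), crossed=False)
    if down.size > 1:
        warnings.warn("multiple 0.5 crossings; using the first")
    if down.size == 0:
        return MeltingEstimate(float(t[hits[0]]))
    i = down[0]
    if hits.size and hits[0] <= i + 1:
        return MeltingEstimate(float(t[hits[0]]))
    frac = (0.5 - f[i]) / (f[i + 1] - f[i])
    return MeltingEstimate(float(t[i] + frac * (t[i + 1] - t[i])))


def melting_curve_from_surfaces(surfaces: Sequence[FreeEnergySurface],
                                threshold: float,
                                folded_side: str = "above") -> MeltingCurve:
    """Fold per-temperature surfaces into a melting curve (each surface must
    carry its temperature)."""
    pairs = []
    for fes in surfaces:
        if fes.temperature is None:
            raise ValueError("every surface needs a temperature")
        pairs.append((fes.temperature, folded_fraction(fes, fes.temperature, threshold, folded_side)))
    pairs.sort()
    temps, fracs = zip(*pairs)
    return MeltingCurve(np.asarray(temps), np.asarray(fracs))


# ---------------------------------------------------------------------------
# Clustering.
# ---------------------------------------------------------------------------

def daura_cluster(frames, cutoff: float) -> tuple[np.ndarray, list[int]]:
    """Iterative largest-neighborhood clustering under an RMSD cutoff (nm).

    Repeatedly the frame with the most neighbors within ``cutoff`` (ties
    resolved toward the lowest frame index) seeds a cluster; it and its
    neighbors are removed.  Returns per-frame cluster labels (0, 1, ... in
    discovery order) and the center frame indices.
    """
    if isinstance(frames, Trajectory):
        frames = frames.frames
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = len(frames)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(frames[i], frames[j])
    neighbors = rmsd <= cutoff
    remaining = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    cid = 0
    while remaining.any():
        counts = np.where(remaining, (neighbors & remaining).sum(axis=1), -1)
        center = int(np.argmax(counts))      # argmax takes the lowest index on ties
        members = remaining & neighbors[center]
        labels[members] = cid
        remaining &= ~members
        centers.append(center)
        cid += 1
    return labels, centers


def cumulative_clusters(assignments) -> np.ndarray:
    """Number of distinct clusters seen up to each frame (nondecreasing)."""
    assignments = np.asarray(assignments)
    if assignments.size == 0:
        raise ValueError("assignments must be nonempty")
    seen: set = set()
    out = np.empty(assignments.size, dtype=int)
    for k, a in enumerate(assignments):
        seen.add(int(a))
        out[k] = len(seen)
    return out


# ---------------------------------------------------------------------------
# Text output.
# ---------------------------------------------------------------------------

def write_fes(fes: FreeEnergySurface, path) -> Path:
    """Write a surface as a text grid with a header recording the bias
    factor, temperature and grid spec."""
    path = Path(path)
    meta = (
        f"# bias_factor={fes.bias_factor} temperature={fes.temperature} "
        + " grid="
        + ";".join(f"{a[0]:.17g},{a[-1]:.17g},{len(a)}" for a in fes.axes)
    )
    lines = [meta]
    if fes.ndim == 1:
        for x, f, vis in zip(fes.axes[0], fes.values, fes.visited):
            lines.append(f"{x:.17g} {f:.17g} {int(vis)}")
    else:
        for i, x in enumerate(fes.axes[0]):
            for j, y in enumerate(fes.axes[1]):
                lines.append(
                    f"{x:.17g} {y:.17g} {fes.values[i, j]:.17g} {int(fes.visited[i, j])}"
                )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_melting_curve(curve: MeltingCurve, path) -> Path:
    """CSV with columns temperature_K, folded_fraction."""
    path = Path(path)
    lines = ["temperature_K,folded_fraction"]
    for t, f in zip(curve.temperatures, curve.fractions):
        lines.append(f"{t:.17g},{f:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path
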