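"""The distogram-compliance collective variable and its gradient.

Given a conformation with Calpha coordinates and a distogram, the discrete
score sums, over residue pairs, the model probability of the distance bin
each pair currently occupies: the expected number of inter-residue distances
that "agree" with the probability model.  To bias a simulation the score
must be differentiable, so each per-pair term is smoothed with the
one-dimensional path-variable kernel

    P_ij(d) = sum_k D[i,j,k] exp(-lam (d - d_k)^2)
              / (eps + sum_k exp(-lam (d - d_k)^2)),

where d_k are the bin-center distances, lam sets the sharpness (1000 nm^-2
by default) and eps is a small pseudocount that keeps the ratio finite when
d falls outside the binned range.  The CV is the sum of P_ij over included
pairs; its analytic gradient with respect to the coordinates reuses the
kernel evaluations.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import numpy as np

from .distogram import BinGeometry, Distogram


@dataclasses.dataclass
class Conformation:
    """Ordered Calpha positions, one (x, y, z) triple per residue, in nm."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) coordinate array, got shape {coords.shape}")
        if not np.isfinite(coords).all():
            raise ValueError("conformation contains non-finite coordinates")
        self.coords = coords

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def pair_distances(self, pairs: np.ndarray) -> np.ndarray:
        """Euclidean distances for an array of (i, j) index pairs."""
        diff = self.coords[pairs[:, 0]] - self.coords[pairs[:, 1]]
        return np.linalg.norm(diff, axis=1)


@dataclasses.dataclass(frozen=True)
class CVParams:
    """Tunable parameters of the collective variable.

    lam : kernel sharpness in nm^-2 (> 0).
    eps : pseudocount in the kernel denominator (>= 0); the default 1e-10 is
        small enough to leave in-range values unchanged to better than nine
        significant digits while preventing 0/0 far outside the bin range.
    min_separation : smallest |i - j| for a pair to be included (>= 1).
    subset : optional residue indices (0-based); when given, only pairs with
        both residues in the subset contribute ("focused" variant).
    """

    lam: float = 1000.0
    eps: float = 1e-10
    min_separation: int = 1
    subset: frozenset[int] | None = None

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.eps < 0:
            raise ValueError(f"eps must be non-negative, got {self.eps}")
        if int(self.min_separation) != self.min_separation or self.min_separation < 1:
            raise ValueError(f"min_separation must be an integer >= 1, got {self.min_separation}")
        if self.subset is not None:
            object.__setattr__(self, "subset", frozenset(int(i) for i in self.subset))


@dataclasses.dataclass
class CVResult:
    """Value (dimensionless), optional gradient (n x 3, nm^-1) and optional
    per-pair probabilities of one CV evaluation."""

    value: float
    gradient: np.ndarray | None = None
    per_pair: Mapping[tuple[int, int], float] | None = None


def pair_mask(n: int, params: CVParams) -> list[tuple[int, int]]:
    """Lexicographically ordered included pairs (i < j).

    A pair is included when |i - j| >= ``min_separation`` and, if a subset is
    given, both residues belong to it.
    """
    if n < 2:
        raise ValueError(f"need at least 2 residues, got {n}")
    subset = params.subset
    if subset is not None:
        if any(i < 0 or i >= n for i in subset):
            raise ValueError("subset contains residue indices outside [0, n)")
        if len(subset) < 2:
            raise ValueError("subset must contain at least 2 residues")
    pairs = []
    for i in range(n):
        if subset is not None and i not in subset:
            continue
        for j in range(i + params.min_separation, n):
            if subset is not None and j not in subset:
                continue
            pairs.append((i, j))
    return pairs


def _kernels(d: np.ndarray, centers: np.ndarray, lam: float):
    """Gaussian kernels exp(-lam (d - d_k)^2) and the displacement d - d_k."""
    delta = d[..., None] - centers
    return np.exp(-lam * delta * delta), delta


def pair_probability(probs_ij: np.ndarray, geometry: BinGeometry, d: float,
                     params: CVParams) -> float:
    """Smoothed probability P_ij(d) for one pair; value in [0, 1)."""
    row = np.asarray(probs_ij, dtype=float)
    if row.shape != (geometry.m,):
        raise ValueError(f"expected a length-{geometry.m} probability row, got {row.shape}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    kern, _ = _kernels(np.asarray(float(d)), geometry.centers, params.lam)
    return float(row @ kern / (params.eps + kern.sum()))


def pair_probability_derivative(probs_ij: np.ndarray, geometry: BinGeometry,
                                d: float, params: CVParams) -> float:
    """Analytic dP_ij/dd in nm^-1 (quotient rule, reusing the kernels)."""
    row = np.asarray(probs_ij, dtype=float)
    kern, delta = _kernels(np.asarray(float(d)), geometry.centers, params.lam)
    dkern = -2.0 * params.lam * delta * kern
    num, den = row @ kern, params.eps + kern.sum()
    dnum, dden = row @ dkern, dkern.sum()
    return float((dnum * den - num * dden) / (den * den))


def cv_value(conf: Conformation, disto: Distogram, params: CVParams = CVParams(),
             want_gradient: bool = False, want_per_pair: bool = False) -> CVResult:
    """Evaluate the collective variable (and optionally its gradient).

    The value is the sum of P_ij over the pair mask; the gradient accumulates
    dP/dd times the unit inter-residue vector onto residues i (+) and j (-),
    so it sums to the zero vector over residues (translation invariance).
    Coincident pairs (d = 0) contribute P(0) to the value but no gradient
    (the direction is undefined); a warning is emitted.
    """
    if conf.n != disto.n:
        raise ValueError(
            f"conformation has {conf.n} residues but distogram has {disto.n}"
        )
    pairs = np.asarray(pair_mask(conf.n, params), dtype=int)
    diff = conf.coords[pairs[:, 0]] - conf.coords[pairs[:, 1]]
    d = np.linalg.norm(diff, axis=1)
    rows = disto.probs[pairs[:, 0], pairs[:, 1]]            # (P, M)
    kern, delta = _kernels(d, disto.geometry.centers, params.lam)
    num = (rows * kern).sum(axis=1)
    den = params.eps + kern.sum(axis=1)
    p = num / den
    result = CVResult(value=float(p.sum()))
    if want_per_pair:
        result.per_pair = {tuple(pr): float(v) for pr, v in zip(pairs, p)}
    if want_gradient:
        dkern = -2.0 * params.lam * delta * kern
        dnum = (rows * dkern).sum(axis=1)
        dden = dkern.sum(axis=1)
        dpdd = (dnum * den - num * dden) / (den * den)
        unit = np.zeros_like(diff)
        nonzero = d > 0
        unit[nonzero] = diff[nonzero] / d[nonzero, None]
        if not nonzero.all():
            bad = pairs[~nonzero][0]
            warnings.warn(
                f"coincident residue pair ({bad[0]}, {bad[1]}): zero gradient "
                "contribution for that pair",
                stacklevel=2,
            )
        contrib = dpdd[:, None] * unit
        grad = np.zeros_like(conf.coords)
        np.add.at(grad, pairs[:, 0], contrib)
        np.add.at(grad, pairs[:, 1], -contrib)
        result.gradient = grad
    return result


def discrete_expected_matches(conf: Conformation, disto: Distogram,
                              params: CVParams = CVParams()) -> float:
    """Discrete expected-match score: sum over pairs of D[i, j, bin(d_ij)].

    The occupied bin is the half-open interval [lower + k w, lower + (k+1) w)
    containing d_ij; distances below the range map to bin 0 and at or above
    the upper edge to bin M - 1.
    """
    if conf.n != disto.n:
        raise ValueError(
            f"conformation has {conf.n} residues but distogram has {disto.n}"
        )
    pairs = np.asarray(pair_mask(conf.n, params), dtype=int)
    d = conf.pair_distances(pairs)
    k = disto.geometry.bin_index(d)
    return float(disto.probs[pairs[:, 0], pairs[:, 1], k].sum())


class DistogramCV:
    """Adapter exposing the CV as a function of flat coordinates.

    Instances are callables ``x -> (value, gradient)`` with ``x`` a flat
    (3 n,) array, suitable as the biased variable of the toy sampler.
    """

    def __init__(self, disto: Distogram, params: CVParams = CVParams()):
        self.disto = disto
        self.params = params

    def __call__(self, x: np.ndarray):
        conf = Conformation(np.asarray(x, dtype=float).reshape(-1, 3))
        res = cv_value(conf, self.disto, self.params, want_gradient=True)
        return res.value, res.gradient.ravel()
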