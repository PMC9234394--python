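"""Synthetic distograms, toy systems and exchange logs with known ground
truth.

These generators stand in for cluster-scale inputs: a distogram built from a
known reference conformation plays the role of a confident structure
prediction, a harmonic-chain polymer plays the role of a mini-protein, and a
quartic double well provides an analytically known free-energy surface.
Every generator takes an explicit seed and is bitwise reproducible; none of
them touches global random state.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .constants import KB
from .cv import Conformation
from .distogram import BinGeometry, Distogram
from .fes import FreeEnergySurface
from .sampling import ExchangeEvent, ExchangeLog, ToySystem

__all__ = [
    "SyntheticSpec", "synthetic_distogram", "random_chain", "toy_polymer",
    "double_well_1d", "synthetic_exchange_log", "two_state_fraction",
    "two_state_potential", "two_state_surface",
]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic distogram.

    concentration : width (nm) of the Gaussian probability peak placed at
        each reference pair distance; small values emulate a confident model.
    background : fraction of per-pair mass spread uniformly over all bins.
    """

    n: int
    m: int = 64
    geometry: BinGeometry | None = None
    concentration: float = 0.02
    background: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 residues")
        if not 0 <= self.background < 1:
            raise ValueError("background fraction must lie in [0, 1)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.geometry is None:
            object.__setattr__(self, "geometry", BinGeometry(self.m))
        elif self.geometry.m != self.m:
            raise ValueError("geometry bin count must equal m")


def synthetic_distogram(reference: Conformation, spec: SyntheticSpec) -> Distogram:
    """Distogram whose per-pair mass peaks at the reference distances.

    Each off-diagonal row is a discretized Gaussian centered at the
    reference pair distance (sigma = ``concentration``) mixed with a uniform
    background, renormalized per pair.  Symmetric by construction.  Pair
    distances outside the bin range clamp their mass onto the edge bins,
    with a warning.
    """
    if reference.n != spec.n:
        raise ValueError(f"reference has {reference.n} residues, spec declares {spec.n}")
    g = spec.geometry
    centers = g.centers
    coords = reference.coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    out_of_range = (d < g.lower) | (d > g.upper)
    np.fill_diagonal(out_of_range, False)
    if out_of_range.any():
        i, j = np.argwhere(out_of_range)[0]
        warnings.warn(
            f"reference distance {d[i, j]:.3f} nm for pair ({i}, {j}) is outside "
            f"the bin range [{g.lower}, {g.upper}] nm; its mass clamps to the edge bins",
            stacklevel=2,
        )
    z = (d[:, :, None] - centers) / spec.concentration
    peak = np.exp(-0.5 * z * z)
    norms = peak.sum(axis=2, keepdims=True)
    # A peak far outside the range can underflow every bin; clamp to the
    # nearest edge bin in that case.
    dead = norms[:, :, 0] <= 0
    if dead.any():
        edge = np.where(d[dead] < g.lower, 0, g.m - 1)
        peak[dead] = np.eye(g.m)[edge]
        norms = peak.sum(axis=2, keepdims=True)
    probs = (1.0 - spec.background) * peak / norms + spec.background / g.m
    probs = 0.5 * (probs + probs.transpose(1, 0, 2))
    probs /= probs.sum(axis=2, keepdims=True)
    return Distogram(probs, g)


def random_chain(n: int, bond_length: float, rng: np.random.Generator,
                 min_distance: float = 0.0, compactness: float = 0.0) -> np.ndarray:
    """Random walk with fixed step length; optionally self-avoiding within
    ``min_distance`` and biased toward the centroid by ``compactness``."""
    coords = np.zeros((n, 3))
    for i in range(1, n):
        best, best_sep = None, -np.inf
        for _ in range(200):
            u = rng.standard_normal(3)
            if compactness > 0 and i > 1:
                u = u - compactness * (coords[i - 1] - coords[:i].mean(axis=0))
            u /= np.linalg.norm(u)
            cand = coords[i - 1] + bond_length * u
            sep = (
                np.linalg.norm(coords[: i - 1] - cand, axis=1).min() if i > 1 else np.inf
            )
            if sep >= min_distance:
                best = cand
                break
            if sep > best_sep:
                best, best_sep = cand, sep
        coords[i] = best
    return coords


def toy_polymer(n_residues: int, bond_length: float = 0.38, seed: int = 0
                ) -> tuple[ToySystem, Conformation]:
    """Harmonic-chain polymer attracted toward a seeded compact reference.

    The potential (over flat coordinates, kJ/mol) has three quadratic terms:
    bonds of stiffness 1000 kJ/mol/nm^2 at ``bond_length``, a soft excluded
    volume pushing non-bonded beads beyond 0.25 nm, and a weak pair-distance
    attraction toward the reference conformation.  All three vanish at the
    reference, which is therefore the global minimum (energy zero).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    ref = random_chain(n_residues, bond_length, rng, min_distance=0.3, compactness=0.35)
    reference = Conformation(ref)

    k_bond, k_ev, r_ev = 1000.0, 200.0, 0.25
    k_att = 2.0 / n_residues
    pairs = np.array(
        [(i, j) for i in range(n_residues) for j in range(i + 2, n_residues)], dtype=int
    )
    d_ref = np.linalg.norm(ref[pairs[:, 0]] - ref[pairs[:, 1]], axis=1)

    def _terms(x):
        c = x.reshape(n_residues, 3)
        bond_vec = c[1:] - c[:-1]
        bond_d = np.linalg.norm(bond_vec, axis=1)
        pair_vec = c[pairs[:, 0]] - c[pairs[:, 1]]
        pair_d = np.linalg.norm(pair_vec, axis=1)
        return c, bond_vec, bond_d, pair_vec, pair_d

    def potential(x):
        _, _, bond_d, _, pair_d = _terms(np.asarray(x, dtype=float))
        e = 0.5 * k_bond * ((bond_d - bond_length) ** 2).sum()
        overlap = np.minimum(pair_d - r_ev, 0.0)
        e += 0.5 * k_ev * (overlap**2).sum()
        e += 0.5 * k_att * ((pair_d - d_ref) ** 2).sum()
        return float(e)

    def gradient(x):
        c, bond_vec, bond_d, pair_vec, pair_d = _terms(np.asarray(x, dtype=float))
        grad = np.zeros_like(c)
        unit_b = bond_vec / bond_d[:, None]
        g_b = k_bond * (bond_d - bond_length)[:, None] * unit_b
        np.add.at(grad, np.arange(1, n_residues), g_b)
        np.add.at(grad, np.arange(n_residues - 1), -g_b)
        unit_p = pair_vec / pair_d[:, None]
        coef = k_ev * np.minimum(pair_d - r_ev, 0.0) + k_att * (pair_d - d_ref)
        g_p = coef[:, None] * unit_p
        np.add.at(grad, pairs[:, 0], g_p)
        np.add.at(grad, pairs[:, 1], -g_p)
        return grad.ravel()

    system = ToySystem(3 * n_residues, potential, gradient, x0=ref.ravel().copy())
    return system, reference


def double_well_1d(barrier: float, separation: float = 1.0) -> ToySystem:
    """Quartic double well U(s) = barrier ((s/a)^2 - 1)^2 with minima at
    +-a (a = ``separation``) and the stated barrier at s = 0.

    Because the system is one-dimensional, ``potential`` doubles as the
    analytic free-energy surface for validating reconstruction.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    a2 = separation * separation

    def potential(x):
        s2 = float(np.asarray(x).ravel()[0]) ** 2
        return barrier * (s2 / a2 - 1.0) ** 2

    def gradient(x):
        s = float(np.asarray(x).ravel()[0])
        return np.array([4.0 * barrier * s * (s * s / a2 - 1.0) / a2])

    return ToySystem(1, potential, gradient, x0=np.array([-separation]))


def synthetic_exchange_log(n_replicas: int, n_events: int, acceptance_rate: float,
                           seed: int = 0, dt: float = 1.0,
                           ) -> tuple[ExchangeLog, np.ndarray]:
    """Random neighbor-swap log plus its ground-truth final permutation.

    Events are uniform random neighbor pairs accepted with probability
    ``acceptance_rate``; the returned array maps each continuous replica to
    its final temperature slot (the composition of the accepted swaps).
    """
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    if not 0 <= acceptance_rate <= 1:
        raise ValueError("acceptance rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ladder = tuple(300.0 + 10.0 * k for k in range(n_replicas))
    slot_of = np.arange(n_replicas)
    replica_at = np.arange(n_replicas)
    events = []
    for e in range(n_events):
        a = int(rng.integers(n_replicas - 1))
        b = a + 1
        accepted = bool(rng.random() < acceptance_rate)
        if accepted:
            ra, rb = replica_at[a], replica_at[b]
            slot_of[ra], slot_of[rb] = b, a
            replica_at[a], replica_at[b] = rb, ra
        events.append(ExchangeEvent((e + 1) * dt, a, b, accepted))
    return ExchangeLog(ladder, events), slot_of


# ---------------------------------------------------------------------------
# Two-state thermodynamics (for the melting pipeline).
# ---------------------------------------------------------------------------

def two_state_fraction(temperature, dH: float, dS: float) -> np.ndarray:
    """Folded fraction 1 / (1 + exp(-(dH - T dS) / kB T)) of a two-state
    model with unfolding enthalpy dH (kJ/mol) and entropy dS (kJ/mol/K)."""
    t = np.asarray(temperature, dtype=float)
    return 1.0 / (1.0 + np.exp(-(dH - t * dS) / (KB * t)))


def two_state_potential(temperature: float, dH: float, dS: float,
                        folded_center: float = 5.5, unfolded_center: float = 4.0,
                        curvature: float = 100.0):
    """Analytic 1-D free-energy profile of the two-state model.

    Two identical parabolic wells; the unfolded well is offset by
    dG_unfold = dH - T dS, so Boltzmann integration on either side of a
    threshold between the wells reproduces :func:`two_state_fraction`.
    Returns a vectorized callable F(s) in kJ/mol.
    """
    dg = dH - temperature * dS

    def f(s):
        s = np.asarray(s, dtype=float)
        folded = curvature * (s - folded_center) ** 2
        unfolded = curvature * (s - unfolded_center) ** 2 + dg
        return np.minimum(folded, unfolded)

    return f


def two_state_surface(temperature: float, dH: float, dS: float,
                      grid=(3.0, 6.5, 2049), **well_kwargs) -> FreeEnergySurface:
    """The two-state profile sampled on a grid as a
    :class:`~afcv.fes.FreeEnergySurface` (all nodes visited)."""
    lo, hi, npts = grid
    x = np.linspace(lo, hi, int(npts))
    f = two_state_potential(temperature, dH, dS, **well_kwargs)(x)
    f = f - f.min()
    return FreeEnergySurface((x,), f, np.ones_like(x, dtype=bool), temperature=temperature)
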