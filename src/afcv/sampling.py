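"""Overdamped Langevin sampling with well-tempered metadynamics and
parallel tempering.

This is a desk-scale sampler meant to exercise a differentiable collective
variable as a bias, not a molecular-dynamics engine.  Positions evolve by
the overdamped (Brownian) update

    x <- x - (dt / gamma_f) grad U(x) + sqrt(2 kB T dt / gamma_f) xi,

with xi standard normal from an explicitly seeded generator, so every run is
bitwise reproducible.  Well-tempered metadynamics deposits Gaussian hills
along the CV every ``deposition_stride`` steps with heights damped by
exp(-V / (kB dT)), dT = (gamma - 1) T; parallel tempering swaps coordinates
between neighboring rungs of a temperature ladder with the Metropolis
criterion including the metadynamics bias cross-terms.

Units: kJ/mol, nm, ps, K.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .constants import KB, DEFAULT_LADDER
from .plumed import Hill

__all__ = [
    "ToySystem", "WTMetadParams", "ExchangeEvent", "ExchangeLog",
    "LangevinResult", "MetadResult", "PTMetadResult", "DemuxResult",
    "coordinate_cv", "run_langevin", "bias_energy", "wt_metad_run",
    "pt_exchange_attempt", "pt_metad_run", "demux",
    "write_exchange_log", "read_exchange_log", "DEFAULT_LADDER",
]

_NOISE_CHUNK = 8192


@dataclasses.dataclass
class ToySystem:
    """A potential-energy surface over ``n_dof`` flat coordinates.

    ``potential(x)`` returns kJ/mol and ``gradient(x)`` its derivative,
    kJ/mol/nm, for a flat coordinate vector of length ``n_dof``.
    """

    n_dof: int
    potential: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    x0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.x0 is None:
            self.x0 = np.zeros(self.n_dof)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (self.n_dof,):
            raise ValueError(f"x0 must have shape ({self.n_dof},), got {self.x0.shape}")


@dataclasses.dataclass(frozen=True)
class WTMetadParams:
    """Well-tempered metadynamics settings.

    hill_height_0 : initial hill height w0 in kJ/mol.
    widths : per-CV Gaussian sigma in CV units.
    bias_factor : gamma > 1; the fictitious temperature is T + (gamma-1) T.
    deposition_stride : integration steps between hill depositions.
    temperature : simulation temperature in K.
    """

    hill_height_0: float = 0.5
    widths: tuple[float, ...] = (0.1,)
    bias_factor: float = 8.0
    deposition_stride: int = 500
    temperature: float = 300.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "widths", tuple(float(w) for w in np.atleast_1d(self.widths)))
        if self.hill_height_0 <= 0 or any(w <= 0 for w in self.widths):
            raise ValueError("hill height and widths must be positive")
        if not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")
        if self.deposition_stride < 1:
            raise ValueError("deposition stride must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclasses.dataclass(frozen=True)
class ExchangeEvent:
    time: float
    slot_a: int
    slot_b: int
    accepted: bool


@dataclasses.dataclass
class ExchangeLog:
    """Temperature ladder plus the ordered record of swap attempts."""

    ladder: tuple[float, ...]
    events: list[ExchangeEvent]

    def __post_init__(self) -> None:
        self.ladder = tuple(float(t) for t in self.ladder)
        self.events = list(self.events)
        n = len(self.ladder)
        prev = -np.inf
        for ev in self.events:
            if ev.slot_a == ev.slot_b:
                raise ValueError("exchange event with identical slots")
            if not (0 <= ev.slot_a < n and 0 <= ev.slot_b < n):
                raise ValueError(f"exchange event references slot outside [0, {n})")
            if ev.time < prev:
                raise ValueError("exchange event times must be nondecreasing")
            prev = ev.time


@dataclasses.dataclass
class LangevinResult:
    times: np.ndarray
    positions: np.ndarray      # (samples, n_dof)
    energies: np.ndarray


@dataclasses.dataclass
class MetadResult:
    times: np.ndarray
    positions: np.ndarray
    cv_values: np.ndarray      # (samples, n_cv)
    hills: list[Hill]
    colvar: pd.DataFrame


@dataclasses.dataclass
class PTMetadResult:
    slots: list[MetadResult]   # one per temperature slot
    log: ExchangeLog


def coordinate_cv(index: int = 0):
    """CV that simply reads one coordinate (for low-dimensional toys)."""

    def cv(x: np.ndarray):
        grad = np.zeros((1, x.shape[0]))
        grad[0, index] = 1.0
        return np.array([x[index]]), grad

    return cv


def _as_cv(cv):
    """Normalize a CV callable to return (values (C,), jacobian (C, n_dof))."""

    def wrapped(x):
        s, g = cv(x)
        s = np.atleast_1d(np.asarray(s, dtype=float))
        g = np.asarray(g, dtype=float)
        if g.ndim == 1:
            g = g[None, :]
        return s, g

    return wrapped


# ---------------------------------------------------------------------------
# Bias potential.
# ---------------------------------------------------------------------------

class _HillStore:
    """Growable arrays of hill centers/widths/heights with fast evaluation."""

    def __init__(self, n_cv: int, capacity: int = 256):
        self.n_cv = n_cv
        self.count = 0
        self.centers = np.empty((capacity, n_cv))
        self.widths = np.empty((capacity, n_cv))
        self.heights = np.empty(capacity)

    @classmethod
    def from_hills(cls, hills: Sequence[Hill]) -> "_HillStore":
        ncv = len(hills[0].centers) if hills else 1
        store = cls(ncv, capacity=max(1, len(hills)))
        for h in hills:
            store.append(np.asarray(h.centers), np.asarray(h.widths), h.height)
        return store

    def append(self, center: np.ndarray, width: np.ndarray, height: float) -> None:
        if self.count == self.centers.shape[0]:
            for name in ("centers", "widths"):
                arr = getattr(self, name)
                setattr(self, name, np.concatenate([arr, np.empty_like(arr)]))
            self.heights = np.concatenate([self.heights, np.empty_like(self.heights)])
        self.centers[self.count] = center
        self.widths[self.count] = width
        self.heights[self.count] = height
        self.count += 1

    def evaluate(self, s: np.ndarray):
        """Bias V(s) in kJ/mol and dV/ds (n_cv,)."""
        h = self.count
        if h == 0:
            return 0.0, np.zeros(self.n_cv)
        z = (s - self.centers[:h]) / self.widths[:h]
        e = self.heights[:h] * np.exp(-0.5 * (z * z).sum(axis=1))
        v = e.sum()
        dv = -(e[:, None] * z / self.widths[:h]).sum(axis=0)
        return float(v), dv


def bias_energy(hills: Sequence[Hill], s) -> tuple[float, np.ndarray]:
    """Metadynamics bias V(s) = sum_h height_h prod_c exp(-(s_c - c_hc)^2 /
    (2 sigma_hc^2)) and its analytic derivative with respect to s."""
    s = np.atleast_1d(np.asarray(s, dtype=float))
    store = _HillStore.from_hills(hills)
    if hills and len(s) != store.n_cv:
        raise ValueError(f"CV point has {len(s)} components, hills have {store.n_cv}")
    if not hills:
        return 0.0, np.zeros(len(s))
    return store.evaluate(s)


# ---------------------------------------------------------------------------
# Integrators.
# ---------------------------------------------------------------------------

class _NoiseStream:
    """Chunked standard-normal draws from one Generator (cuts call overhead)."""

    def __init__(self, rng: np.random.Generator, n_dof: int):
        self.rng = rng
        self.n_dof = n_dof
        self.buffer = np.empty((0, n_dof))
        self.pos = 0

    def next(self) -> np.ndarray:
        if self.pos >= self.buffer.shape[0]:
            self.buffer = self.rng.standard_normal((_NOISE_CHUNK, self.n_dof))
            self.pos = 0
        row = self.buffer[self.pos]
        self.pos += 1
        return row


def run_langevin(system: ToySystem, n_steps: int, dt: float, temperature: float,
                 friction: float = 1.0, seed: int = 0, x0=None,
                 sample_stride: int = 1) -> LangevinResult:
    """Integrate the overdamped Langevin equation; bitwise reproducible.

    Samples (including the initial state) are recorded every
    ``sample_stride`` steps.  A non-finite force aborts with the step index.
    """
    if dt <= 0 or friction <= 0 or temperature < 0:
        raise ValueError("dt and friction must be positive, temperature non-negative")
    x = np.array(system.x0 if x0 is None else x0, dtype=float)
    rng = np.random.default_rng(seed)
    noise = _NoiseStream(rng, system.n_dof)
    mob = dt / friction
    amp = np.sqrt(2.0 * KB * temperature * dt / friction)
    times, positions, energies = [], [], []
    for step in range(n_steps + 1):
        if step % sample_stride == 0:
            times.append(step * dt)
            positions.append(x.copy())
            energies.append(system.potential(x))
        if step == n_steps:
            break
        f = -np.asarray(system.gradient(x), dtype=float)
        if not np.isfinite(f).all():
            raise RuntimeError(f"non-finite force at step {step}")
        x = x + mob * f + amp * noise.next()
    return LangevinResult(np.asarray(times), np.asarray(positions), np.asarray(energies))


class _Walker:
    """State of one biased replica: coordinates, hill store, RNG stream."""

    def __init__(self, system: ToySystem, cv, params: WTMetadParams | None,
                 temperature: float, dt: float, friction: float,
                 seed_seq: np.random.SeedSequence, x0):
        self.system = system
        self.cv = _as_cv(cv)
        self.params = params
        self.temperature = temperature
        self.mob = dt / friction
        self.amp = np.sqrt(2.0 * KB * temperature * dt / friction)
        self.noise = _NoiseStream(np.random.default_rng(seed_seq), system.n_dof)
        self.x = np.array(system.x0 if x0 is None else x0, dtype=float)
        ncv = len(self.cv(self.x)[0])
        if params is not None and len(params.widths) != ncv:
            raise ValueError(
                f"params declare {len(params.widths)} widths but the CV has {ncv} components"
            )
        self.store = _HillStore(ncv)
        self.widths = np.asarray(params.widths) if params is not None else None
        self.hills: list[Hill] = []
        self.times: list[float] = []
        self.positions: list[np.ndarray] = []
        self.cv_trace: list[np.ndarray] = []
        self.bias_trace: list[float] = []

    def step(self, step_index: int, dt: float) -> None:
        s, dsdx = self.cv(self.x)
        if not (np.isfinite(s).all() and np.isfinite(dsdx).all()):
            raise RuntimeError(f"non-finite CV or CV gradient at step {step_index}")
        v, dvds = self.store.evaluate(s)
        p = self.params
        if p is not None and step_index > 0 and step_index % p.deposition_stride == 0:
            height = p.hill_height_0 * np.exp(
                -v / (KB * (p.bias_factor - 1.0) * p.temperature)
            )
            self.store.append(s, self.widths, height)
            self.hills.append(
                Hill(step_index * dt, tuple(s), tuple(self.widths), float(height),
                     p.bias_factor)
            )
            v, dvds = self.store.evaluate(s)
        f = -np.asarray(self.system.gradient(self.x), dtype=float) - dvds @ dsdx
        if not np.isfinite(f).all():
            raise RuntimeError(f"non-finite force at step {step_index}")
        self._last_cv, self._last_bias = s, v
        self.x = self.x + self.mob * f + self.amp * self.noise.next()

    def record(self, t: float, s: np.ndarray, v: float) -> None:
        self.times.append(t)
        self.positions.append(self.x.copy())
        self.cv_trace.append(np.atleast_1d(s).copy())
        self.bias_trace.append(v)

    def sample_now(self) -> tuple[np.ndarray, float]:
        s, _ = self.cv(self.x)
        v, _ = self.store.evaluate(s)
        return s, v

    def result(self) -> MetadResult:
        cvs = np.asarray(self.cv_trace)
        colvar = pd.DataFrame({"time": self.times})
        for c in range(cvs.shape[1] if cvs.size else 1):
            colvar[f"cv{c + 1}" if cvs.shape[1] > 1 else "afcv"] = (
                cvs[:, c] if cvs.size else []
            )
        colvar["bias"] = self.bias_trace
        return MetadResult(
            np.asarray(self.times), np.asarray(self.positions), cvs,
            self.hills, colvar,
        )


def wt_metad_run(system: ToySystem, cv, params: WTMetadParams, n_steps: int,
                 seed: int = 0, dt: float = 0.001, friction: float = 1.0,
                 x0=None, sample_stride: int = 100) -> MetadResult:
    """Well-tempered metadynamics on one replica.

    Every ``deposition_stride`` steps a Gaussian hill is placed at the current
    CV value with height w0 exp(-V(s) / (kB (gamma - 1) T)), V being the bias
    accumulated so far; the first hill therefore has height exactly w0.
    Forces include the chain-rule term -dV/ds ds/dx.
    """
    seq = np.random.SeedSequence(seed)
    walker = _Walker(system, cv, params, params.temperature, dt, friction, seq, x0)
    for step in range(n_steps + 1):
        if step % sample_stride == 0:
            s, v = walker.sample_now()
            walker.record(step * dt, s, v)
        if step == n_steps:
            break
        walker.step(step, dt)
    return walker.result()


# ---------------------------------------------------------------------------
# Parallel tempering.
# ---------------------------------------------------------------------------

def pt_exchange_attempt(u_i: float, u_j: float, vi_si: float, vi_sj: float,
                        vj_sj: float, vj_si: float, t_i: float, t_j: float,
                        rng: np.random.Generator) -> bool:
    """Metropolis swap decision between replicas i and j.

    Accept with probability min(1, exp[(beta_i - beta_j)(U_i - U_j)
    + beta_i (V_i(s_i) - V_i(s_j)) + beta_j (V_j(s_j) - V_j(s_i))]), where
    V_i is replica i's own bias.  With all bias terms zero this reduces to
    plain parallel tempering.
    """
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    bi, bj = 1.0 / (KB * t_i), 1.0 / (KB * t_j)
    delta = (bi - bj) * (u_i - u_j) + bi * (vi_si - vi_sj) + bj * (vj_sj - vj_si)
    if delta >= 0:
        return True
    return bool(rng.random() < np.exp(delta))


def pt_metad_run(systems, cv, params: WTMetadParams | None,
                 ladder: Sequence[float] = DEFAULT_LADDER[:4],
                 exchange_stride: int = 1000, n_steps: int = 10000,
                 seed: int = 0, dt: float = 0.001, friction: float = 1.0,
                 x0=None, sample_stride: int = 100) -> PTMetadResult:
    """Parallel-tempering (metadynamics) over a temperature ladder.

    ``systems`` is one :class:`ToySystem` shared by all slots or a list with
    one per slot.  Exchange attempts occur every ``exchange_stride`` steps
    (0 disables them) between ladder neighbors, alternating even/odd pairs
    each epoch; every attempt is logged.  ``params`` None runs plain
    (unbiased) parallel tempering.  Each slot keeps its own hill store and
    its own substream of the seed.  Returned trajectories are per
    temperature slot (demultiplex with :func:`demux`).
    """
    ladder = tuple(float(t) for t in ladder)
    if len(ladder) < 2:
        raise ValueError("ladder needs at least 2 temperatures")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be sorted in strictly increasing order")
    n_rep = len(ladder)
    if isinstance(systems, ToySystem):
        systems = [systems] * n_rep
    if len(systems) != n_rep:
        raise ValueError(f"need one system per ladder slot ({n_rep}), got {len(systems)}")
    if params is not None and params.temperature not in ladder:
        # per-slot temperature overrides params.temperature below; nothing to check
        pass
    seqs = np.random.SeedSequence(seed).spawn(n_rep + 1)
    swap_rng = np.random.default_rng(seqs[-1])
    walkers = []
    for k in range(n_rep):
        slot_params = (
            dataclasses.replace(params, temperature=ladder[k]) if params is not None else None
        )
        walkers.append(
            _Walker(systems[k], cv, slot_params, ladder[k], dt, friction, seqs[k], x0)
        )
    events: list[ExchangeEvent] = []
    epoch = 0
    for step in range(n_steps + 1):
        if step % sample_stride == 0:
            for w in walkers:
                s, v = w.sample_now()
                w.record(step * dt, s, v)
        if step == n_steps:
            break
        if exchange_stride > 0 and step > 0 and step % exchange_stride == 0:
            parity = epoch % 2
            epoch += 1
            for a in range(parity, n_rep - 1, 2):
                b = a + 1
                wa, wb = walkers[a], walkers[b]
                sa, va_sa = wa.sample_now()
                sb, vb_sb = wb.sample_now()
                va_sb, _ = wa.store.evaluate(sb)
                vb_sa, _ = wb.store.evaluate(sa)
                ua = wa.system.potential(wa.x)
                ub = wb.system.potential(wb.x)
                ok = pt_exchange_attempt(
                    ua, ub, va_sa, va_sb, vb_sb, vb_sa, ladder[a], ladder[b], swap_rng
                )
                if ok:
                    wa.x, wb.x = wb.x, wa.x
                events.append(ExchangeEvent(step * dt, a, b, ok))
        for w in walkers:
            w.step(step, dt)
    return PTMetadResult([w.result() for w in walkers], ExchangeLog(ladder, events))


# ---------------------------------------------------------------------------
# Demultiplexing.
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DemuxResult:
    """Piecewise-constant slot occupancy of each continuous replica.

    ``slot_of_replica[e, r]`` is the temperature slot of continuous replica r
    after the first ``e`` events; row 0 is the identity.  ``times`` are the
    event times (the assignment changes at accepted events only).
    """

    times: np.ndarray
    slot_of_replica: np.ndarray

    @property
    def final_permutation(self) -> np.ndarray:
        return self.slot_of_replica[-1]


def demux(log: ExchangeLog, n_replicas: int | None = None) -> DemuxResult:
    """Compose the accepted swaps into continuous-replica slot assignments.

    Starting from the identity (replica r at slot r), each accepted event
    swaps the two replicas occupying slots a and b.  At every time point the
    assignment is a permutation (each slot holds exactly one replica).
    """
    n = len(log.ladder) if n_replicas is None else int(n_replicas)
    for ev in log.events:
        if not (0 <= ev.slot_a < n and 0 <= ev.slot_b < n):
            raise ValueError(f"event references slot outside [0, {n})")
    slot_of = np.arange(n)
    replica_at = np.arange(n)          # inverse permutation: slot -> replica
    rows = [slot_of.copy()]
    times = []
    for ev in log.events:
        times.append(ev.time)
        if ev.accepted:
            ra, rb = replica_at[ev.slot_a], replica_at[ev.slot_b]
            slot_of[ra], slot_of[rb] = ev.slot_b, ev.slot_a
            replica_at[ev.slot_a], replica_at[ev.slot_b] = rb, ra
        rows.append(slot_of.copy())
    return DemuxResult(np.asarray(times, dtype=float), np.asarray(rows))


# ---------------------------------------------------------------------------
# Exchange-log text format: "time slot_a slot_b accepted".
# ---------------------------------------------------------------------------

def write_exchange_log(log: ExchangeLog, path):
    from pathlib import Path

    path = Path(path)
    lines = [
        "# ladder_K " + " ".join(format(t, ".17g") for t in log.ladder),
        "# time slot_a slot_b accepted",
    ]
    for ev in log.events:
        lines.append(
            f"{format(ev.time, '.17g')} {ev.slot_a} {ev.slot_b} {int(ev.accepted)}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_exchange_log(path) -> ExchangeLog:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# ladder_K"):
        raise ValueError(f"{path}: missing '# ladder_K' header")
    ladder = tuple(float(t) for t in lines[0].split()[2:])
    events = []
    for ln in lines[1:]:
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        t, a, b, acc = ln.split()
        events.append(ExchangeEvent(float(t), int(a), int(b), bool(int(acc))))
    return ExchangeLog(ladder, events)
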