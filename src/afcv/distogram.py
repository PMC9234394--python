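"""Distance-probability tensors ("distograms") and their bin geometry.

An AlphaFold-style structure model attaches to every residue pair (i, j) a
probability distribution over M discretized inter-residue distance bins,
stored as an N x N x M tensor of logits or probabilities.  This module loads
such tensors from open serializations, converts logits to per-pair
probabilities (softmax along the bin axis), symmetrizes them, and validates
the result.  Everything downstream (the collective variable, the exported
sampling input) consumes the :class:`Distogram` produced here.

Lengths are nanometres throughout; Angstrom values are converted at I/O
boundaries only.  Diagonal entries (i == j) carry no information and are
ignored by all consumers.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import softmax

#: Default bin range quoted for the AlphaFold distogram head: 2 A to 22 A.
DEFAULT_LOWER_NM = 0.2
DEFAULT_UPPER_NM = 2.2
DEFAULT_NBINS = 64

_NORM_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class BinGeometry:
    """Uniform distance-bin layout of a distogram.

    Parameters
    ----------
    m : int
        Number of bins (>= 2).
    lower, upper : float
        Inner edge of the first bin and outer edge of the last bin, in nm.

    Bin centers sit at ``lower + (k + 0.5) * (upper - lower) / m``; the
    open-ended last bin of the original model is represented by a finite
    center strictly inside ``[lower, upper]``.
    """

    m: int
    lower: float = DEFAULT_LOWER_NM
    upper: float = DEFAULT_UPPER_NM

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 2:
            raise ValueError(f"need at least 2 bins, got m={self.m}")
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise ValueError("bin range must be finite")
        if not self.lower < self.upper:
            raise ValueError(
                f"lower edge must be below upper edge, got [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        """Bin width (upper - lower) / m in nm."""
        return (self.upper - self.lower) / self.m

    @property
    def centers(self) -> np.ndarray:
        """Array of the m bin-center distances in nm."""
        return self.lower + (np.arange(self.m) + 0.5) * self.width

    def bin_index(self, d) -> np.ndarray:
        """Index of the bin containing distance ``d`` (nm), clamped to [0, m-1]."""
        k = np.floor((np.asarray(d, dtype=float) - self.lower) / self.width)
        return np.clip(k, 0, self.m - 1).astype(int)


@dataclasses.dataclass
class Distogram:
    """Symmetric, per-pair-normalized distance-probability tensor.

    ``probs[i, j, k]`` is the model probability that residues i and j lie at
    a distance inside bin k.  Off-diagonal pairs must be normalized along the
    bin axis and symmetric in (i, j); diagonal entries are ignored.
    """

    probs: np.ndarray
    geometry: BinGeometry
    residue_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 3 or probs.shape[0] != probs.shape[1]:
            raise ValueError(f"expected an N x N x M tensor, got shape {probs.shape}")
        if probs.shape[2] != self.geometry.m:
            raise ValueError(
                f"tensor has {probs.shape[2]} bins but geometry declares {self.geometry.m}"
            )
        n = probs.shape[0]
        off = ~np.eye(n, dtype=bool)
        block = probs[off]
        if not np.isfinite(block).all():
            raise ValueError("distogram contains non-finite probabilities")
        if block.min() < -1e-12 or block.max() > 1.0 + 1e-12:
            raise ValueError("distogram probabilities must lie in [0, 1]")
        sums = probs.sum(axis=2)[off]
        if np.abs(sums - 1.0).max() > _NORM_TOL:
            raise ValueError(
                "per-pair probabilities do not sum to 1 "
                f"(max error {np.abs(sums - 1.0).max():.3g})"
            )
        asym = np.abs(probs - probs.transpose(1, 0, 2)).max()
        if asym > 1e-8:
            raise ValueError(
                f"distogram is not symmetric (max asymmetry {asym:.3g}); "
                "symmetrize before construction"
            )
        if self.residue_labels is not None:
            self.residue_labels = tuple(str(s) for s in self.residue_labels)
            if len(self.residue_labels) != n:
                raise ValueError("residue_labels length must equal residue count")
        self.probs = probs

    @property
    def n(self) -> int:
        """Residue count."""
        return self.probs.shape[0]


def symmetrize(probs: np.ndarray) -> np.ndarray:
    """Average ``probs[i, j, :]`` with ``probs[j, i, :]``.  Idempotent."""
    probs = np.asarray(probs, dtype=float)
    return 0.5 * (probs + probs.transpose(1, 0, 2))


def logits_to_probabilities(logits: np.ndarray, geometry: BinGeometry) -> Distogram:
    """Convert a logit tensor to a normalized, symmetric :class:`Distogram`.

    The conversion is a per-pair softmax along the bin axis (max-subtracted
    for stability, which makes the result invariant under per-pair additive
    shifts of the logits), followed by arithmetic-mean symmetrization.
    """
    logits = np.asarray(logits, dtype=float)
    if logits.ndim != 3 or logits.shape[0] != logits.shape[1]:
        raise ValueError(f"expected an N x N x M logit tensor, got shape {logits.shape}")
    if logits.shape[2] != geometry.m:
        raise ValueError(
            f"logit tensor has {logits.shape[2]} bins but geometry declares {geometry.m}"
        )
    bad = ~np.isfinite(logits)
    if bad.any():
        i, j, _ = np.argwhere(bad)[0]
        raise ValueError(f"non-finite logits for residue pair ({i}, {j})")
    probs = softmax(logits, axis=2)
    return Distogram(symmetrize(probs), geometry)


@dataclasses.dataclass(frozen=True)
class DistogramDiagnostics:
    """Per-pair health report of a distance-probability tensor.

    All arrays are N x N with the diagonal set to NaN.  ``asymmetry`` is the
    max-norm difference between the (i, j) and (j, i) rows of the tensor as
    given, i.e. before any symmetrization.
    """

    normalization_error: np.ndarray
    asymmetry: np.ndarray
    entropy: np.ndarray

    @property
    def max_normalization_error(self) -> float:
        return float(np.nanmax(self.normalization_error))

    @property
    def max_asymmetry(self) -> float:
        return float(np.nanmax(self.asymmetry))


def validate_distogram(d: "Distogram | np.ndarray") -> DistogramDiagnostics:
    """Report per-pair normalization error, asymmetry and entropy.

    Accepts either a :class:`Distogram` or a raw N x N x M tensor (useful for
    inspecting a tensor before symmetrization).  Never mutates its input.
    """
    probs = d.probs if isinstance(d, Distogram) else np.asarray(d, dtype=float)
    n = probs.shape[0]
    norm_err = np.abs(probs.sum(axis=2) - 1.0)
    asym = np.abs(probs - probs.transpose(1, 0, 2)).max(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    ent = -plogp.sum(axis=2)
    diag = np.eye(n, dtype=bool)
    for arr in (norm_err, asym, ent):
        arr[diag] = np.nan
    return DistogramDiagnostics(norm_err, asym, ent)


# ---------------------------------------------------------------------------
# Serialization: tensor archive (.npz) and tabular text.
# ---------------------------------------------------------------------------

def save_distogram(d: Distogram, path, format_tag: str = "tensor-archive") -> Path:
    """Write a distogram; returns the path actually written.

    ``tensor-archive`` is a compressed NumPy ``.npz`` container with named
    arrays ``probs``, ``bin_lower_nm``, ``bin_upper_nm``, ``n``, ``m`` and
    optional ``labels``; it round-trips probabilities bit-exactly.
    ``tabular-text`` is the human-readable sidecar format (17 significant
    digits, also lossless for doubles).
    """
    path = Path(path)
    if format_tag == "tensor-archive":
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        payload = {
            "probs": d.probs,
            "bin_lower_nm": np.float64(d.geometry.lower),
            "bin_upper_nm": np.float64(d.geometry.upper),
            "n": np.int64(d.n),
            "m": np.int64(d.geometry.m),
        }
        if d.residue_labels is not None:
            payload["labels"] = np.asarray(d.residue_labels)
        np.savez_compressed(path, **payload)
        return path
    if format_tag == "tabular-text":
        path.write_text(format_tabular(d))
        return path
    raise ValueError(f"unknown distogram format {format_tag!r}")


def format_tabular(d: Distogram) -> str:
    """Tabular-text serialization: header ``# n m lower_nm upper_nm`` then one
    whitespace-separated line ``i j p_1 ... p_M`` per pair i < j (1-based)."""
    g = d.geometry
    lines = [f"# {d.n} {g.m} {g.lower:.17g} {g.upper:.17g}"]
    for i in range(d.n):
        for j in range(i + 1, d.n):
            row = " ".join(format(p, ".17g") for p in d.probs[i, j])
            lines.append(f"{i + 1} {j + 1} {row}")
    return "\n".join(lines) + "\n"


def _parse_tabular(text: str) -> Distogram:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].lstrip().startswith("#"):
        raise ValueError("tabular distogram must start with a '# n m lower_nm upper_nm' header")
    header = lines[0].lstrip("#").split()
    if len(header) != 4:
        raise ValueError(f"malformed tabular header: {lines[0]!r}")
    n, m = int(header[0]), int(header[1])
    geometry = BinGeometry(m, float(header[2]), float(header[3]))
    # Diagonal entries are irrelevant; fill everything uniform, then overwrite.
    probs = np.full((n, n, m), 1.0 / m)
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != m + 2:
            raise ValueError(f"expected {m + 2} columns, got {len(parts)}: {ln[:60]!r}")
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        row = np.array([float(x) for x in parts[2:]])
        probs[i, j] = probs[j, i] = row
    return _finalize_loaded(probs, geometry, None)


def _finalize_loaded(probs, geometry, labels) -> Distogram:
    probs = np.asarray(probs, dtype=float)
    if np.isnan(probs).any():
        raise ValueError("distogram file contains NaN entries")
    n = probs.shape[0]
    off = ~np.eye(n, dtype=bool)
    sums = probs.sum(axis=2)
    if (sums[off] <= 0).any():
        raise ValueError("distogram file contains non-positive per-pair mass")
    asym = np.abs(probs - probs.transpose(1, 0, 2)).max()
    if asym > 1e-12:
        warnings.warn(
            f"asymmetric distogram (max asymmetry {asym:.3g}); symmetrizing",
            stacklevel=3,
        )
        probs = symmetrize(probs)
        sums = probs.sum(axis=2)
    # renormalize only when needed so clean archives round-trip bit-exactly
    if np.abs(sums[off] - 1.0).max() > _NORM_TOL:
        probs = probs / probs.sum(axis=2, keepdims=True)
    return Distogram(probs, geometry, labels)


def load_distogram(path, format_tag: str | None = None) -> Distogram:
    """Load and validate a distogram from disk.

    ``format_tag`` is one of ``tensor-archive`` / ``tabular-text``; when
    omitted it is inferred from the suffix (``.npz`` -> archive).  Archives
    storing ``logits`` are converted through
    :func:`logits_to_probabilities`; stored probabilities are symmetrized
    (with a warning) and renormalized.  When the archive carries no bin
    geometry the default 64-bin [0.2, 2.2] nm layout is assumed; that default
    is refused for any other bin count.
    """
    path = Path(path)
    if format_tag is None:
        format_tag = "tensor-archive" if path.suffix == ".npz" else "tabular-text"
    if format_tag == "tabular-text":
        return _parse_tabular(path.read_text())
    if format_tag != "tensor-archive":
        raise ValueError(f"unknown distogram format {format_tag!r}")

    with np.load(path, allow_pickle=False) as archive:
        keys = set(archive.files)
        if "logits" in keys:
            tensor, is_logits = np.asarray(archive["logits"], dtype=float), True
        elif "probs" in keys:
            tensor, is_logits = np.asarray(archive["probs"], dtype=float), False
        else:
            raise ValueError(f"{path} declares neither 'probs' nor 'logits'")
        m = tensor.shape[2] if tensor.ndim == 3 else -1
        if "bin_lower_nm" in keys and "bin_upper_nm" in keys:
            geometry = BinGeometry(m, float(archive["bin_lower_nm"]), float(archive["bin_upper_nm"]))
        elif m == DEFAULT_NBINS:
            geometry = BinGeometry(DEFAULT_NBINS, DEFAULT_LOWER_NM, DEFAULT_UPPER_NM)
        else:
            raise ValueError(
                f"{path} has {m} bins but no bin geometry; the default geometry "
                f"only applies to m={DEFAULT_NBINS}"
            )
        for key, expect in (("n", tensor.shape[0]), ("m", m)):
            if key in keys and int(archive[key]) != expect:
                raise ValueError(f"{path}: declared {key}={int(archive[key])} but tensor says {expect}")
        labels = tuple(str(s) for s in archive["labels"]) if "labels" in keys else None

    if is_logits:
        d = logits_to_probabilities(tensor, geometry)
        return Distogram(d.probs, geometry, labels)
    return _finalize_loaded(tensor, geometry, labels)
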