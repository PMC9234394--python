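# Methods

## The score and its smooth form

A distogram assigns each residue pair (i, j) a probability row D[i, j, ·]
over M distance bins with centers d_k = lower + (k + ½)(upper − lower)/M.
Given Cα coordinates, the discrete expected-match score sums, over included
pairs, the probability of the bin each pair distance occupies; by linearity
of expectation it is the expected number of pair distances consistent with
the model.  Distances below the binned range map to the first bin, at or
above the upper edge to the last.  The open-ended last bin of the original
network head is represented by a finite center strictly inside the range;
bin geometry is always explicit and recorded in output files, so a user can
supply the network's exact internal edges instead.

The biasable form replaces the hard bin indicator with a normalized
Gaussian-kernel interpolant (the one-dimensional specialization of a path
variable):

P_ij(d) = Σ_k D[i,j,k] e^{−λ(d−d_k)²} / (ε + Σ_k e^{−λ(d−d_k)²}).

Properties used throughout the tests: P is continuous and differentiable in
d, bounded in [0, 1); for a uniform row it is exactly 1/M wherever the
kernels have support; as λ → ∞ with distances at bin centers it converges to
the discrete score.  The CV is the sum of P_ij over the pair mask, its
gradient the chain-rule accumulation of dP/dd along pair unit vectors,
which makes it exactly translation- and rotation-invariant and gives a
per-structure gradient that sums to zero over residues.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ | 1000 | nm⁻² | kernel sharpness; larger tracks the bins more strictly |
| ε | 1e-10 | — | denominator pseudocount; prevents 0/0 when d leaves the binned range while leaving in-range values unchanged to > 9 digits |
| min_separation | 1 | — | smallest \|i−j\| included; adjacent-pair terms are nearly constant and can be excluded |
| subset | none | — | optional residue set for a focused variant of the score |
| bins | 64 over [0.2, 2.2] nm | — | default geometry; configurable |

With ε = 0 the ratio is undefined once every kernel underflows (roughly
\|d − d_k\| > 0.86 nm at λ = 1000 nm⁻² in double precision); ε exists
precisely to remove that singularity, so closed-form identities that assume
ε = 0 only hold for in-range distances.

Distances are measured between Cα atoms even though distogram heads are
trained on Cβ-referenced distances; this is a deliberate fidelity choice
(the workflow the package mirrors does the same) and is invisible to the
synthetic fixtures, which define their distograms on the same atoms they
score.

## Degenerate inputs and numerics

* Coincident residues (d = 0): the pair still contributes P(0) to the value
  (continuity) but zero gradient — the direction is undefined — with a
  warning.
* Logit conversion is a max-subtracted softmax per pair, hence invariant
  under per-pair additive shifts; tensors are symmetrized by arithmetic
  mean after the softmax and validated to per-pair normalization 1e-9.
* Loaders renormalize only when a file's rows are off by more than 1e-9,
  so clean archives round-trip bit-identically.
* All text formats print 17 significant digits, making write → parse →
  write byte-identical; that idempotence is the round-trip contract the
  tests enforce.
* Kernel evaluations are computed once per pair and shared between the
  value, the normalization and the derivative.

## The toy sampler

The sampler exists to exercise the CV as a bias, not to be an MD engine,
so it uses the simplest correct dynamics: overdamped Langevin,
x ← x − (dt/γ_f)∇U + √(2 k_B T dt/γ_f) ξ, with k_B = 0.0083144621
kJ mol⁻¹ K⁻¹ and an explicitly seeded generator (bitwise reproducible; the
Euler–Maruyama discretization inflates stationary variances by O(k dt/γ_f),
which the equipartition tests account for by keeping k dt small).

Well-tempered metadynamics deposits a Gaussian hill every
`deposition_stride` steps at the current CV value with height
w₀ e^{−V(s)/(k_B ΔT)}, ΔT = (γ − 1)T; the first hill is exactly w₀ and
heights at a fixed CV point are nonincreasing.  Defaults (w₀ = 0.5 kJ/mol,
σ = 0.1, γ = 8) follow the mini-protein study this package accompanies.

Parallel tempering swaps coordinates between ladder neighbors, alternating
even/odd pairs each epoch, with acceptance
min(1, exp[(β_i−β_j)(U_i−U_j) + β_i(V_i(s_i)−V_i(s_j)) + β_j(V_j(s_j)−V_j(s_i))]);
the bias cross-terms make the criterion exact when each replica carries its
own metadynamics bias, and it reduces to plain parallel tempering when the
biases vanish.  The published exchange criterion of the original study is
not printed there; this choice is the package's own.  Each replica draws
from its own SeedSequence substream.  The default demo ladder is the
32-temperature geometric-like ladder 278–595 K used in the original
simulations.

Demultiplexing composes accepted swaps into the slot occupancy of each
continuous replica, starting from the identity; it is an exact integer
permutation at every time point, and the tests verify that walking the
events backwards restores the identity.

## Free-energy analysis

`fes_from_hills` sums the bias on a grid and applies the well-tempered
estimator F = −(γ/(γ−1))V (the Metadynminer convention; the plain
estimator −V applies when hills carry no bias factor), shifts the visited
minimum to zero, and flags nodes further than 5σ from every hill as
unvisited (NaN, excluded from integrals).  `fes_time_average` averages the
pre-shift estimator over the last half of the depositions (20 checkpoints
by default): the instantaneous well-tempered estimate keeps fluctuating
around the true profile even after convergence in the mean, and tail
averaging suppresses that variance without biasing the profile — on the
15 kJ/mol double-well benchmark it roughly halves the error of the
well-to-well free-energy difference.

`folded_fraction` integrates e^{−F/k_BT} with trapezoidal node weights on
either side of a CV threshold; each node is assigned wholly to one side, so
the two fractions sum to one exactly.  For this CV the folded state lies
*above* the threshold (a well-matched structure scores high); threshold and
side are always explicit arguments — the 4.75 value used in the melting
tests is an input, not something the package infers.  Melting temperature
is the linear interpolation of the 0.5 crossing of folded fraction versus
temperature; curves that never cross return the nearest ladder end with a
flag, multiple crossings use the first with a warning.

Clustering is the iterative largest-neighborhood algorithm under a pairwise
superposition-RMSD cutoff (ties toward the lower frame index), with
superposition by centering plus the optimal proper rotation (reflections
excluded, as appropriate for chiral molecules).

## Synthetic data: what it does and does not show

`synthetic_distogram` places, for each pair, a discretized Gaussian at the
reference distance (σ = `concentration`, default 0.02 nm) mixed with a
uniform background (default 1%), renormalized per pair.  It emulates one
property of a confident prediction — per-pair probability mass concentrated
near the true distances with pair-dependent but narrow widths — and none of
the others: no correlation structure between pairs, no Cβ reference, no
secondary-structure-dependent width patterns, no systematically wrong
pairs.  Tests passing on these fixtures therefore demonstrate the
correctness of the machinery (scores, gradients, bias mechanics, analysis),
not the biophysical performance of the CV on real proteins, which requires
all-atom simulation beyond desk scale.

The toy polymer is a harmonic chain (stiffness 1000 kJ/mol/nm², bond
0.38 nm — the Cα–Cα virtual bond length), soft excluded volume below
0.25 nm, and a weak pair-distance attraction toward a seeded compact
self-avoiding reference; all terms vanish at the reference, making it the
known global minimum at zero energy.  The double well
U(s) = B((s/a)²−1)² provides an analytic one-dimensional free-energy
surface with minima at ±a and barrier B.

## Benchmark problem sizes

The validation suite runs the double-well recovery with 10⁶ Langevin steps
(dt = 0.0005 ps, hills every 500 steps → 2000 hills) at 300 K with the
default hill parameters; parallel-tempering statistics use 10⁵ closed-form
exchange draws and 1.5–2 × 10⁵ two-replica steps; gradient accuracy uses
100 random 10-residue instances against central differences.  These sizes
give statistical errors comfortably inside the asserted tolerances (FES RMS
≈ 0.3 kJ/mol against a 1 kJ/mol bound) while keeping the whole suite under
a minute of compute for the sampler-heavy parts.

## Known limitations

* The exported input dialect is self-defined: the keyword set of the
  original Plumed extension is not published, so interoperability with an
  actual Plumed build is not claimed (and not tested).
* Raw CV magnitudes from the original all-atom study cannot be reproduced
  without the original distogram; validation is property-based.
* The sampler has no inertia, constraints or solvent; binary trajectory
  formats are out of scope.
* `folded_fraction` supports one-dimensional surfaces only; two-CV
  surfaces can be reconstructed but not yet integrated by state.
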