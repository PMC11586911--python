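# Methods

This note records the models, estimators and numerical choices behind
the package, what the synthetic generators do and do not emulate, and
the design decisions taken where more than one reasonable construction
existed.

## Conformational free energy and torsion maps

The dyad-distance free energy is the Boltzmann inversion of the sampled
distribution,

    ΔG(dd_Asp) = −RT ln P(dd_Asp),     R = 1.9872041×10⁻³ kcal/(mol·K),

estimated per histogram bin and shifted so the global minimum is zero.
The estimator is deliberately a plain histogram (no kernel smoothing):
bin width defaults to 0.1 Å and is configurable; edges are aligned to
integer multiples of the width so profiles from different runs share a
lattice. Empty bins are reported as NaN ("unsampled"), never as +∞, so
downstream arithmetic has to handle missing support explicitly.
Torsion-pair maps use 72 × 72 cells (5°) on (−180°, 180°]²; angles are
wrapped periodically before binning so samples either side of ±180° land
in adjacent wrap-around cells. Extremum detection is a discrete
neighbour scan; equal-value plateaus collapse to their centre bin, and
the barrier between two minima is the maximum bin between them.

The default temperature everywhere is 303.15 K, the simulation
temperature of the data this pipeline targets.

## Geometry conventions

Torsions follow the IUPAC convention and agree with MDAnalysis'
`calc_dihedrals` sign exactly (verified in the test suite). One
consequence worth stating: the standard torsion is *symmetric* under
chain reversal, dihedral(a,b,c,d) = dihedral(d,c,b,a); it is negated
only under improper operations (mirror reflection). The hydrogen-bond
predicate is donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor angle
≥ 135°, both configurable. The 3.5 Å default matches the only printed
distance criterion in the analysis this package implements (the
lytic-water proximity cutoff); the angle term is the common MD-analysis
convention — treat both as stand-ins where a source protocol specifies
otherwise. Residue numbering follows the 6IYC author numbering (dyad
D257/D385, substrate T48–M51), but every atom selector is config-driven.

## Active-state classification

A frame is active when (1) the protonated Asp donates a hydrogen bond to
the scissile carbonyl oxygen, (2) the lytic water oxygen is within
3.5 Å of the carbonyl carbon, (3) one water hydrogen is hydrogen-bonded
to the deprotonated Asp, and — for the double-bridged tier only —
(4) the *other* water hydrogen is bonded to the protonated Asp.
Frames satisfying all four criteria are assigned to the stricter
double-bridged tier; criteria 1–3 with criterion 4 false give the
single-bridged tier. Sub-state letters are resolved from which
carboxylate oxygen participates: i = inner (OD1), o = outer (OD2); the
first slot of a label comes from the criterion-4 bond ("no" when it is
absent), the second from the criterion-3 bond. The canonical label sets
enumerate {i, no} × {i, o} per protonated system; a criterion-4 bond via
the outer oxygen would generate an 'o' first slot, which the classifier
constructs generically even though it does not occur in the canonical
eight.

Occupancy tables keep exact probabilities (count/Ns) and present them
rounded half-away-from-zero to 4 decimals. Representative structures
are medoids: the frame minimising the mean pairwise RMSD (after optimal
Kabsch superposition, heavy atoms of the dyad plus the scissile-bond
residues) to all other active frames, ties broken to the lowest frame
id. Hydrogens are excluded from the RMSD region since constraint-driven
MD hydrogens carry no independent information.

## Umbrella windows and seeding

The production grid spans CV1 ∈ [−2.0, 2.0] Å and CV2 ∈ [−2.0, 1.5] Å
at 0.1 Å spacing, endpoints included: 41 × 36 = 1476 windows. Window i
is seeded with the exploratory sample j minimising

    v_i(j) = (CV1_j − CV1_i,ref)² + (CV2_j − CV2_i,ref)²,

ties broken to the smallest j. The squared-Euclidean form is the
natural isotropic choice; the metric exponent and per-CV weights are
exposed for anisotropic variants. Force constants default to
100 kcal/(mol·Å²) per CV and are config inputs throughout.

## WHAM

The 2D PMF is reconstructed by direct iteration of the standard WHAM
equations,

    p(x) = Σᵢ nᵢ(x) / Σᵢ Nᵢ exp[(fᵢ − Uᵢ(x))/kT]
    fᵢ  = −kT ln Σₓ p(x) exp[−Uᵢ(x)/kT],

with the gauge fixed by f₁ = 0 and all sums accumulated in the log
domain (`scipy.special.logsumexp`), so stiff biases and low temperatures
do not underflow. Convergence is declared when max|Δfᵢ| < tolerance
(default 10⁻⁵ kcal/mol); applying the criterion to cell probabilities
instead is supported via config, since either reading of a bare "10⁻⁵"
is defensible. The iteration cap is 10⁵; a non-converged fit is
returned with `converged=False` and a warning, never silently. Cells no
window sampled are excluded from the fᵢ sums and reported unsampled.
Histogram cells default to the window spacing (0.1 Å), independently
configurable per axis.

Block convergence follows the 2-ps convention: each window's series is
cut into consecutive 2-ps blocks (a 10-ps series gives 0–2, …, 8–10),
WHAM runs per block, and the deviation between consecutive blocks is the
maximum absolute difference over their common occupied cells after
min-shifting each block's PMF on those cells.

## Minimum free-energy path

On a discrete surface the MFEP between two basins is taken as the
8-connected path minimising the maximum free energy encountered
(minimax / watershed criterion); among minimax-equal paths the one with
the smallest summed free energy is preferred. This is the standard MFEP
definition on gridded landscapes and reproduces what node-exploration
tools report for well-separated basins; 4-connectivity is available but
produces staircase artifacts. The search is a Dijkstra variant with
lexicographic (bottleneck, sum) costs. Unsampled cells are impassable.
RS and GD are the path endpoints, TS the profile maximum between them,
barrier = G(TS) − G(RS); the path is flagged "concerted" when no strict
local minimum of the profile precedes the TS. The barrier is invariant
under a constant shift of the surface; the node sequence need not be,
because the summed-energy tie-break adds (constant × path length) and
can re-rank minimax-equal paths of different lengths.

State centres (RS/TS/GD CV coordinates) are configuration inputs rather
than constants: the source protocols report slightly different TS CV1
values per protonated system, so snapshot selection takes the centre
and a ±0.1 Å box as parameters, with uniform-stride down-selection to
150 snapshots per state when more qualify.

## Per-residue decomposition

For residue i and one snapshot,

    ΔE_i = (E_QM/MM − E_QM)_residue − (E_QM/MM − E_QM)_Gly,

and the stabilization effect is ΔΔE_i = ⟨ΔE_i⟩_TS − ⟨ΔE_i⟩_RS with
SE² = s²_TS/n_TS + s²_RS/n_RS. Negative ΔΔE means the residue lowers
the barrier. The module consumes precomputed energy tables; it performs
no QM, no structure mutation, and no free-energy (as opposed to energy)
decomposition. Any per-snapshot constant added to all four energies
cancels exactly — the gauge invariance the tests assert. The residue
scope (e.g. "all residues within 5 Å of the reactive region") is an
input list, since it depends on structural context the tables do not
carry.

## Synthetic generators

The generators provide every pipeline input with known ground truth at
desk scale. The sampler is Metropolis Monte Carlo (uniform proposals,
10% burn-in discarded) rather than Langevin dynamics: at these problem
sizes exactness of the stationary distribution matters more than
kinetic realism, and the umbrella generator runs all windows in
lock-step vectorised sweeps. Model surfaces: harmonic; 1D/2D double
wells with closed-form minima and saddle (the 2D form
V = h(x²−1)² + ½k_y y² has its saddle exactly at height h); a tilted
double well; and a three-well Gaussian-mixture potential with minima at
4.5 / 7.0 / 8.5 Å emulating the dyad-distance landscape. Quadrature
references (per-bin Boltzmann integrals) serve as the oracles histogram
estimators are tested against.

Geometry frames are built top-down from the planted sub-state: bond
distances/angles are drawn inside the passing region for criteria the
sub-state requires and inside the failing region otherwise, so a correct
classifier recovers planted fractions up to multinomial noise. Energy
tables plant per-residue effects with N(0, σ) noise (σ = 0.3 kcal/mol,
150 snapshots/state by default) and random per-snapshot gauge offsets.
Structure fixtures are small synthetic active-site sketches — not
coordinates from any deposited structure — sufficient to exercise the
reader and feature extractor.

What the generators do *not* emulate: atomistic force fields, membrane
environment, autocorrelated dynamics (beyond what Metropolis chains
have), metadynamics hill deposition, or QM energetics. Passing tests
therefore demonstrate estimator correctness — that WHAM, the MFEP
search, the classifier and the decomposition recover known ground truth
from data with the right statistical structure — not that any specific
enzyme simulation is converged.

## Problem sizes and determinism

Default verification sizes were chosen so the whole suite runs in well
under a minute of sampling: 20 × 20 windows × 5 × 10³ steps for barrier
recovery (recovered 2.0 ± 0.06 kcal/mol across seeds against the
analytic 2.0), 10³ frames for classifier equivalence, 150
snapshots/state for decomposition recovery, 25 windows × 2.5 × 10³ steps
for block convergence. Every generator takes an explicit seed and is
byte-deterministic for a fixed seed; the pipeline manifest records
per-stage parameter hashes so unchanged stages are skipped on rerun and
identical configs reproduce identical outputs.

## Known limitations

* WHAM direct iteration can converge slowly for strongly overlapping
  stiff windows; no MBAR estimator is provided.
* The MFEP is grid-resolution-limited; barriers carry one-cell
  discretization error and no continuous-space refinement (string
  method, NEB) is attempted.
* The classifier trusts the hydrogen-bond geometry labels it is given;
  it does not re-derive donor/acceptor identities from coordinates.
* Occupancy probabilities at the 10⁻⁴ scale need order 10⁶ frames for
  stable 4-decimal presentation; the synthetic defaults use inflated
  fractions at smaller n for that reason.
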