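# Methods

This note documents the models, parameter choices, numerical decisions, and
known limitations of `idpre`.

## System and scope

The package models a two-chain fuzzy complex: a long disordered chain
(default 311 residues) carrying short helical anchor motifs (defaults
"LD1" 3–14, "LD2" 144–155, "LD4" 263–274 — approximate boundaries inferred
from typical label/mutation sites, configurable), bound to a rigid
four-helix-bundle receptor with two binding faces (`a1a4`, `a2a3`).  Binding
is multistate: each bound state anchors exactly two motifs, one per face,
with LD2 engaged in every state (four states by default).  All coordinates
are coarse-grained to one bead (Cα) per residue; 0-based half-open index
ranges internally, native author numbering (receptor 892–1051) preserved at
every interface.

## PRE forward model

Per frame and label site, candidate electron positions are placed at a fixed
tether length (8 Å) from the attachment bead on a Fibonacci direction
lattice, Boltzmann-weighted by a soft-sphere clash energy
(min((σ/d)¹², 10³) kT with σ = 3.5 Å) against all other beads.  This
pseudo-rotamer construction is a deliberately simple stand-in for an atomistic
rotamer library: it reproduces the two features that matter downstream —
⟨r⁻³⟩/⟨r⁻⁶⟩ averaging and solvent-exposure asymmetry (buried directions get
vanishing weight) — and the `RotamerCloud` interface accepts arbitrary
positions/probabilities, so a real rotamer library can be plugged in.

Order parameters follow the standard decomposition
S² = S²_radial · S²_angular with S²_radial = ⟨r⁻³⟩²/⟨r⁻⁶⟩ and S²_angular the
second-rank order parameter of the r⁻³-weighted electron direction
distribution (computed from the 3×3 direction second-moment tensor).  For a
single rotamer both factors are exactly 1.

Physical parameters (all configurable on `PhysicalConstants`):

| parameter | default | meaning / rationale |
|---|---|---|
| field_mhz | 600 | ¹H spectrometer frequency; sets ω_I |
| tau_c | 29 ns | complex rotational correlation time; the 0.6 ns/kDa empirical rule at 47.8 kDa |
| tau_i | 500 ps | spin-label internal correlation time |
| tau_t | derived | 1/τ_t = 1/τ_c + 1/τ_i; the total-correlation-time rule (the combination is a modelling choice — only τ_i is usually quoted) |
| t_d | 10 ms | total INEPT transfer time attenuating intensity |
| r2_red | 40 s⁻¹ | diamagnetic transverse rate for a ~48 kDa complex |
| gamma2_cap | 450 s⁻¹ | truncation of inverted Γ2: below ratio ≈ 9×10⁻⁴ the ratio–Γ2 relation is flat and inversion is numerically meaningless |

The intensity relation is strictly decreasing, so inversion uses bracketed
Brent root-finding on [0, cap]; ratios ≥ 1 map to 0, ratios at or below the
cap's ratio (and nonpositive ratios) map to the cap.

## BME reweighting

Constraints are fitted as Γ2 values (after smoothing, inversion and capping),
not as intensity ratios — the exponential ratio–rate relation makes direct
ratio fitting badly conditioned.  The dual cost
C(λ) = log Z(λ) + Σλ_iΓ2ᵢ^exp + (θ/2)Σλ_i²σ_i² is minimized by L-BFGS after
standardizing the variables (u_i = λ_iσ_i), which makes the penalty spherical
and the constraint rows O(1); initialization is λ = 0 (deterministic), with
warm starts along the θ grid.  Convergence demands a small standardized
gradient (tolerance 10⁻⁸ scaled by the data magnitude, with a hard failure
threshold 10⁴ above it); weights are nonnegative and normalized by
construction of the exponential form.

Error model: σ_i² = scale / max(ratio_i, floor), defaults scale = 1 (Γ2²
units) and floor = 0.05, plus a constant-σ fallback mode.  The inverse form
encodes that small ratios map to large, unstable Γ2 values.  The absolute
scale is degenerate with θ (both multiply the same penalty), so the default
leaves it at 1; when the noise level is known, setting `error_scale` to the
propagated Γ2-space variance makes χ² interpretable on its usual scale (the
examples set `error_scale=10` for 5% multiplicative ratio noise).

θ selection: fits run along a decreasing log grid (default 10⁴ → 10⁻², 13
points) and the selected θ is the largest value for which a further 10×
decrease improves χ² by less than 5% relative — a quantified elbow rule.  A
flat χ²(θ) curve (data already consistent with the prior) therefore selects
the largest θ, i.e. minimal reweighting.

All states are pooled into a single reweighting problem with one shared
normalization; per-state populations are aggregates of the refined frame
weights over state labels.

LOESS smoothing of the experimental ratio profiles uses plain local linear
regression (span 0.2 per site, no robustness iterations — matching classic
gaussian-family LOESS; robustness reweighting would treat genuine PRE dips as
outliers).  Smoothed fitting is the default with a raw-data switch.

## Synthetic-data generator

The generator defines the study conditions for every test: it emulates a
multi-state fuzzy complex with known ground truth, not any particular force
field.

*Apo chains* are von-Mises–Fisher correlated walks (persistence length 6.5 Å)
with fixed 3.8 Å bonds, hard-sphere excluded volume (radius 2.0 Å, enforced
against the entire growing chain with bounded resampling and frame
regeneration; persistent infeasibility raises a diagnostic error), and rigid
ideal-helix geometry (2.3 Å radius, 1.5 Å rise, 100°/residue) at the motif
segments.  The persistence default places the mean Rg of the default chain
in the 52–59 Å window expected for a compact 311-residue disordered domain.

*Bound complexes* anchor each state's two motifs as rigid helices at the
receptor face anchor points (orientation jittered, center within the anchor
tolerance), bridge the intervening chain with persistent random walks sheared
to close on the far endpoint and projected to constant bond length by
iterative forward/backward (FABRIK-style) passes, and grow confined
persistent tails.  A pushout pass keeps flexible beads out of the receptor
core cylinder, followed by bond re-projection.  Loop persistence (12 Å) and
the confinement radius (70 Å) were calibrated once so the weighted mean
complex Rg lands at ~35 Å, the compaction a complex of this size shows by
small-angle scattering; they are ordinary keyword arguments thereafter.
An earlier design used crank-shaft/pivot Monte Carlo for this sampler; the
constrained-growth construction replaced it because it vectorizes across
frames and reaches the frame counts the validation experiments need in
seconds rather than hours, with the same physical content (fixed bonds,
persistence, excluded volume, anchoring).

*Observables*: PRE tables apply the package's own forward model under the
ground-truth frame weights, then multiplicative Gaussian noise clipped to
[0, 1.2] (experimental ratios slightly exceed 1); titrations apply the
quadratic depletion isotherm per motif residue over the 9-point 10–300 μM
ladder at 100 μM observed protein.  With zero noise both are exact fixed
points of the corresponding inverse analyses — the basis of the round-trip
tests.

What the generator does **not** emulate: atomistic side-chain packing,
sequence-specific intra-chain interactions (its loops form few persistent
intra-chain contacts, so state-specific contact lists on default synthetic
data are short), force-field energetics, and kinetics.  Passing tests
therefore demonstrate the correctness of the inference machinery, not the
realism of any particular ensemble.

## Landscape

Features are minimum Cα–Cα distances between consecutive 4-residue segments
(final partial segment retained — 78 segments for 311 residues) for pairs
with more than two segments strictly between (b − a ≥ 4), giving
n(n−1)/2 − (3n−6) features (2775 at n = 78).  PCA keeps the top 50
components (constant features dropped; fully degenerate input collapses to a
single zero component).  UMAP trains on a seeded random 10% subsample —
time-correlated trajectories otherwise dominate the embedding — and projects
the remaining frames into the trained space; training frames keep their
fitted coordinates by construction.  Clustering is Louvain community
detection (seeded, resolution 1.0) on a symmetrized 15-nearest-neighbour
graph over the PC coordinates.  Note the resolution limit of modularity:
components much larger than the neighbourhood size legitimately subdivide,
so the "one blob = one cluster" regime holds when blob size is comparable to
k.  Validation clusters the 2-D embedding with K-means at the same k and
compares partitions by ARI/AMI against permutation nulls (both indices have
expectation ≈ 0 under label shuffling).  Representative structures are the
frames nearest each cluster's embedding centroid.

## Contacts

A segment pair is in contact when the minimum bead–bead distance between the
two windows is at or below the cutoff — default 8 Å for Cα-only models
(4.5 Å would suit heavy-atom frames); the cutoff is a package choice,
recorded in the run summary.  Intra-chain maps omit pairs two segments apart
or closer.  Frequencies are weighted frame averages; per-state maps restrict
and renormalize the weights.  A contact is state-specific when its frequency
is ≥ 0.6 in one state and ≤ 0.2 in all others (thresholds shared with the
entropy contact classes).

## Entropy

Torsions: true φ/ψ on backbone (N, CA, C) frames (ω excluded as essentially
rigid), the Cα pseudo-dihedral on coarse chains.  Angles are histogrammed
into n = 35 bins of width h = 2π/35 rad under the ensemble weights (a quoted
"35 bins of 10°" is internally inconsistent — 350° ≠ 360° — so n = 35 is
honored and h follows).  The per-torsion estimator is
S = −[Σ P_i ln(P_i h) + (n−1)/(2N)] with N the raw frame count: note the
undersampling term is *subtracted* here, following the form used by the
reference analysis this package mirrors, whereas the conventional
Miller–Madow correction adds it; both are available
(`correction="subtracted" | "miller-madow" | "none"`), and since the term is
weight-independent it shifts profiles without reordering them.  Bin-width
units shift all entropies by the constant −ln h, leaving differences intact.
Residue entropy sums the residue's torsions; the energy form multiplies by
R·T at 310 K (2.577 kJ/mol per nat).  Contact-class comparisons use the
two-sided Wilcoxon rank-sum test on residues below 20% vs above 60% contact
frequency, with significance bands **, * (0.01–0.05), NS (> 0.05); groups
under 3 members skip the test with a flag.

## Titration

Fraction bound is read from intensity decay (fb = 1 − I/I₀, clipped to
[0, 1]) and fitted per residue with the single-site depletion isotherm
fb = [(P+L+K_d) − √((P+L+K_d)² − 4PL)]/(2P), because the observed protein
concentration (100 μM) is comparable to the fitted constants — the L ≫ P
hyperbola would bias them.  K_d is optimized in log space within (10⁻³, 10⁶)
concentration units; residues with fewer than three informative points are
flagged and excluded.  Motif summaries report mean ± sample (n−1) SD.
Units are carried as entered throughout.

## Problem sizes and determinism

The validation suite runs at desk scale: the flagship recovery experiment
uses 2000 frames per state (8000 total), four label sites, and all 311×4
residue rows, completing in ~3 minutes on one CPU; unit tests use tens to
hundreds of frames.  Every stochastic component (generators, UMAP, Louvain,
permutation nulls) takes an explicit seed, and fixed seeds give bit-identical
ensembles, embeddings, and cluster labels across runs.

## Known limitations

- The pseudo-rotamer label model ignores tether dihedral energetics and
  shares one direction lattice across frames (only the Boltzmann weights are
  frame-specific).
- Bound-state excluded volume is approximate: bridges and tails avoid the
  receptor core and their own recent history, not the full chain.
- The χ²(θ) elbow rule quantifies an otherwise qualitative choice; on noiseless data the
  curve is flat and the rule correctly selects minimal reweighting, but on
  real data the chosen θ should be inspected alongside the effective sample
  size.
- Entropy ignores correlations between torsions (no mutual-information
  correction) and solvent/vibrational contributions.
- Per-state analyses assume every frame carries a state label; unlabeled
  ensembles are treated as single-state.
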