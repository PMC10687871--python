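# Methods

## Pair-specific Lennard-Jones correction

All pair interactions use the A/R form of the 12-6 potential,
U(r) = ε[(R/r)¹² − 2(R/r)⁶], whose minimum is −ε exactly at r = R.
Unmodified pairs follow the Lorentz–Berthelot rules
(R_ij = R_i/2 + R_j/2, ε_ij = √(ε_i ε_j)); the NBfix correction
replaces R_ij of the H5–OR/OS and H4–OR/OS pairs by the
combination-rule value plus a signed offset, default −0.25 Å, and
never touches ε_ij (an ε override exists behind an explicit flag for
scanning experiments only).

Atom-type radii and well depths ship in `data/atom_types.yaml`:
H5 1.3590/0.0150, H4 1.4090/0.0150, OR 1.7718/0.1700 (the RNA OL3_CP
bridging-phosphate-oxygen revision), OS 1.6837/0.1700 (the DNA OL15
bridging/sugar oxygen).  The two donor radii differ by exactly
0.05 Å, which is why the corrected purine and pyrimidine minima sit
0.05 Å apart.  Because O3′ (and O4′ in DNA) share the bridging-oxygen
atom type, their pairs with H8/H6 inherit the correction; those atoms
sit systematically farther from the base protons, so the inherited
change is incidental and the reweighting machinery tracks the O5′
contact only by default.

Scan grids are inclusive arithmetic progressions; the endpoint is
accepted within half a step to absorb floating-point drift.  Patches
serialize to an AMBER frcmod-style LJEDIT block or a GROMACS
`[ nonbond_params ]` override (σ in nm, ε in kJ/mol); full-precision
values ride in end-of-line comments so the round trip is bit-exact.

## 0BPh geometry

A type-0 base–phosphate contact is intranucleotide: donor H8 (purine)
or H6 (pyrimidine) to the same residue's O5′.  A contact counts as
*formed* when the H···O5′ distance is within a cutoff **and** the
glycosidic torsion χ (O4′–C1′–N9–C4 purine, O4′–C1′–N1–C2
pyrimidine) is anti.  Choices the underlying geometry does not fix:

* syn/anti boundary: IUPAC, syn = χ ∈ [−90°, 90°), configurable;
* formed-distance cutoff: 3.2 Å, a weak C–H···O criterion,
  configurable — annotation reports raw distances so any cutoff can be
  re-applied;
* ensemble statistics use the population standard deviation, since a
  deposited multi-model bundle is a fixed set, not a sample;
* hydrogens must be present; no hydrogen inference is attempted;
  5′-terminal residues without a phosphate are flagged rather than
  dropped.

Sugar pucker uses the Altona–Sundaralingam pseudorotation phase from
the five furanose torsions ν0–ν4 (convention ν_j = τ_m·cos(P +
144°(j−2))); C3′-endo is P ∈ [0°, 36°), C2′-endo P ∈ [144°, 180°).
A planar ring (all ν ≈ 0) has no defined phase and raises.

## Reweighting

Weights are computed in log space with a max shift, so deep parameter
excursions underflow gracefully; if every weight vanishes the point is
flagged degenerate rather than silently zero.  ΔU sums only the
tracked modified pairs — everything else cancels.  k_B =
0.0019872041 kcal·mol⁻¹·K⁻¹ (RT = 0.59219 kcal/mol at 298 K).
Upstream bias weights (e.g. from metadynamics) enter as a base-weight
column and are not re-derived here.

Reliability: the Kish effective sample size N_eff = 1/Σw² is reported
per grid point and points with N_eff < 5 % of N are flagged, since
exponential reweighting degrades as the target parameters leave the
sampled ensemble.  Uncertainties come from a block bootstrap over 50
contiguous blocks with 200 resamples (seeded); blocks respect time
ordering so autocorrelation inflates the error estimate as it should.

The "both" scan role moves the purine and pyrimidine pairs together,
preserving their 0.05 Å spacing, with the grid value referring to the
purine pair; "purine"/"pyrimidine" move one pair only.

## NMR observables

³J couplings use J(θ) = A·cos²(θ+φ) + B·cos(θ+φ) + C and average
linearly over frames (fast exchange).  Coefficient sets live in a
named registry; the set used is recorded per restraint, because χ²
values are only comparable under a fixed parameterization.  NOEs
average as r_eff = (Σᵢ wᵢ rᵢ⁻⁶)^(−1/6); ambiguous NOEs sum the r⁻⁶
contributions of their 2–3 proton pairs inside each frame before
averaging.  Unobserved NOEs are one-sided flat-bottom: only
r_eff < bound is penalized, by ((bound − r_eff)/σ)².

Class χ² is the mean squared z-score; the total is the count-weighted
mean Σnᵢχ²ᵢ/Σnᵢ, so splitting a class leaves the total invariant.
Default σ when a restraint carries none: 1.5 Hz for J classes, 20 % of
the value for NOE, 0.5 Å for uNOE — conventions, stated in the report,
not physical constants.  Comparison happens in distance space;
intensity-to-distance conversion is out of scope.

## εRMSD and folding

Base frames anchor on the six-membered ring: origin at the C2/C4/C6
centroid, x toward C2, z normal to the ring plane with the cross
product ordered opposite ways for purines and pyrimidines so z points
to the same base face.  Relative positions scale anisotropically by
the ellipsoid a = 5 Å (in plane) and b = 3 Å (normal), cutoff 2.4 in
scaled units; each in-range ordered pair contributes the 4-component
G-vector (sin γ·r̃/|r̃|, 1 + cos γ)/γ with γ = π|r̃|/cutoff, which
decays smoothly to zero at the cutoff surface.  εRMSD is the root
mean square G-vector difference per residue.  These constants are
configuration, not code.

Folding: frames with εRMSD ≤ 0.7 to the native reference count as
folded (the boundary counts as folded — a documented tie-break).
ΔG°_fold = −k_BT·ln(p/(1−p)); p ∈ {0, 1} returns ±∞ explicitly.  The
ΔG uncertainty propagates the block-bootstrap population error through
dΔG/dp = −k_BT/(p(1−p)).

Density-peak clustering takes any precomputed distance matrix.  ρ is
the neighbor count within d_c (Gaussian-kernel option), δ the distance
to the nearest higher-ρ point (the global maximum gets the largest
pairwise distance).  d_c defaults to a low percentile of the pairwise
distances, raised at small n so every point keeps a couple of
neighbors.  The number of centers is read off the decision graph
automatically — points with δ ≥ 0.6·max(δ) and at-least-average ρ —
and can be forced explicitly; centers are then the top ρ·δ products
and the rest of the frames follow their nearest higher-density
neighbor in descending density order.

## Synthetic data

The two-state generator emulates the statistics of a folding
enhanced-sampling run at the analysis level: a Bernoulli state per
frame with p* = 1/(1+exp(ΔG*/k_BT)), εRMSD uniform on (0.1, 0.6) for
folded and (0.9, 2.0) for unfolded frames (cleanly separated across
the 0.7 threshold), and an H8···O5′ distance drawn Boltzmann-
distributed under the reference pair potential within a
state-conditional window — short (2.5–3.6 Å, contact formed) when
folded, long (4.2–6.5 Å) when unfolded.  Because the distances are
exactly Boltzmann under the reference parameters, the reweighted
folded population under modified parameters has a closed quadrature
answer (`two_state_reweight_truth`), giving the reweighting stack an
independent oracle.

What it does not emulate: time correlation (frames are i.i.d., so
block-bootstrap errors on synthetic data are conservative only for
real trajectories), misfolded intermediates, coupling between εRMSD
and the contact distance beyond the shared state, and multi-pair
cooperativity.  Passing recovery tests therefore validates the
estimators and bookkeeping, not force-field realism.

The 1-D Boltzmann sampler inverts the CDF on a 20 001-point grid;
its ground truth stores the quadrature mean for 3-standard-error
comparisons.  The restraint generator back-calculates J (ring
dihedrals) and NOE (adjacent C2–C2 distances) from a structure, adds
Gaussian noise, and sets σ to the noise level with a 0.02 floor so
noiseless restraint sets score χ² → 0 while nominal noise scores
χ² ≈ 1.  The toy helix builder places idealized planar bases on a
regular helix — a self-consistent geometric substrate, not a refined
nucleic-acid model — and is labelled synthetic throughout.

All generators are deterministic given (parameters, seed); every
emitted record carries its ground truth.

## Problem sizes

Recovery and consistency checks use 10⁵-frame ensembles (recovery
tolerance ±0.05 kcal/mol at binomial error ≈ 0.004); the acceptance
script uses 2×10⁵ frames per ensemble.  Clustering fixtures use
10-point blobs over 10 seeds.  The full test suite runs in a few
seconds on one CPU.

## Known limitations

* Only the type-0 (intranucleotide) base–phosphate interaction is
  annotated; the wider BPh taxonomy is out of scope.
* Reweighting is single-state exponential; no MBAR-style multistate
  estimation, matching its intended screening use.
* χ² totals against published experimental tables depend on the σ and
  Karplus conventions of the originating experimental studies; the
  machinery reproduces the form of such tables, not their exact
  values.
* Trajectory input is multi-model PDB or tabular distances only; no
  binary trajectory formats.
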