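# nbfixtools

Tools for building and evaluating a pair-specific Lennard-Jones
correction (an *NBfix*) for the type-0 base–phosphate interaction
(0BPh) in AMBER-family RNA and DNA force fields, together with the
analysis stack used to derive and validate such corrections:
geometric 0BPh annotation, Boltzmann reweighting of trajectory
ensembles over van der Waals parameter grids, NMR χ² agreement
scoring, and εRMSD-based folding free-energy analysis.

## Who this is for

Force-field developers and simulators of small nucleic-acid motifs
(tetranucleotides, hexanucleotides, tetraloops) who want to

* generate AMBER/GROMACS patch blocks that break the Lorentz–Berthelot
  combination rules for the H8···O5′ and H6···O5′ atom-type pairs,
* re-evaluate existing enhanced-sampling ensembles under candidate
  parameters without resimulating, and
* score the resulting ensembles against NMR restraints and two-state
  folding thermodynamics.

## The model

The 0BPh interaction is the intranucleotide weak C–H···O hydrogen bond
between the base H8 (purines, AMBER atom type H5) or H6 (pyrimidines,
type H4) and the O5′ bridging phosphate oxygen.  Standard combination
rules place the 12-6 minimum-energy distance R\_ij of these pairs too
far out; the correction shifts it by a signed offset (default
−0.25 Å) while keeping the well depth ε\_ij at its combination-rule
value:

    U(r) = ε_ij [ (R_ij / r)^12 − 2 (R_ij / r)^6 ]
    R_ij ← R_ij(Lorentz–Berthelot) + Δ,   ε_ij unchanged

With the shipped RNA OL3_CP atom-type radii this gives R = 2.8808 Å
(H5–OR) and 2.9308 Å (H4–OR) at Δ = −0.25 Å, with ε = 0.0505 kcal/mol.

Candidate parameters are screened by exponential reweighting: frame i
of a reference ensemble receives weight w\_i ∝ b\_i·exp(−ΔU\_i/k\_BT),
where ΔU\_i is the tracked-pair energy change and b\_i an optional
upstream bias weight.  Observables (χ² against NMR restraints, the
folded population) are then re-averaged per grid point, with the Kish
effective sample size as the reliability guard.  Folding is quantified
by εRMSD to a native reference (threshold 0.7) and
ΔG°\_fold = −k\_BT·ln(p/(1−p)).

## Worked example

```pycon
>>> import nbfixtools as nt
>>> table = nt.build_nbfix_table("RNA-OL3CP", offset=-0.25)
>>> [(p.type_i, p.type_j, round(p.r_min, 4), round(p.eps, 4)) for p in table.entries]
[('H5', 'OR', 2.8808, 0.0505), ('H4', 'OR', 2.9308, 0.0505)]
>>> nt.dg_from_population(0.683, 298.0)      # 68.3 % native population
-0.45455850985249446
>>> nt.population_from_dg(-0.5) - nt.population_from_dg(0.1)
0.24149236291548798
```

The first call builds the two corrected pairs for the RNA flavor: the
purine pair bottoms out at 2.8808 Å and the pyrimidine pair at
2.9308 Å, both keeping the 0.0505 kcal/mol well depth.  The second
line converts a 68.3 % native population at 298 K into a folding free
energy of −0.45 kcal/mol (−0.5 at one decimal), and the third shows
that a −0.5 vs +0.1 kcal/mol change in ΔG°_fold corresponds to a
24-point gain in native population.

The same operations are available from the shell:

```sh
nbfix build --flavor rna-ol3cp --offset -0.25 --dialect amber
nbfix grid --lo 2.33 --hi 3.33 --step 0.025          # 41 candidate R_ij values
nbfix synth --dg -0.5 --n 10000 --seed 1 --out frames.tsv
nbfix scan --ensemble frames.tsv --role both --lo 2.33 --hi 3.33 --step 0.025
nbfix annotate --pdb ensemble.pdb --cutoff 3.2
nbfix fold --traj frames.pdb --ref native.pdb --threshold 0.7 --temp 298
```

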