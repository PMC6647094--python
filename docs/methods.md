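# Methods

## Substitution grammar and metabolite enumeration

Metabolites are identified by a parent tag (M = mitragynine, C23H30N2O4;
H = 7-hydroxymitragynine, C23H30N2O5; both neutral) and one substitution
state per reactive position. The shipped grammar
(`src/mitrametab/data/grammar_default.yaml`) is data, not code, so restricted
or hypothetical grammars are expressible for testing.

| position | chemistry | states | transitions |
|---|---|---|---|
| 9 | aromatic methyl ether | m, d, g, s | m→d (O-demethylation), d→g (glucuronidation), d→s (sulfation) |
| 16 | methyl ester | m, d, g | m→d (ester hydrolysis), d→g (glucuronidation) |
| 17 | enol methyl ether | m, d, o, r, G | m→d (O-demethylation), d→o (oxidation), d→r (reduction), r→G (glucuronidation) |

Each position's transition graph is a DAG rooted at `m`, which gives every
metabolite a well-defined step count from the parent. State `d` at position
17 denotes the aldehyde tautomer produced by demethylation of the enol
ether; the enol is not modeled as a distinct species. Per-state formula
deltas relative to `m` are: `d` −CH2 (all positions); `o` −CH2 +O; `r`
−CH2 +H2 (alcohol); `g` −CH2 +C6H8O6 (glucuronide, after loss of water);
`G` −CH2 +H2 +C6H8O6 (glucuronide of the position-17 alcohol); `s` −CH3
+SO3 with charge −1 (the sulfate ester anion R–OSO3⁻). The `s` and `G`
deltas are the unique choices under which every conjugation step balances
with the cofactor templates below; parent formulas are validated in the
tests against an independent monoisotopic-mass computation (mitragynine
398.2206 amu).

The full grammar gives 60 metabolites and 133 steps per parent. The curated
experimental subset (18 metabolites, 21 steps per parent; 36 compounds over
both parents) is shipped as
`data/pathway_subset_reconstructed.yaml`. It is a *reconstruction* of the
published rat/human LC-MS pathway scheme from its textual description and
the compounds named alongside it; the published pathway diagram is the only primary
source, so the file is flagged as reconstructed and its rat/human/bracketed
evidence flags are approximate annotation, never computed on. The 18-code
set admits 24 grammar transitions; the three not in the curated 21-arrow
list are deliberately excluded, so the subset stores explicit edges.

## Reaction steps and balance

Each transition is completed into a balanced equation with fixed cofactor
templates (exact `fractions.Fraction` coefficients, so balance checks are
exact):

* O-demethylation / ester hydrolysis: +H2O → +CH3OH
* oxidation (default): +C6H7N2O⁺ (protonated nicotinamide) +2 H2O →
  +C6H8N2O (1,4-dihydronicotinamide) +H3O⁺;
  alternative `o2` mode: +½ O2 → (nothing)
* reduction: +C6H8N2O +H3O⁺ → +C6H7N2O⁺ +H2O
* glucuronidation: +C6H10O7 → +H2O
* sulfation: +SO4²⁻ +H3O⁺ → +2 H2O

These are the smallest-integer element- and charge-balanced schemes using
only the reference reagents/products considered here (water, methanol,
glucuronic acid, sulfate, hydronium, the nicotinamide model couple,
oxygen). They are an inference of this package, not a literature-assigned
enzymatic mechanism; in particular O-demethylation is balanced as net
methyl transfer to water, not as P450 monooxygenation, and the
nicotinamide-vs-O2 choice for the aldehyde oxidation is configurable
because either reference is chemically sensible. Every generated step is
re-validated for per-element and charge balance; the test suite checks all
266 two-parent steps exhaustively and verifies that cofactor bookkeeping is
path-order independent on every diamond motif.

## Thermochemistry

Gas-phase Gibbs energies use the rigid-rotor harmonic-oscillator model at
T = 298.15 K (overridable; mixed-temperature reaction energies are
refused): Sackur–Tetrode translation at 1 atm, classical rotation with
symmetry number (monoatomic/linear/nonlinear cases; linearity is detected
from the principal moments of inertia), harmonic vibrations with ZPE from
unscaled frequencies (no scaling factor, no quasi-harmonic low-frequency
treatment), and spin-degeneracy electronic entropy. Records with imaginary
frequencies are refused unless explicitly flagged as non-minima, and then
they are still refused by the thermochemistry stage.

Aqueous standard states: G°(aq) = G°(gas, 1 atm) + RT ln(c/c_gas°) +
ΔG_solv, where c_gas° = P°/RT ≈ 1/24.46 mol/L at 298.15 K, c = 1 M for
solutes and 55.34 M for liquid water. The solvation energy is treated as an
additive transfer free energy; if it was produced under a convention that
already contains the gas→1 M term, `solvation_includes_1M=True` adds only
RT ln(c/1 M). The correction is applied to every species including O2
(dissolved-oxygen reference); this is one documented choice among two
defensible ones and is configurable at the species level through the
record's `standard_concentration`.

Constants are fixed for bit-reproducibility: R = 1.98720×10⁻³
kcal/(mol·K), 1 hartree = 627.5095 kcal/mol, CODATA values elsewhere via
scipy.

## Aggregation

Relative energy ladders accumulate step ΔG°_aq from the parent code along a
spanning tree and then re-check every edge against the assigned levels;
deviations beyond 1e-6 kcal/mol (pure floating-point summation noise) are a
hard error, since they can only arise from an unbalanced or inconsistent
network. Group averages are unweighted arithmetic means per (parent,
reaction type, position) — "average" without qualification is read as the
plain mean. Substitution effects match steps across parents by their
parent-independent transition and report ΔΔG (H − M) per step and per
group. "Most reactive position" statements are always computed rankings
over these means, never hard-coded; on real data the comparison
with published qualitative claims is a report, not a unit test.

## Synthetic data

`SyntheticSpec` defines a study: group contributions per substitution state
(defaults chosen once to emulate the reported qualitative pattern —
sulfation/oxidation/reduction strongly exergonic, demethylation most
favorable at 9, glucuronidation most favorable at 17), parent energies
(H set 38.3 kcal/mol below M under the balanced-hydroxylation comparison
M + ½O2 → H, the reported parent gap), cofactor constants, per-(type,
position) offsets including 7-hydroxy modifiers (d17 −3, g17 −2, g9 +2
kcal/mol), per-species Gaussian noise, and a charge-dependent solvation
rule (−2 − 60·|q| kcal/mol) with per-ion constants for hydronium (−110),
sulfate (−250) and protonated nicotinamide (−60) at magnitudes typical of
small aqueous ions — without these the redox couple's solvation would
cancel and reduction steps would show no gas-vs-aqueous discrepancy, which
real charged-species reactions do show.

Each species gets a fake geometry (4–9 atoms), 3N−6 positive frequencies
in 200–3500 cm⁻¹, and an electronic energy *back-solved* so that the full
pipeline's G°(aq) equals the group-contribution target. The back-solve uses
this module's own single-expression partition-function arithmetic
(G_corr = ZPE − RT ln q), written independently of the pipeline's
enthalpy/entropy route; their agreement to ~1e-8 kcal/mol is asserted in
the tests. Ground-truth step energies are computed by plain group
arithmetic, sharing no code path with the pipeline. Noise enters the
records only; the truth table is the noiseless construction, so zero-noise
runs must agree with truth to 1e-6 kcal/mol and noisy runs must be
unbiased about it.

What the synthetic data does *not* emulate: real geometries, realistic
frequency distributions, conformational ensembles, correlated errors
between related species, or any actual electronic-structure physics.
Passing tests therefore demonstrate the pipeline's arithmetic, balance,
unit handling and statistical behavior — not the accuracy of any quantum
chemistry.

## Problem sizes and determinism

The test suite and the acceptance script run the full two-parent network
(120 metabolites + 8 cofactors, 266 steps). Noise-recovery checks use 100
replicates at noise 0.5 kcal/mol (about 7 s total); the recovery assertion
is a 4-sigma Monte-Carlo band computed from the replicate spread, plus a
0.02 kcal/mol floor for degenerate groups. All randomness flows through
`numpy.random.default_rng` seeded from explicit integers; reruns with
identical configuration produce byte-identical TSV outputs.

## Known limitations

* The curated pathway subset is a reconstruction (see above); analyses on
  it are structurally faithful (18/21 counts, chemistry classes) but the
  specific arrow set may differ from the published diagram in up to a few
  edges.
* The cofactor assignment per reaction class is inferred, not
  literature-assigned; changing it shifts all steps of a class by a
  constant and leaves rankings within a class unchanged.
* No kinetics, enzyme assignment, pKa/microstate handling, conformational
  ensembles, or statistical inference over energy differences.
* The quantum-chemistry log reader implements this package's documented
  `qcout` dialect; logs from other programs should be converted to the
  portable record format.
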