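# Methods

## The two-state model

Serine hydrolases pass through a tetrahedral intermediate in which the
catalytic serine's O&gamma; is covalently bonded to the substrate's carbonyl
carbon.  The protocol approximates the Gibbs activation-energy change of a
variant by a potential-energy difference between two minimized complex
states per ensemble conformer:

* **ES** — the substrate docked in the active site, no covalent bond;
* **ES\*** — the same complex with a harmonic restraint pulling the
  Ser-O&gamma; / carbonyl-C distance to the transition-state bond length
  (default 1.9 Å, force constant 200 kcal·mol⁻¹·Å⁻²; the forming bond and
  the 1–3 pairs it creates are removed from the non-bonded terms, as a real
  bond would be).

Per frame *i*, ΔE_i = E(ES\*_i) − E(ES_i).  Mutant frames derive 1:1 from
wild-type frames, so normalization is per-frame by default:
ΔẼ_v = median_i(ΔE_mut,i / ΔE_wt,i), with a |ΔE_wt| floor of 1e-6 guarding
the division and an alternate median-of-medians mode.  The median (not the
mean) is deliberate: single-frame clashes produce heavy-tailed ΔE outliers.
The wild type scores exactly 1 in both modes, and the score is invariant
under uniform rescaling of all energies.

## Energy model

A deliberately simple, *swappable* force field: Lennard-Jones (per-element
well depths, Lorentz-like combination on r_min), Coulomb with
distance-dependent dielectric ε(r) = 4r (constant-ε available), harmonic
bond and angle terms whose reference values are taken from the input
geometry, 1-2/1-3 non-bonded exclusions, and the ES\* restraint.  Partial
charges come from a per-residue template table; atoms not in the table are
neutral.  Fidelity target is **ordinal** behaviour of rankings, not
reproduction of production force-field energies — the protocol this package
probes is known to give parameterization-dependent rankings, so the model
spec (`EnergyModelSpec`) is a first-class object the stability analysis can
swap (`charge_scale`, `lj_scale`, dielectric, term toggles).

Minimization is steepest descent with multiplicative step adaptation
(accept → ×1.2 capped at 0.05 Å; reject → ×0.5), so the energy trace is
monotone by construction.  Convergence is RMS gradient ≤ 0.01
kcal·mol⁻¹·Å⁻¹, cap 2000 iterations; ΔE production runs use a smaller cap
(the difference of two equally-truncated minimizations is ordinally stable
and an order of magnitude cheaper).

## Conformer generation

Ensembles are sampled distance-geometry style: bounds derived from the seed
(covalent 1-2 ±0.05 Å, 1-3 ±0.10 Å, 1-4 ±0.30 Å; heavy-atom contacts within
6.0 Å ±0.50 Å; catalytic-triad side-chain pairs ±0.05 Å "anchor" bounds),
then a Gaussian perturbation (σ = 0.8 Å per axis) followed by sequential
pairwise projection with rng-shuffled pair order until every bound is met
within 0.01 Å (cap 5000 sweeps, up to 5 deterministic restarts).  Anchored
atoms are perturbed by at most half the anchor tolerance — their bounds make
them quasi-rigid, and starting them at seed geometry keeps the projection
feasible.  Chirality and planarity are not restrained beyond distances; this
is a documented simplification of the distance-bound family of generators.
The default design ensemble is the seed plus 95 conformers (96 members).
On the 20-residue toy this produces a mean Cα RMSD to the seed of ≈0.4 Å
while the anchored active site stays within twice the anchor tolerance.

## Mutagenesis

Side chains are rebuilt from idealized internal-coordinate templates; each
χ angle is scanned on {−60°, 60°, 180°} and the combination minimizing a
steric clash count (heavy-atom pairs < 0.8 × ΣBondi radii against all atoms
outside the residue and the flanking backbone) wins, ties broken by grid
order.  Backbone atoms are never modified.  Ring residues (His, Phe, Tyr,
Trp, Pro) are built as idealized chains whose rings close only
approximately — adequate for clash scoring and occupancy geometry on toys,
not for publication-grade side-chain modelling.  If no clash-free rotamer
exists the structure carries `meta["clash_warning"]` rather than failing
silently.

## Conservation filter

PSSM scores are base-2 log-odds with background-scaled pseudocounts
(default 1.0, uniform background), no sequence weighting:
score(p,a) = log2((count + pc·bg) / ((N_eff + pc)·bg)).  Gaps are excluded
from counts; all-gap columns are flagged.  The −4.0 bits cutoff is treated
as ordinal — with a different background or weighting the absolute scale
would shift, which is why both are exposed in config.

## Hydrogen-bond occupancy

A bond is formed when donor–acceptor ≤ 3.0 Å **and** the donor–H–acceptor
angle ≥ 150° (both inclusive).  Structures without hydrogens use an
idealized amide H for backbone-N donors (1.01 Å from N, opposite the
CA/C(prev) bisector); other H-less donors fall back to distance-only.  The
"Transition State analogue" metric is the fraction of frames with all four
canonical bonds formed simultaneously, so it can never exceed any marginal
occupancy — this is asserted on every table.  Threshold scans (2.5–4.0 Å)
run distance-only, where occupancy is provably monotone in the cutoff.
Association with experimental activity uses Spearman ρ (average ranks,
zero-variance series reported as ρ = 0 with a degeneracy flag), a seeded
label-permutation p-value (10 000 permutations, vectorized), an
active-vs-inactive rank-sum test (inactive ≡ activity exactly 0), and
Benjamini–Hochberg adjusted p-values alongside the raw ones.

## Rank stability

`rank_stability` re-ranks variants under every supplied condition (energy
spec / parameterization) × frame subsamples drawn without replacement, and
reports pairwise Spearman ρ and top-k overlap.  Defaults: 20 subsample
conditions, subsample size 8 (of 96 frames), top_k = 3.  The subsample size
was calibrated once against the protocol's paired stability bounds — with
planted effects spaced 1 kcal/mol apart, frame noise σ = 0.1 must leave the
ranking stable (mean ρ ≥ 0.9) while σ = 5.0 must scramble it (mean ρ ≤ 0.5).
Sizes 6–12 all satisfy the first bound; 8 satisfies the second robustly
across seeds (size 16 does not), and small subsets are also the realistic
regime, mimicking analyses on a handful of hand-picked frames.

## Synthetic data: what it does and does not establish

Generators are deterministic under (config, rng_seed) via named RNG
substreams, and every dataset carries a JSON ground-truth sidecar.

* **Toy enzyme** — ideal-geometry helix–loop–helix backbone (all-Ala) with
  Ser/His/Asp carved at n/3, n/2, 2n/3 and a 6-atom ester-like fragment
  (carbonyl C/O, ester O + methyl, α-C, tail hydroxyl) posed 2.9 Å from the
  serine O&gamma;.  It has the *topology* of a serine hydrolase active site,
  not its electrostatics or packing.
* **Flexibility ensembles** — per-residue isotropic Gaussian noise; the
  expected RMSF is σ√3 exactly, giving an analytic recovery target.
* **Planted ΔE tables** — wild-type ΔE ~ Normal(10, 1) kcal/mol (positive,
  barrier-like, keeps ratio normalization well-defined); variant tables add
  a planted offset δ plus frame noise.  The ±2 kcal/mol planted grid sits at
  the scale of the real activity effects this class of protocol must resolve
  (< 2 kcal/mol for a ~10-fold activity change).
* **H-bond frames** — per frame, each bond is placed in exactly-formed
  geometry (2.8 Å, 165°) or broken geometry (4.5 Å) with its target
  probability, independently or all-or-none.
* **MSAs** — per-column target consensus frequency; 1/20 reproduces the
  uniform background, 1.0 full conservation.

A green recovery test therefore establishes that the *machinery* (scoring,
normalization, counting, ranking) is correct and that its stability behaves
as the noise model predicts.  It does not establish that the simplified
force field ranks real enzyme variants correctly — the stability analysis
exists precisely because that claim fails for far more detailed models.

## Numerical choices and edge cases

* Strict inequalities at all three selection thresholds (ΔẼ < 0.985,
  PSSM > −4.0, dist < 5.0), matching their printed form; boundary values
  fail.
* Ranks are a permutation over all candidates (ascending ΔẼ_v, ties broken
  lexicographically); pass flags mark the survivors.
* Divergent minimization frames are excluded pairwise (dropped from mutant
  and wild type via the shared-frame intersection) and always logged.
* Altloc policy on PDB input: highest occupancy wins, ties by altloc letter.
* Atom pairs closer than 0.1 Å abort energy evaluation (corrupt geometry)
  rather than returning a huge number.
* The run-config hash excludes the output directory: same science, same
  hash, byte-identical TSV/JSON outputs.

## Known limitations

Idealized rotamer and ring geometry; no generalized Born or explicit
solvation; no backbone-dependent rotamer statistics; distance-only bound
taxonomy (no chirality restraints); the toy substrate is an ester-shaped
fragment, not a parameterized ligand; PSSM thresholds do not transfer
quantitatively to differently-built alignments.
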