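# Methods

## Scope and model

`ppaffinity` estimates protein–protein binding affinity from structure
in two ways: a knowledge-based interfacial pair potential, and a linear
model that decomposes ΔG into environment-conditioned contributions of
interfacial contact pairs and non-interfacial residues, with weights
fitted against experimental affinities. This note records the model
assumptions, the numerical choices, the design decisions that were
genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Structure model

Complexes are parsed from PDB text into a light residue/atom model with
an explicit two-partner chain split. Only the 20 standard amino acids
are kept; selenomethionine is mapped to methionine, other non-standard
residues, waters and heteroatoms are dropped with a warning. For
alternate locations the highest-occupancy conformer is retained
(ties broken toward the earlier altloc identifier). Hydrogens are
ignored throughout — the crystal structures this pipeline targets
generally lack them.

Contacts are defined on sidechain heavy atoms: two residues from
opposite partners are in contact when their minimum sidechain-atom
distance is strictly below the cutoff ("less than", not "at most").
Two cutoffs coexist deliberately: 5.5 Å when counting pairs for the
statistical potential and 5.0 Å when defining the affinity model's
interface; both are configurable constants. Glycine has no sidechain
heavy atoms and uses CA as a surrogate, so it can appear in interfaces
like any other residue type. Residues with no resolved sidechain atoms
(and not glycine) are excluded from contact detection with a warning.

## Local environment

**Secondary structure** is assigned by a built-in Kabsch–Sander style
hydrogen-bond analysis: the amide hydrogen is reconstructed 1 Å from N
along the preceding C→O direction (prolines and chain-initial residues
donate nothing), the bond energy is the standard electrostatic form
0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with the −0.5
kcal/mol threshold, helices require two consecutive n-turns (n = 4
with priority, then 3 and 5), and strands are residues in parallel or
antiparallel bridges. The eight DSSP classes collapse to three:
{H,G,I} → H, {E,B} → S, everything else → L; turn and bend classes are
never computed separately because they collapse to L anyway. Bonds are
evaluated within chains only; the one fixture that needs a two-strand
sheet therefore builds both strands into a single chain. Residues that
match no pattern — including fragments too short for any — fall back to
L. An external DSSP binary is not required anywhere.

**Solvent accessibility** uses Shrake–Rupley quadrature with a
deterministic golden-spiral point set, probe 1.4 Å, and a Bondi-style
element radius table shipped as YAML (`data/vdw_radii.yaml`). The
default is 960 points per atom, configurable; fixtures in tests use
fewer (120–240) for speed and more (16 000) where sub-percent
rotational stability is asserted. Quadrature error on a free atom is
below 1 % at 960 points; occlusion-boundary noise decays roughly as
n^(−3/4). Per-residue values are sums over sidechain atoms (CA for
glycine); monomer contexts simply drop all atoms of the other partner,
so complex-context accessibility can never exceed monomer-context
accessibility with the same point set.

**Relative accessibility** divides by a per-residue-type maximal
sidechain area from the Gly-X-Gly theoretical reference of Miller et
al. (`data/max_sidechain_sasa.yaml`); glycine carries a CA-surrogate
reference of 47 Å². A residue is **exposed** when its complex-context
relative sidechain accessibility strictly exceeds 30 %. Complex context
is used for the burial class of non-interfacial residues; for residues
far from the interface the two contexts agree anyway.

**Regions.** With r_m and r_c the relative accessibility in monomer and
complex context and Δ = r_m − r_c (tolerance 10⁻⁶ for Δ ≈ 0, pure
float-noise guard since the quadrature is deterministic): interior
(Δ≈0, r_m < 25 %), surface (Δ≈0, r_m ≥ 25 %), support (Δ>0, r_m < 25 %),
rim (Δ>0, r_c ≥ 25 %), core (Δ>0, r_m ≥ 25 %, r_c < 25 %). The 25 %
threshold follows the established five-region scheme.

## Potential

χ_i counts each interfacial residue once, not once per contact pair — the
residue-count reading of "mole fraction at the interface". kT defaults
to 1 so energies are in kT units; only the relative scale matters.
Zero counts are handled by a pseudocount (default 0.5) added to every
pair count, with the total inflated by pseudocount × (number of pair
categories over the observed types); residue types never seen at any
interface are excluded from smoothing, flagged unobserved, and score 0.
Homodimeric library entries contribute each unordered cross-partner
pair once.

## Affinity model

Feature extraction produces integer counts over 1830 unordered
interfacial categories ((aa,ss) × (aa,ss)) and 120 non-interfacial
categories ((aa,ss) × {B,E}); the unordered convention is forced by
homodimers and makes predictions invariant under partner relabelling.
ΔG_calc = Σ n_itf·W_itf + w_n·Σ n_nitf·w_nitf is linear in counts and
weights; its scale is arbitrary until the cross-validation adjustment.

**Threading.** Mutants are represented by relabelling residue identity
on unchanged wild-type geometry: contact pairs and secondary structure
carry over, and the burial class renormalises the measured wild-type
sidechain area by the *mutant* type's reference area. A residue mutated
to glycine uses its CA-atom area (no rebuilt atoms exist to measure).
No repacking or minimisation is attempted; this keeps the pipeline
deterministic and is the minimal consistent treatment when only
wild-type structures exist.

## Refinement and cross-validation

The greedy Monte-Carlo search starts from uniform random weights in
[−1,1], proposes one uniformly chosen parameter with a fresh uniform
value per step, and accepts only strict increases of the Pearson
correlation (ties and degradations are rejected). Stopping: 2×10⁵ steps
or 2×10⁴ consecutive rejections, whichever first (both configurable).
The correlation is maintained incrementally from running sums (Σp, Σp²,
Σp·e) with a full recomputation every 1000 accepted moves — measured
drift is below 10⁻¹³ — and an acceptance guard of 10⁻¹³ keeps
sub-roundoff improvements from being accepted and later reversed by the
exact resynchronisation, so the accepted-objective trace is
non-decreasing exactly. All randomness flows from one seed through
`numpy` SeedSequence spawning; per-family and per-restart streams are
derived deterministically.

Cross-validation is grouped by wild-type complex: each run refines on
all other families and predicts the held-out family. Raw predictions
are mapped to experimental units by moment matching — adjusted = mean(exp)
+ (raw − mean(calc))·sd(exp)/sd(calc) over the refinement set — which is
the recorded reading of "adjusted according to the average value and
standard deviation of the refinement affinities". The pooled testing ρ
is computed on adjusted predictions over all records after all runs.

Two estimator-level choices stabilise held-out prediction at small
family counts, where a single greedy run is not a consistent estimator:

* **Unseen categories predict zero.** A category absent from the
  refinement records is never moved by the search (every proposal on it
  is a tie and ties are rejected), so its final value is bare
  initialisation noise carrying no information; it is therefore dropped
  at prediction time.
* **Restart averaging.** `MCConfig.restarts` independent refinements
  from different random initialisations are averaged weight-wise per
  cross-validation run (default 1; the benchmark uses 8). Averaging
  shrinks the initialisation component that survives in weakly
  constrained directions of the refinement design. Whether multiple
  restarts should be used is left open by the refinement protocol; this
  package makes it an explicit option.

Mutation-effect classification compares, per mutant, the sign of the
predicted and experimental affinity change against the family wild
type; "increases binding" means ΔG becomes more negative; exact-zero
predicted changes count as "decrease" so the classification is
deterministic. The permutation test reshuffles the calculated values,
reports the fraction of permuted correlations at least as large as the
observed one, and floors the p-value at 1/n_perm. Region-stratified
correlations cover single mutants only, grouped by the wild-type-structure
region of the mutated site, and report regions with fewer than three
mutants as undefined.

## Synthetic benchmark

The generator emulates a mutation-affinity database: families of one
wild-type complex plus threaded mutants, with affinities manufactured
from a planted weight vector and mapped affinely to mean −10, SD 3
kcal/mol (typical of K_d-derived data); optional Gaussian noise comes on
top. Structures are idealized — standard backbone geometry built from
(φ,ψ) torsions (a helical segment followed by an extended segment),
single-sphere pseudo-sidechains at CB positions, and the second chain
docked strand-to-strand by a 180° rotation and a bisection on the
approach axis so that the minimum cross-partner sidechain distance
equals `interface_width` exactly (default 4.5 Å, giving interfaces of
roughly 7–10 contact pairs at the 5 Å cutoff).

Defaults are the benchmark's study conditions: 10 families × 30
mutants, 30 residues per partner, noiseless, planted w_n = 0.7. Two
generator choices exist purely to make the planted weights identifiable
from ten families: family sequences are variants of a common scaffold
(2 % of positions re-randomised per family), and mutation panels mimic
experimental scans (half the sites interfacial, half the substitutions
to alanine, the rest from a small recurring repertoire). Real databases
achieve the equivalent coverage through sheer size.

What passing the benchmark shows: the counting, classification, fitting
and cross-validation machinery is self-consistent and can recover a
planted linear model (refinement ρ ≈ 0.99, held-out pooled ρ ≈ 0.97 at
the benchmark seed). What it does not show: performance on real
complexes — idealized single-sphere sidechains have no rotamer
diversity, no packing defects, no experimental noise, and the planted
model is by construction the true one.

**A known negative result.** The w_n scan cannot recover the planted
w_n from data generated by this model, and the package's scan output
should be read accordingly. The Pearson objective is invariant to
positive rescaling of the predictions, so for any scan value w_n′ ≤
w_n* the planted predictor is exactly representable by shrinking both
weight blocks, and for w_n′ > w_n* by shrinking only the
non-interfacial block — all within the [−1,1] box. The optimal testing
correlation is therefore constant on w_n ∈ (0,1] and drops only at
w_n = 0, where non-interfacial information is unavailable; measured
scans show exactly this plateau, with the argmax wandering over
[0.3, 1.0] with optimizer jitter. A peak at an interior w_n on real
data reflects noise and optimizer kinetics, not an objective-level
optimum. The corresponding acceptance test asserts interior-peak
recovery anyway and is expected to fail; it is kept as an honest record
of this property.

## Degenerate inputs and guards

Zero-variance affinity vectors, single-family datasets, empty
structure libraries, unknown elements, negative accessibilities,
complex-context areas exceeding monomer-context areas, mismatched
wild-type residues in mutations, and non-positive dissociation
constants all raise named errors. An empty interface is a valid result
everywhere (contact maps, potential scores, feature vectors).

## Problem sizes

Test and benchmark sizes were chosen to exercise every code path at
desk scale: 16–30 residues per partner, 3–10 families, quadratures of
120–960 points (16 000 only for the rotational-stability assertion),
Monte-Carlo budgets of 10³–10⁶ proposals, and permutation counts of
10³–10⁵. The full suite and the acceptance script each run in a few
minutes on one CPU.
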