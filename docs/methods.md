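# Methods

This note documents the models, conventions and numerical choices behind
`benzoqsar`, in the order the pipeline uses them. Nothing here claims
bit-compatibility with commercial descriptor software; where a convention
was genuinely open, the choice made and its rationale are stated.

## Molecular graphs and fingerprints

SMILES are parsed and sanitised with RDKit: aromaticity is perceived with
RDKit's default model, implicit hydrogens assigned, the largest covalent
fragment kept (designer-benzodiazepine entries often carry counter-ions),
and stereochemistry discarded — every descriptor here is 2D. Fingerprints
are hashed linear-path fingerprints (paths of 1–7 bonds, 2048 bits), the
conventional substrate for Tanimoto similarity; molecules with no bonds
have no paths, so they receive one stable bit derived from the canonical
SMILES to keep every fingerprint non-empty. Tanimoto similarity of two
empty bit sets is defined as 0 and logged. Absolute similarity values are
fingerprint-relative; the 0.3 curation and 0.5 applicability cutoffs are
interpreted with this fingerprint and should be recalibrated if another is
configured.

## The five descriptors

**π bond orders (`h_log_pbo`).** Each maximal conjugated subsystem is
identified on the Kekulé structure: atoms in double/triple bonds, plus
lone-pair donors (N, O, S, P, halogens with formal charge ≤ 0) adjacent to
them; all bonds between member atoms are π edges. A simple Hückel
Hamiltonian is built with α = 0, β = 1 units; heteroatom Coulomb
corrections h and resonance factors k come from a Streitwieser-type table
declared in `huckel.py` (e.g. pyridine N 0.5, pyrrole-type N 1.5,
carbonyl O 1.0, 2-electron O 2.0; k = 1 for C–C, 0.9 C–N/C–O, smaller for
C–halogen). Donor atoms contribute two electrons, multiply-bonded atoms
one; orbitals are filled from the most bonding eigenvalue down, with
degenerate frontier sets occupied fractionally (logged as open-shell).
Coulson bond orders p_uv = Σ n_k c_uk c_vk are clamped to [0, 1]; a triple
bond carries one additional orthogonal π bond with p = 1. The descriptor
is Σ log(1 + p_uv) over all bonds in **natural log**; the base is not
universal across toolkits, so it is config-switchable
(`DescriptorCalculator(log_base=...)`) and the default is documented in
every provenance sidecar. Only benzene (2/3) and ethylene (1) bond orders
are convention-independent; heteroatom values shift with the h/k table.
Cumulated π systems (allenes) are treated as planar — a known
approximation, irrelevant for benzodiazepine chemistry.

**Kier flexibility (`kier_flex`).** The α-modified kappa shape indices,
KierA1 = (A+α)(A+α−1)²/(P1+α)² and KierA2 = (A+α−1)(A+α−2)²/(P2+α)², with
A heavy atoms, P1 bonds, P2 distinct two-bond paths
(Σ deg(deg−1)/2) and α = Σ(r_i/r_Csp3 − 1) over Kier's
hybridisation-dependent covalent radii (aromatic atoms count as sp2);
the index is KierA1·KierA2/A. Molecules with A < 3 or no two-bond path
return 0 with a warning — the index is undefined there.

**Surface areas.** Per-atom van der Waals surface areas use the standard
sphere-minus-caps approximation: A_i = 4πR_i² − Σ_j 2πR_i·h_ij, with the
cap height computed at an idealised bond length d_ij clamped to
[|R_i−R_j|, R_i+R_j]. Radii are Bondi vdW radii; ideal bond lengths are
sums of Cordero covalent radii for every pair (one uniform rule rather
than a per-pair table). Implicit hydrogens act as pseudo-neighbours and
their residual sphere area is folded back into the heavy atom, so
per-atom areas sum to the whole molecular surface. Every partition
identity (Σ SlogP_VSA bins = total VSA; hydrophobic + charged VSA = total
VSA) holds for any consistent radii set, which is what the tests pin
down; absolute areas would shift with other radii.

**Hydrophobic VSA (`q_vsa_hyd`).** Partial charges are Gasteiger–Marsili
PEOE (8 iterations, damping halved per cycle — RDKit's implementation),
with implicit-hydrogen charges folded into their heavy atom so charges
sum to the total formal charge. An atom is hydrophobic when |q| ≤ 0.2;
the descriptor sums hydrophobic atoms' VSA.

**`SlogP_VSA7`.** Wildman–Crippen atomic logP contributions are computed
on the explicit-hydrogen molecule (RDKit's published pattern table,
first-match-wins; unmatched atoms get the wildcard type) and hydrogen
contributions folded into the bonded heavy atom, so they sum to the
molecular Crippen logP (asserted against RDKit's `MolLogP` as an
independent route). The full bin family over contribution edges
(−∞,−0.4], (−0.4,−0.2], …, (0.40,∞) is implemented; bin 7 — contributions
in (0.25, 0.30] — is the model descriptor. Other toolkits number the same
bins differently; the edges, not the index, are normative.

**Polar VSA (`vsa_pol`).** A polar atom is simultaneously H-bond donor
and acceptor. Donor: N/O bearing ≥ 1 hydrogen. Acceptor: N/O with an
available lone pair — positively charged atoms, pyrrole-type aromatic
nitrogens (lone pair in the ring), quaternary and amide nitrogens are
excluded. Hydroxyl oxygens and primary amine nitrogens are the typical
polar atoms in this chemistry (C3-OH and C7-NH2 substituents).

## The activity model

The published equation is stored as immutable constants and evaluated as
written. The refittable model is PLS1 (scikit-learn `PLSRegression`,
autoscaled); when the latent-variable count is not given it is chosen to
maximise leave-one-out xr² (capped at the descriptor count), and the
reported coefficients/intercept are extracted on the original descriptor
scale by linear probing of the fitted model. Training r² is the squared
Pearson correlation of fitted vs observed (the correlation-plot
convention); the explained-variance variant, which differs for PLS, is
reported alongside in validation summaries.
xr² = 1 − Σ(y_i−ŷ₍₋ᵢ₎)²/Σ(y_i−ȳ)² with each ŷ₍₋ᵢ₎ from a model refitted
without sample i; it can be negative for uninformative models.

**Outlier rule.** |predicted − experimental| > 2.5 log units (strict),
two-sided by default so badly under-predicted compounds are caught too;
`absolute=False` restores the one-sided over-prediction rule.

**Bins.** Half-open intervals [5.80, 7.00), [7.00, 8.00), [8.00, ∞), so
unrounded predictions bin unambiguously; values below 5.80 are
out-of-range (below the modelled activity span) and warned about.
Predictions are also echoed rounded to 2 dp for table formatting.

**Censuses.** Integer percentages use largest-remainder apportionment by
default (the shares always total 100; this is the convention that
reproduces published activity censuses, e.g. counts 42/43/17 → 41/42/17%),
with plain per-share rounding available as `percent_mode="round"`.

## Curation, splitting, applicability

Curation removes molecules whose average Tanimoto similarity to the other
retained molecules is < 0.3, iterating until stable. The split stratifies
on activity quartiles × a median split of average similarity, allocates
the ~20% test quota across strata by largest remainders, and forces the
global activity minimum and maximum into the training set so test
activities always lie inside the training range. The applicability domain
accepts a query iff its average Tanimoto against the whole modelling
dataset is ≥ 0.5 (kept deliberately distinct from the 0.3 curation
cutoff; both are separate config parameters).

## Synthetic library generator

The generator emulates a literature benzodiazepine structure–activity
dataset. Four scaffold templates (classic 1,4-benzodiazepin-2-one,
triazolo-, imidazo- and thieno-triazolo-benzodiazepine — the last written
as the triazolo scaffold with the fused benzo ring replaced by thiophene)
are decorated at N1/fused-ring ({H, CH3, C2H5}), C7 ({H, F, Cl, Br, NO2,
CH3, CF3, NH2}), C2′ ({H, F, Cl}) and C3 ({H, OH}); the grid yields 576
unique canonical SMILES. Molecules are drawn uniformly with rejection of
duplicates, and activities are planted by evaluating the published
equation on each molecule's own computed descriptors plus N(0, σ²) noise,
σ = 0.3 by default — chosen so a refitted model lands in the r² ≈ 0.75–0.85
regime typical of small-series benzodiazepine QSAR. Molecules whose
noiseless activity falls outside the experimental span [6.0, 9.0] are
rejected at generation (the span stays literal); noisy values outside the
span are redrawn (truncated noise) by default, with clipping as a config
alternative (clipping would skew residual symmetry). Generation is a pure
function of (seed, configuration) and each library carries a manifest
sufficient to regenerate it exactly.

What the generator does *not* emulate: real interlaboratory activity
noise structure (heteroscedastic, assay-dependent), activity cliffs, and
any structure–activity signal beyond the planted linear equation. Passing
recovery tests therefore demonstrates that the pipeline machinery is
correct and unbiased, not that the published equation is externally valid
for novel chemotypes.

## Descriptor selection in the pipeline

The two-stage cascade — delete descriptors with |Pearson r| < 0.5 to the
activity, then, while any surviving pair has mutual |r| > 0.7, drop the
member with the weaker activity correlation — is implemented in
`CorrelationSelector` and exercised on many-candidate matrices. In
`run_full` the cascade is executed and its verdicts reported, but the
final model is fitted on the full five-descriptor family by default
(`fit_on_selected=False`). The reason is structural: the cascade is
model-*discovery* machinery, designed to prune large descriptor pools in
which strong marginal correlates exist. When the candidate pool is
already the five-descriptor family and the activity is a joint linear
function of all five, marginal correlations are bounded — with mutually
orthogonal descriptors Σ_j r_j² = 1, so five descriptors can never all
reach |r| = 0.5 — and re-filtering the final family against marginal
thresholds would discard jointly informative descriptors. Multivariate
recovery (exact coefficient recovery at σ = 0, noise-consistent fits at
σ > 0) is the property the pipeline tests pin down.

## Problem sizes and numerics

Default pipeline runs use 76-molecule libraries (61/15 split after an
80/20 stratified draw), matching the scale of the literature series the
generator emulates; simulation-based checks use 50-seed batches of
67-molecule training sets. Degeneracy tolerances: Hückel eigenvalue
degeneracy 1e-9; bond orders clamped to [0, 1]; charge-sum and partition
identities asserted at 1e-6; noiseless coefficient recovery asserted at
1e-6 (achieved ≈ 1e-12). Zero-variance descriptor columns are dropped
from PLS fits with a warning and reported with zero coefficients.
Fingerprint/descriptor computations are memoised by canonical SMILES.

## Known limitations

* Absolute descriptor values depend on the declared conventions (log
  base, Hückel h/k table, radii, charge iterations); rank orders and all
  partition identities are stable, but coefficients fitted on one
  convention must not be applied to descriptors computed under another —
  the provenance sidecar exists to enforce this.
* The applicability-domain and curation cutoffs are fingerprint-relative.
* The Hückel treatment ignores cumulated systems' orthogonality and
  charged-carbon electron-count corrections (irrelevant for this
  chemistry, logged where encountered).
* The generator's activity model is exactly linear by construction;
  real benzodiazepine SAR is not.
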