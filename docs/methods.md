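# Methods

This note documents the models, parameter choices and numerical decisions
behind `fiasma`, in the order the pipeline uses them.

## Activity endpoint

The endpoint is residual ASM activity in cell culture after drug exposure,
as a percent of solvent-treated control (mean of three replicates, each
with a standard deviation of roughly 16 percentage points). A compound is
*active* when residual activity ≤ 50.0 % (inclusive). Because the
distribution over a compound panel is strongly bimodal — an active mode
far below and an inactive mode far above the threshold — dichotomisation
loses little information; calls within one replicate SD of the threshold
carry a low-reliability flag. `bimodality_analysis` quantifies the
bimodality with a two-sided Kolmogorov–Smirnov test of the pooled sample
against a normal with the sample's mean/SD (the paper-style software
convention; the Lilliefors-corrected p, which accounts for the estimated
parameters, is reported alongside) and a two-component Gaussian mixture
fitted by EM, initialised from the empirical split at 50 %. If either side
of the split is empty or EM fails, a single-Gaussian fallback is reported
with `converged=False`.

## Descriptors

The classifier's four mechanistic axes:

| descriptor | formula | units / scale | why |
|---|---|---|---|
| `logp_logweight` | logP − ½·log₁₀(MW) | log units | diffusion through lipid phases scales with lipophilicity corrected for molecular size |
| `pka_sum_basic_mod` | pKa₁ + pKa₂ if pKa₂ > 0, else pKa₁ | pKa units | each basic centre can pick up a proton in the acidic lysosome |
| `pka_most_acidic` | most-acidic pKa | pKa units | real acids are anionic, membrane-impermeant and excluded from acidic compartments |
| `si_vsa_pol` | vsa_pol / MW | Å²·mol/g | size-intensive polar surface; both H-bond donors and acceptors count as polar |

Missing-value imputation is fixed and auditable: missing basic pKa → 0
("no basic group"), missing acidic pKa → 15 ("no acidic group"), missing
heavy-atom count k → 12. Every imputed entry is flagged in the sidecar
flags table. The logarithm base of the weight correction is 10
(consistent with logP's scale) and is a named constant.

Ionization categories use the relevance windows basic pKa ≥ 3 and acidic
pKa < 10; an acid plus at least one relevant base is a zwitterion, values
outside both windows give category `none`. These windows are applied to
*pre-imputation* values so genuine missingness stays visible.

logP, pKa, vsa_pol, HBD/HBA are inputs from external property calculators.
The structure-based vsa_pol surrogate (Labute approximate-surface-area
contributions summed over N/O atoms and their hydrogens) is clearly flagged
`surrogate` and intended only for screening libraries without precomputed
values.

Count descriptors are SMARTS-based; the patterns are documented choices,
fixed in one place (`descriptors._SMARTS`): quaternary N = `[N+;X4;H0]`,
carboxylic acid = `[CX3](=O)[OX2H1]`, amine = neutral trivalent
non-aromatic N that is not an amide/sulfonamide N, amidine/guanidine motif
= `[NX3][CX3]=[NX2]`. Partial-charge descriptors are not implemented (no
charge model is bundled); 3D conformer-dependent descriptors are out of
scope.

Rule-of-Five violation = any of MW > 500, logP > 5, HBD > 5, HBA > 10
(strict inequalities); missing inputs give an explicit not-evaluable
result which is excluded from contingency tables.

## Lysosomal accumulation model

Four well-stirred compartments — external medium, cytosol, lysosome,
mitochondrion — connected external↔cytosol↔{lysosome, mitochondrion}.
Within a compartment the compound speciates instantaneously
(Henderson–Hasselbalch; for the zwitter variant the basic and acidic sites
dissociate independently). Fluxes per membrane and species:

* neutral species: J = Pₙ (c_out − c_in), with
  log₁₀ Pₙ = min(logP, 4) + log₁₀(perm_scale). The cap at logP 4 models the
  unstirred-layer limit of transmembrane permeation.
* charged species (charge z): Goldman/Nernst–Planck constant-field flux
  J = Pᵢ N (c_out − c_in·eᴺ)/(eᴺ − 1), N = zFE/RT, with E the membrane
  potential (inside − outside) and Pᵢ = Pₙ·10⁻³·⁵. The net-neutral
  zwitterion crosses with Pᵢ and no field term.
* lipid sorption: fraction dissolved in water
  w = 1/(1 + lipid_fraction · Σ_s f_s K_s), K = 10^logP for the neutral
  species and one tenth of that for ions. Sorption is *not* capped, so very
  lipophilic compounds present a large depot with bounded flux — the model
  origin of slow accumulation at high logP; a second basic centre slows
  accumulation through a vanishing neutral fraction.

Defaults (one preset, every constant overridable, YAML-serialisable):
pH 7.4 external (7.5 in the DMEM preset), 7.2 cytosol, 5.0 lysosome,
8.0 mitochondrion; membrane potentials −70 mV plasma, +10 mV lysosome,
−160 mV mitochondrion; volumes 1000 / 1 / 0.01 / 0.05 (relative);
area-to-volume ratios 6 / 100 / 50 folded with perm_scale = 0.1 min⁻¹ into
first-order rates; lipid fraction 0.05 in all cell compartments;
T = 310.15 K; external concentration 10 µM (the assay's test
concentration). Units: µM, minutes, mV.

Because speciation fractions are fixed per compartment, the system is
linear in the total concentrations; the steady state is computed exactly
by solving the 3×3 linear system, and the time course by LSODA with the
exact constant Jacobian. In a closed-system configuration (finite external
reservoir) total mass is conserved to ~10⁻¹⁵ relative. `required_incubation`
reports the first time the lysosomal concentration reaches 95 % of steady
state (the documented operationalisation of "minimal but sufficient"
incubation; the fraction is a parameter), compared against the standard
30-minute screening window; exceeding the cap returns infinity.

In the neutral-species-dominated limit the steady-state lysosome/external
ratio equals the closed-form Henderson–Hasselbalch ion-trap expression for
all four variants (verified to 10⁻⁴ relative over randomized
configurations), and the monobase ratio is monotone in pKa up to a plateau
near pKa ≈ pH_ext + 4. At the default ionic permeability (10⁻³·⁵ of
neutral) the ratio instead *peaks* near pKa ≈ 8.5 and declines — the
cation leak through the charged species, pushed by the positive lysosomal
potential, caps the trap for very strong bases. Both behaviours are
physically expected; the monotonicity property is therefore asserted in
the low-ionic-permeability regime where the closed form applies.

## Classifier and validation

Random forest with the fixed study hyperparameters: 51 trees, terminal
node size 1, depth ≤ 8, Gini splits, mtry = ⌊log₂ m⌋ + 1 features per
split (natural log available via `mtry_log_base`), bootstrap row
resampling, majority vote. The implementation drives scikit-learn's
compiled tree builder directly; a `DecisionTreeClassifier`-based backend
with identical semantics exists as a fallback and a test asserts their
agreement. All randomness flows from explicit integer seeds through a
counter-based SHA-256 fan-out (`fiasma._rng`), so every result is
bit-reproducible.

Validation is bootstrap resampling (default n = 200): fit on a
with-replacement sample of rows, evaluate on the out-of-bag rows; means
and *across-resample* SDs of the Youden index and accuracy are reported.
Resamples whose out-of-bag set lacks a class are redrawn (counted; > 50 %
redraws abort). The optimism-corrected .632 estimator
(0.368·resubstitution + 0.632·OOB) is available behind a flag.

Feature selection: a near-zero-variance filter (variance of the
range-scaled column < 10⁻⁸, configurable), then a candidate pool formed as
the union of the top-q columns under correlation, information-gain and
ReliefF weightings (q default 30), pruned for collinearity: candidates are
visited in decreasing combined rank weight and dropped at |Pearson r| >
0.90 to an already-kept candidate, so each signal axis enters the search
once, represented by its best-weighted descriptor.

Beam search (default width 10) grows combinations one descriptor at a
time, scored by the mean bootstrap Youden index. Two deliberate
variance-reduction choices: (1) *common random numbers* — every candidate
combination is scored on the same bootstrap resamples, so comparisons are
paired and small true differences are not drowned by resampling noise;
(2) *two-stage selection* — per size, the top few beam members are
re-validated at the full resample count and the best of that shortlist is
the reported winner. Ties break toward fewer descriptors, then
lexicographic order.

Y-scrambling refits and re-validates the fixed combination under uniformly
permuted labels (default 1000 permutations); the null mean ± SD of the
per-permutation mean Youden/accuracy and the z-distance of the true score
are reported. On imbalanced labels the null accuracy falls below the
zero-rule accuracy, as expected for a forest trained on noise.

## Structural diversity

Typed-triangle 2D pharmacophore fingerprints: atoms are typed by SMARTS
rules (donor, acceptor, cation/protonizable N, anion/acidic O, aromatic,
hydrophobe; an atom may carry several types), every typed atom triple
yields a key of the three types plus pairwise topological distances binned
into {1, 2, 3, 4–5, 6–8, 9+}, canonicalized over vertex orderings.
Molecules with fewer than three typed atoms fall back to pair/single keys.
Similarity is the Tanimoto coefficient on key sets (two empty sets define
similarity 1). Clustering is hand-rolled agglomerative with complete
linkage (guaranteeing all within-cluster pairs meet the cutoff — the
definition "clusters at 0.85 similarity" relies on this), deterministic
lexicographic tie-breaking (hence permutation invariance), and early stop
at the cutoff; single and average linkage are available but carry no such
guarantee. `div_rel` = clusters at the cutoff / compounds.

This triangle-key dialect is an open implementation; absolute `div_rel`
values are only comparable within one dialect. On the synthetic libraries
`div_rel` is additionally dominated by set size (template-derived
structures), so cross-set comparisons there are not meaningful; the test
suite asserts the measure's properties (1/N, 1.0, cutoff monotonicity)
and a size-matched comparison — a close-analogue series scores well below
an equally sized set of unrelated scaffolds, which is the signal the
measure exists to detect. Real compound collections, which are not built
from a small template grammar, do not share this size confound to the
same degree.

## Virtual screening and enrichment

Exclusions are applied in fixed order: (1) compounds whose model
descriptors are incalculable, (2) quaternary nitrogens (`[N+;X4;H0]` — no
passive membrane permeation, outside the model's applicability domain),
(3) duplicates by canonical salt-stripped SMILES (largest fragment; first
occurrence kept). All counts reconcile with the input size by
construction. Per drug group, enrichment of predicted actives is tested
one-sided via the hypergeometric tail (exact Fisher), BH-adjusted across
groups at 0.05; compounds may belong to several groups and are counted
once per group. The global heterogeneity test is a chi-square contingency
test over the group × class table, labelled an approximation to a global
exact test. ATC-style group labels can be derived from codes at any
classification level (default level 2, the therapeutic main group). The
Rule-of-Five association uses the Pearson chi-square without continuity
correction (Yates variant behind a flag). The logBB association
cross-tabulates activity against logBB ≥ 0 and *lists* any active
compound with logBB < 0 as a violation of the expected pattern rather
than failing.

## Synthetic data generator

The generator defines the study conditions the test suite runs under:

* 276 compounds; ionization mix 23 acid / 155 monobase / 22 zwitter /
  45 bibase / 31 none (9 of the 31 with no ionizable group, the rest with
  out-of-window pKa values), sampled proportionally.
* Physicochemical inputs per compound: MW ~ N(360, 85) clipped to
  [88, 850] g/mol, logP ~ N(3.5, 1.6) in [−3, 9], category-conditional pKa
  values (monobase ≈ N(8.6, 1.4) ≥ 3; bibase pKa₂ below pKa₁; acids/zwitter
  acidic pKa ≈ N(4.5, 1.5) < 10), vsa_pol coupled to H-bond counts.
* Activity mechanism: a latent utility = 1.6·(logp_logweight − 2.2) +
  0.5·(pka_sum − 8.2) + 0.7·(pka_acid − 13) − 30·(si_vsa_pol − 0.22) +
  offset + logistic noise (scale 0.5); the top 26.6 % utilities are the
  generated actives. This is the logistic activity model conditioned on
  the panel's designed class proportion, so realized class counts sit at
  the 72/204 design with only the measurement-noise wobble. The
  coefficients were calibrated once so that the four-descriptor forest's
  bootstrap Youden index lands in the 0.68 ± 0.09 regime of the
  experimental study, and frozen.
* Residual activity: the latent compound value is drawn from the class's
  mode — active N(32, 6) truncated to [0, 50], inactive N(85, 10)
  truncated to (50, 120] — and the *observed* value adds replicate noise
  N(0, 16/√3) (mean of three replicates, each with SD 16), clipped to
  [0, 120]. Observed values can therefore cross the 50 % threshold: about
  3–4 % of labels flip relative to the generating class, which produces
  the near-threshold low-reliability calls and bounds achievable
  validation scores, as in real assays. With replicate noise set to 0 the
  observed labels reproduce the generating class exactly.
* Structures are template molecules: category-specific scaffolds
  (carboxylic acids *and* phenols for acids, aliphatic amines *and* a
  pyridine-type base for monobases, piperazines/diamines, amino acids,
  ethers/esters for neutrals) decorated by an aromatic substituent, a
  second ring substituent and an aliphatic tail decoded from a
  per-category counter, with a canonical-SMILES uniqueness guard — every
  non-duplicate compound has a unique structure, so the duplicate filter
  sees exactly the planted duplicates. Structures exist to exercise
  parsers, count descriptors, filters and fingerprints; they are not
  realistic chemical space, and count descriptors correlate with the
  ionization category by construction (as functional groups do in
  reality).
* logBB for a ~23 % subset, conditioned on the observed call: observed
  actives draw max(N(0.7, 0.4), 0) — measured inhibition implies the
  compound reached the lysosome — inactives draw N(−0.2, 0.6).
* Libraries: `drug_like` (2000 compounds, shifted logP/pKa mix, ~7 %
  generated actives, 20 groups with three planted enriched groups at odds
  16, so the planted groups carry ~¾ of active memberships) and
  `natural_like` (800 compounds, acid/neutral-heavy, < 1–2 % active, plus
  exactly 13 descriptor-incalculable entries, 2 quaternary-nitrogen
  compounds and 17 exact duplicates to exercise the screening filters).
* Everything derives from one master seed via the SHA-256 counter scheme;
  same (config, seed) → bit-identical output.

What passing tests on this generator do and do not show: they demonstrate
that the pipeline recovers a planted physicochemical mechanism, its null
calibration, its filter arithmetic and its enrichment statistics under the
study's sample sizes and noise levels. They do not validate the chemistry
of real property calculators, the realism of the structure templates, or
absolute diversity values.

## Problem sizes in the standard runs

The default test suite and the acceptance script use scaled problem sizes
chosen as reasonable analysis defaults: beam search with width 4 over the
pruned pool (~10 candidates), 30 scoring resamples with a 4-candidate
final refinement at 200 resamples; Y-scrambling with 100 permutations ×
25 resamples (the pipeline default remains 1000 permutations × 200
resamples, and the report labels any scaled run); bimodality recovery
over 20 generator seeds; enrichment oracle enumeration over all 2×2
tables with margins ≤ 30. Full-scale settings are one parameter away in
every case.

## Known limitations

* The cell model is a single-cell compartment model: no transporters, no
  drug-induced pH shifts, no cytotoxicity; the mitochondrion is simulated
  but unused downstream.
* The vsa_pol surrogate is an approximation and flagged as such; models
  trained on calculator-supplied vsa_pol should be applied to libraries
  with the same provenance.
* The triangle-fingerprint dialect is package-specific; compare `div_rel`
  only within one dialect, and beware its dependence on set size.
* The classifier is qualitative (binary) by design; it does not predict
  IC50s or in-vivo exposure.
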