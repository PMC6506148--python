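# Methods

## Consensus filter

Scores are docking energies: lower is better (a `lower_is_better` flag on
the table flips the convention when a scoring function reports the
opposite sign). Percentiles within a model column use the minimum rank of
a tied block divided by the count of non-absent scores, so a fully tied
column of n compounds places everything at percentile 1/n — a column that
carries no information cannot push its whole library into the "top 10%".
Absent cells (compound never docked to that model, marker `NA`) are
excluded from the column's ranking denominator and never qualify.

Stage 1 keeps a compound when its percentile is ≤ q₁ in ≥ m_min models
and represents it by the minimum score over the *qualifying* models (the
best scoring pose among the models that voted for it). Stage 2 computes
each compound's percentile within its target's stage-1 hit list — the
"top 25%" base is the per-target hit list, not the full library; a
compound absent from a target's list simply does not support that
target. The final ordering (ascending mean of supporting-target
percentiles, ties by broader support then compound id) is the package's
own convention: some deterministic total order is needed to report a
consensus rank, and the mean hit-list percentile is the least surprising
aggregate of what stage 2 already measures. All orderings fall back to
lexicographic compound id, so reruns are byte-identical.

The screen summary reports the final library fraction to three
significant figures (247 of 2,200,000 → 0.0112%) and the total docking
effort as library × targets × models.

## Pocket volumetrics

The free volume of a binding pocket is measured on a cubic lattice
(default spacing 1.0 Å, probe padding 0.0 Å — both exposed because
published grid tools differ) anchored at the minimum corner of the
inclusion region's bounding box, which makes results reproducible
bit-for-bit for a given structure/region/spacing. A point is free iff it
lies inside at least one inclusion sphere (boundary inclusive) and at
distance strictly greater than atom radius + probe padding from every
atom. Radii are a fixed heavy-atom table (C 1.70, N 1.55, O 1.52,
S 1.80 Å; anything else defaults to 1.70 Å with a warning); hydrogens
and waters are skipped by default when reading PDB files (gemmi does the
parsing). An optional contiguity filter keeps only the 26-connected
component containing a seed point, for regions that bleed into solvent.

The inclusion region must be supplied by the user as a sphere list: the
DFG pocket has no canonical geometric definition, so no automatic pocket
detection is attempted. Published per-kinase pocket volumes depend on the
authors' models and region and are not reproducible from geometry alone;
correctness is instead established on analytic fixtures: a spherical
cavity converges to (4/3)πr³ as spacing shrinks (0.5% error at r = 5 Å,
0.5 Å spacing; the test tolerance of 2% comes from the observed
convergence at 1.0 Å), full occlusion gives exactly zero, shell volumes
are additive, and volume ordering matches analytic cavity sizes. Volume
is monotone under adding atoms (↓) or inclusion spheres (↑) and invariant
under lattice-aligned rigid motions up to grid tolerance.

## Enrichment

ROC-AUC is computed as the rank statistic — the probability that a random
active scores strictly better than a random inactive, ties counted ½ —
rather than by integrating an explicit curve; the two agree, but the rank
form is exact under ties and trivially oracle-checkable by pair counting
(the test suite also cross-checks scikit-learn's trapezoid AUC).
EF(f) uses a ceiling cutoff, count = ⌈f·n⌉, with boundary ties resolved
by compound id; no standard EF formula exists in the literature at this
level of detail, so the deterministic choice is documented here.

## Assay statistics

Viability is 100·A/P per replicate vial, with P (empty pupal cases) as
the denominator — the assay counts eclosion events, not seeded embryos,
so a vial with P = 0 has no defined viability and is an error. "Student's
t-test" is read as the classical pooled-variance unpaired test
(df = n₁+n₂−2), one-sided with alternative treated > control, on the
percent viabilities of replicates; Welch is available behind a flag.
Zero pooled variance is handled explicitly: equal means give p = 0.5, a
treated excess gives p = 0 flagged `degenerate`, a deficit p = 1.

The toxicity gate requires *every* wild-type replicate above the
threshold (default 90%), the conservative reading of an "all doses
tolerated" criterion. Synergy is declared when the combination mean
strictly exceeds the sum of the single-agent means *and* the combination
beats the better single arm in a one-sided pooled t at α = 0.05
(computed from summary statistics, since arms may be reported as
mean ± sd × n). This additive-excess rule is deliberately informal — a
6% combination against 3% + 1% singles is the canonical positive — and
is not an isobologram analysis; it is order-invariant in the two single
arms and errors when the arms reference different vehicle controls.

## Synthetic generators

`simulate_scores` uses a one-factor Gaussian model: per target, compound
i draws a latent affinity zᵢ ~ N(0,1), and model j observes
√ρ·zᵢ + √(1−ρ)·εᵢⱼ, so ρ ∈ [0,1) is exactly the inter-model score
correlation the consensus filter exploits. A planted active set (default
50 of 2,000 compounds, a 2.5% spike typical of retrospective benchmarks)
is shared across all targets — the polypharmacology scenario the
cross-target stage is designed for — and has its per-target latent
shifted down by `effect_shift` score units (default 2.0, i.e. a
√ρ·effect_shift shift in each model's score). Defaults are the desk-scale
study conditions: 2,000 compounds, 4 targets × 10 models, ρ = 0.5.

This generator is a statistical stand-in, not a docking model: real score
distributions are heavy-tailed, chemistry-correlated and model-specific,
so passing tests demonstrate the correctness and selectivity mechanics of
the filter, not performance on real screens. One consequence is worth
stating plainly: at the default separation (effect_shift 2, ρ 0.5) the
stage-1 survivors among the inactives are precisely the extreme tail of
the latent distribution and are statistically indistinguishable from the
planted actives, so end-to-end recovery of the planted set is low (~6%
mean over ten seeds; frozen as a ≥4% regression guard). Majority
(>50%) recovery emerges only under strong separation — effect_shift ≳ 3.5
at ρ = 0.5, or ≳ 3 at ρ = 0.7 — which the suite tests as a separate
property. Published screens operate in that strong-separation regime for
genuine type-II binders (a reference inhibitor ranking in the top ten of
a 2.2 M screen implies far more than 2σ of separation).

`simulate_assay` fixes P per vial (default 100 seeded-embryo scale) and
draws A ~ Binomial(P, v/100); `make_toy_pocket` emits
structure/region/closed-form triples (sphere, shell, partially blocked
sphere with the sphere–sphere lens subtracted analytically) used as
volumetrics oracles.

## Problem sizes

The test suite and acceptance script run the synthetic screen at
n = 2,000 × 4 targets × 10 models over ten seeds (seconds per run), grid
fixtures at 0.25–1.0 Å spacing on ≤ 6 Å regions, and exhaustive
enumeration oracles at n ≤ 30. These sizes were chosen so the full
consensus combinatorics, including the cross-target stage, are exercised
at a scale where brute-force verification is feasible.

## Known limitations

- No docking, rescoring, pose geometry or homology modelling; the
  consensus module never reads molecule structures.
- The final consensus ordering is a package convention; other reasonable
  orderings (e.g. best single-target percentile) would permute ranks
  without changing membership.
- Fingerprint generation is delegated (RDKit Morgan by default); Tc
  values are scheme-dependent and only comparable within one scheme.
- The synergy rule is a screening heuristic, not a dose–response model.
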