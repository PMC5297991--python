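# Methods

## Scope and model

famcoseg implements a family-based rare-variant discovery design for a
dominant trait with incomplete penetrance.  Its four stages are a
pipeline, each usable alone:

1. **Linkage scan** (affected-only, nonparametric) over a genome-wide
   biallelic marker panel,
2. **intrafamilial control selection** by minimal regional IBD,
3. **variant filter cascade** over annotated dual-caller exome VCFs,
4. **segregation extension** in the full pedigree plus database-frequency
   and cohort-frequency evaluation.

The disease model assumed throughout: within each multiplex family a
single rare autosomal-dominant variant raises risk; carriers develop the
biopsy-proven phenotype with penetrance `f_carrier`, may instead show
persistent urinary abnormalities, or remain unaffected (obligate-carrier
configurations); non-carrier phenocopies are rare.  "Affected" in the
scan means biopsy-proven cases only — which phenotype codes count is a
parameter (`affected_by_family` in `npl_scan`), because intermediate
phenotypes are real but unreliable.

## Pedigrees and state space

Six-column PED I/O with one extension: phenotype code 3 denotes
documented urinary abnormality (codes 0/−9 unknown, 1 unaffected, 2
affected).  Individuals with only intermittent findings should be coded
unknown.  Half-founders are completed with flagged synthetic spouses.

The exact multipoint machinery (`PedigreeHMM`) enumerates inheritance
vectors: two meiosis bits per non-founder, reduced by founder-phase
symmetry (one designated transmission bit per founder fixed to 0),
leaving `b = 2n − f` effective bits.  Emissions and the allele-sharing
statistic are invariant under founder-phase flips, so they are evaluated
once per equivalence class; the forward–backward recursion runs in the
full `2^(2n)` space, where the Haldane transition kernel factorizes into
independent per-bit flips (`θ = ½(1 − e^(−2d/100))`, d in cM, no
interference).  The default feasibility gate is `b ≤ 16`; larger
pedigrees are rejected with advice to split.

Marker emissions sum founder-allele assignments weighted by population
allele frequencies.  Two code paths produce identical values (tested
against each other): a generic founder-allele-graph elimination
(depth-first with unary and pairwise genotype constraints), and a
vectorized path used when every founder is typed, which enumerates only
heterozygous-founder phases.

## Marker QC

Individuals are screened before markers: missing-call fraction > 5% or
Mendelian-error fraction > 5% excludes the individual.  Markers then
fail on the founder-only Hardy–Weinberg exact test (p ≤ 10⁻⁶; the
Wigginton–Cutler–Abecasis two-sided convention, exact rather than χ²
because founder counts are small, founders only to avoid relatedness
inflation) or minor allele frequency ≤ 0.05.  LD handling is greedy
r²-threshold pruning on founder genotype correlations (drop when
r² > 0.10 with a retained marker in the window): simpler and more
conservative than modelling marker clusters, and adequate for synthetic
panels whose LD comes only from map distance.

## NPL scoring

`S_all` is computed per class from founder-allele labels, vectorized
over classes; null mean and variance come from exhaustive enumeration
over the uniform vector distribution (uniform over classes, since the
founder-phase group acts freely).  A family whose affected set has zero
null variance — e.g. an affected founder–offspring pair, which always
shares exactly one allele — is flagged uninformative and contributes
Z = 0.

Per position, `Z_f = Σ_v P(v|data)(S_all(v) − μ)/σ`.  The Kong–Cox
linear model maximizes `Σ_f log10(1 + δ Z_f)` over `δ ∈ [0, δ_max]` by
bounded scalar optimization (xatol 10⁻¹⁰).  `δ_max` is set from each
family's *minimum achievable* Z (`δ ≤ min_f −1/Z_f,min`), which keeps
the tilted sharing distribution a valid probability distribution — the
constraint the model's mixture null depends on.  (If minima are not
supplied, the bound falls back to the observed scores with a cap of 10.)
`p = ½ Pr(χ²₁ > 2 ln10 · LOD)`, with p = 0.5 at LOD 0; the inverse uses
the χ² quantile, and the round trip is exact to 10⁻¹⁰ relative error.

Linked regions are maximal runs of positions with LOD strictly above
the 1.5 threshold; bounds extend outward to the flanking sub-threshold
markers' physical positions and are reported as inclusive 1-based
intervals (BED export converts to 0-based half-open).  Ties in the peak
go to the leftmost maximum.

## Control selection

Regional IBD for a pair is the posterior-expected shared-allele
proportion, averaged uniformly over the evaluation grid inside the
region; with a uniform posterior it equals twice the kinship
coefficient for non-inbred pairs (a tested identity).  The control
minimizes the mean of its regional IBD with the two affecteds; ties
break toward larger mean kinship (the "closest relative" desideratum,
secondary because the control's role is genetic discordance), then
lexically smallest id, making selection fully deterministic.  A
per-affected maximum IBD column is reported as an alternative metric
for the case of distantly related affecteds.

## Filter cascade

Gates and boundary semantics, in funnel order per caller: QUAL ≥ 30,
MQ ≥ 40, maximum carrier depth ≥ 5 (a site below the depth gate is
rescued iff the alt was called in both affecteds — low-coverage
variants seen twice are unlikely to be artefacts), FS < 60; drop
EUR MAF strictly above 1% (absent MAF = not in the reference panel =
treated as rare); drop LOW impact (synonymous) — HIGH, MODERATE and
MODIFIER all pass, because regulatory (UTR/up/downstream/intron)
variants are first-class candidates; keep positions inside any linked
interval (inclusive).  Multi-allelic sites are split into biallelic
records before filtering, with per-alt dosages.  The four record-level
gates commute; per-stage counts are still reported in the order above
and must be non-increasing (an integrity error otherwise).

Caller merge unions records on (chrom, pos, ref, alt); genotype
disagreements keep the first caller's genotypes and set a
`discordant_callers` review flag — together with an optional
repeat-region flag this replaces manual IGV inspection, which is not
automatable.  Co-segregation keeps variants carried by both affecteds
with a *called* homozygous-reference control: a missing control
genotype drops the variant, since absence cannot be asserted from a
no-call.  Prioritization keeps CADD strictly above 5, descending, with
an include-list escape hatch (gene symbols or chrom:pos) appended after
the scored block for externally motivated candidates.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
three-generation multiplex families (founding couple, children, a
married-in spouse, grandchildren), gene-dropping with Haldane
recombination on a linear 1 cM/Mb map, one causal variant per family on
a single founder haplotype inside a configurable region (distinct
positions across families), Poisson background variants with
configurable MAF spectrum (point mass at "absent" = private, a common
fraction above the 1% gate), categorical effect terms with derived
impact classes, exponential CADD scores, dual callers with independent
per-variant sensitivities, genotype error, missingness, and
pass-dominant site QC values with a configurable hard-filter failure
fraction.  Depth is a negative-binomial draw (mean 20, dispersion 5);
only its interaction with the depth-rescue rule matters.

Defaults are the study conditions: 8 families, 2 chromosomes × 11
markers at 10 cM spacing, causal region chr1:45–55 Mb, `f_carrier` 0.6,
`p_ua_carrier` 0.5, phenocopy 0.001, 60 expected background variants
per family, caller sensitivities 0.95, genotype error 0.002,
missingness 0.01.  The penetrance and nuisance values are explicit
choices of a plausible dominant-disease regime, not estimates.  Marker
informativeness is switchable between fully informative (each founder
haplotype its own allele — the clean-room setting for exact-sharing
experiments) and biallelic with MAF drawn from (0.3, 0.5).

What the generator does **not** emulate: real LD structure (only
map-distance decay), population demography or stratification,
read-level artefacts (no FASTQ/BAM), annotation realism (effect terms
and CADD are parametric draws, no database is consulted), and
variant-calling error that correlates across callers.  Passing tests
therefore demonstrate the *statistical machinery* under its stated
assumptions, not robustness to real-data pathologies.

## Experiments and problem sizes

The packaged experiments choose sizes that make their asymptotics or
determinism valid while staying desk-scale:

* **Null calibration** (`null_lod_exceedance`): 32 affected-sib-pair
  families at one fully informative locus, 5,000 replicates.  The
  Kong–Cox ½χ²₀+½χ²₁ null is asymptotic in the number of families;
  exact enumeration of the sib-pair score lattice puts the true
  exceedance at ~0.0088 for 8 families but ~0.0042 at 32, against the
  analytic level 0.0043 — so the experiment is run where the asymptotic
  claim is meaningful.
* **Causal recovery** (`causal_recovery`): noiseless configuration
  (full penetrance for the sequenced affecteds, no phenocopies, perfect
  caller sensitivity, no genotype error), 50 seeds × 2 families, the
  configured causal region supplied as the linked interval (separating
  cascade behaviour from linkage power).  Survival is 100% with a
  non-carrier control and 0% with a carrier control, by construction of
  the co-segregation rule.
* **Region coverage** (`region_coverage`): 16 families of the larger
  3-children/3-grandchildren shape, fully informative markers.  Affected
  founder–offspring pairs are sharing-uninformative, so reliable
  LOD > 1.5 calling needs several informative affecteds per family at
  roughly the real multiplex-study scale.
* **Haldane check**: 10,000 simulated meioses at 50 cM against
  `½(1 − e⁻¹) = 0.3161`.

## Worked candidate table

A 33-row validated-candidate table ships with the package
(`data/table3.tsv`) and drives the classification rules end to end:
validation states (`Yes`, `Yes + Control`, `Repeat region`,
`Not confirmed`), ExAC/1000 Genomes tokens (numeric, `Absent`, `NC`).
Two conventions matter: `NC` — a position outside ExAC's coding-centric
callable capture — counts as absent for the private/rare partition (the
only reading consistent with the table's own summary arithmetic), and
repeat-region rows count as not validated.  The cohort
carrier-frequency evaluation reports both the naive smallest-detectable
frequency `1/(2n)` and the exact one-sided 95% upper bound
`1 − α^(1/(2n))` for a zero-carrier screen (Clopper–Pearson for nonzero
counts); neither is privileged since they answer different questions.

## Known limitations

* Exact linkage only (`b ≤ 16` bits); no approximate fallback for large
  pedigrees — split them instead.
* Linear Kong–Cox model with equal family weights; no exponential
  model, no parametric LOD, no X chromosome, no variance components.
* LD pruning rather than cluster modelling; on dense real panels this
  discards information.
* The pipeline consumes annotated VCFs; alignment, calling, VQSR,
  effect annotation and CADD scoring are upstream of it by design.
* Genotype discordance between callers keeps one genotype set and
  flags; no attempt at genotype reconciliation.
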