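# Methods

## The model

covcoloc compares two association signals over a genomic locus under the
single-causal-variant colocalization model. For each variant the evidence
for association with one trait is summarised by the Wakefield asymptotic
log Bayes factor

    lABF = ½ [ ln(1 − r) + z² r ],    r = W / (W + V),

where z = β/se, V = se² is the sampling variance of the effect estimate and
W is the prior variance of the true effect. When only a p-value, allele
frequency f and sample size N are available, |z| is reconstructed from the
two-sided p through a log-quantile path (`scipy.special.ndtri_exp`), so
p-values down to the smallest positive double never produce an infinite z,
and V is approximated as

    V ≈ sdY² / (2 N f (1−f))                      (quantitative traits)
    V ≈ 1 / (2 N f (1−f) s (1−s))                 (case-control, case fraction s)

Assuming at most one causal variant per trait, the five hypotheses are
H0 (neither trait associated), H1/H2 (only trait 1/2), H3 (both, distinct
causal variants) and H4 (both, shared causal variant). With per-variant
configuration priors p1, p2, p12 the per-hypothesis Bayes-factor sums are

    BF(H1) ∝ p1 Σᵢ e^{a_i}          BF(H2) ∝ p2 Σⱼ e^{b_j}
    BF(H4) ∝ p12 Σᵢ e^{a_i + b_i}   BF(H3) ∝ p1 p2 Σ_{i≠j} e^{a_i + b_j}

with a, b the two lABF vectors. The H3 sum is evaluated through the O(Q)
identity Σ_{i≠j} = (Σᵢ e^{a_i})(Σⱼ e^{b_j}) − Σᵢ e^{a_i+b_i}, computed in
log space as L1 + L2 + log1p(−exp(S − L1 − L2)) and set to −∞ when
S ≥ L1 + L2 (in particular for single-variant loci, where PP-H3 is exactly
zero). Posteriors are the softmax over (0, ln BF(H1..H4)). Conditional on
H4, each variant's posterior probability of being the shared causal variant
is softmax(a + b); ties at the maximum resolve to the smallest genomic
position (the vectors are position-sorted and argmax takes the first
maximum). An O(Q²) enumeration over all causal configurations, with no
algebraic shortcut, ships as `coloc_oracle_enumeration` and is used as an
independent cross-check in the tests (agreement within 1e-10 per
posterior).

### Priors and effect-size scales

Defaults are the conventional single-variant colocalization priors
p1 = p2 = 1e-4, p12 = 1e-5, and prior effect SD W^½ = 0.2 on the log-odds
scale for case-control traits and 0.15·sdY for quantitative traits (eQTL
slopes are treated as standardized expression, sdY = 1). All are
config-exposed. The evidence mode is "auto": β/se are used whenever both
are complete on a side, otherwise the p-value approximation; the two sides
of a pair may use different modes.

## Harmonization

Pairs of tables are matched on (chromosome, position). Records whose
ref/alt labels agree are taken as-is; swapped labels flip the second
table's β sign and complement its allele frequency; any other allele
combination is dropped and counted. Strand-ambiguous pairs (A/T, C/G) are
kept only on an exact label match, since a label swap cannot be
distinguished from a strand flip — a conservative rule. Coordinates are
1-based throughout; only emitted BED files are 0-based half-open.

## Locus detection and taxonomy

A locus is seeded by any variant with p < 1e-7 (strict) in any study of
the panel, expanded by ±500 kb, and overlapping or book-ended intervals are
merged (distance-0 merge semantics). Genes map to loci by ≥ 1 bp overlap of
the full gene-body interval — the most inclusive reading.

The panel is 4 phenotypes (A2 very severe respiratory COVID-19 vs
population; B1 hospitalized vs non-hospitalized patients; B2 hospitalized
vs population; C2 all patients vs population) × 2 ancestries (European-only
vs multi-ethnic) × 2 control sets (with/without UK Biobank). Per locus,
all 120 unordered study pairs are colocalized and the taxonomy is:

* **susceptibility** — some C2–C2 pair has PP-H4 > 0.9. This overrides
  severity even when A2/B2 also colocalize, because their population
  controls make them sensitive to susceptibility as well.
* **severity** — no C2 pair colocalizes but a within-phenotype A2, B1 or
  B2 pair does.
* **two signals** — some pair colocalizes while another pair of
  locus-significant studies has PP-H3 > 0.5. Requiring both members to be
  locus-significant avoids H3 calls driven by a study with no signal,
  where H3 is prior-dominated. The 0.5 cutoff for "high PP-H3" is a
  config-exposed choice; no published cutoff exists.
* **ethnicity-specific** — within some phenotype, either a within-ancestry
  pair colocalizes or only one ancestry reaches significance, while every
  cross-ancestry pair of that phenotype has PP-H4 < 0.5 (missing
  cross-ancestry results count as failure to colocalize, covering variants
  untestable in one ancestry).

Flags whose phenotypes are absent from a partial panel are reported as
not-evaluable (`NA`), never false. GWAS-pair colocalization uses the strict
rule PP-H4 > 0.9; eGene calling is non-strict (best PP-H4 ≥ 0.9 over
tissues and the phenotype's studies, with a suggestive band
0.5 ≤ PP-H4 < 0.9) — both conventions appear in the reporting tradition
this pipeline follows and both thresholds are configurable.

A reduced classifier operates on per-phenotype maxima of within-phenotype
PP-H4 (susceptibility iff max C2 > 0.9, else severity iff max over
A2/B1/B2 > 0.9, else unassigned); it is what the packaged published-table
replay uses, and it agrees with the full classifier whenever the
ethnicity/two-signal flags are off.

## Synthetic data

GWAS summary statistics are simulated at the z-score level: for a locus of
Q variants with target LD correlation R and noncentrality vector λ (the
expected z at causal variants), marginal z-scores are drawn as
z ~ MVN(Rλ, R) — the standard asymptotic distribution of marginal
association statistics under a joint model. Standard errors come from the
frequency/sample-size approximation above, so β = z·se and
p = 2Φ(−|z|) complete the table. This is sufficient for ABF colocalization
and deliberately does not model genotypes, imputation error, or sample
overlap between studies (a known caveat of colocalization that the
pipeline does not treat).

Benchmark conditions (the package's study conditions, fixed once): Q = 500
variants per locus, block-diagonal AR LD with blocks of 50 and ρ = 0.95,
λ = 8 at causal variants, 16 studies with n ≥ 10,000 (A2/B2/C2:
n = 100,000 with case fraction 0.05; B1: n = 20,000 with case fraction
0.30, mirroring its much smaller patient-only design). Baseline allele
frequencies are drawn once per locus from U(0.05, 0.5) and shared across
studies. Scenario recipes: *susceptibility* (shared causal across the four
C2 studies), *severity* (across B2), *ethnicity-specific* (causal
frequency 0.25 in multi-ethnic studies but near-monomorphic, 0.005, in
European-only studies, which therefore carry no noncentrality at it — the
variant stays in their tables, only uninformative), *two-signal* (C2
driven by one block's variant, B1
by a distant block's, cross-block r = 0), *null*, and the
*phenotype-distinct* (each phenotype its own causal variant; used for the
within- vs between-phenotype comparison). Fixtures are deterministic given
the master seed; per-locus and per-study child seeds derive from numpy
`SeedSequence` spawning.

Haplotype pools (used only for LD reporting, never for association
simulation) are generated per block by a stationary two-state Markov chain
with marginal frequency f and transitions P(1→1) = f + ρ(1−f),
P(0→1) = f(1−ρ), whose lag-k allele correlation is exactly ρ^k. A
dichotomized-Gaussian construction was rejected because thresholding
attenuates correlation (latent ρ = 0.9 at f = 0.5 yields binary r ≈ 0.71),
which would miss the generator's own accuracy contract of |r − ρ^|i−j|| <
0.05 at pool size 10,000. The chain requires ρ ≥ 0 and a common frequency
per block; negative-ρ LD is supported in the Gaussian z-simulation only.

What passing these benchmarks shows — and does not show: the engine
recovers the generating hypothesis and the taxonomy recovers scenario
labels under idealized LD, exact effect-allele alignment, and a correctly
specified single-causal model. Real panels add cross-study heterogeneity,
multi-causal loci, allele-frequency mismatch and sample overlap; results
there depend on those violations, not on the machinery verified here.

## Numerical choices

* All probability algebra in natural-log space with `logsumexp`; the H3
  complement guarded as described above.
* p-value → z always via `ndtri_exp` on log p (never `isf` on p), so the
  path is uniform and underflow-free.
* Rows with p ≤ 0, p > 1, se ≤ 0 or frequencies outside (0,1) are dropped
  at parse time and counted, never clamped. Duplicate variant keys keep
  the record with the smaller p.
* Colocalization requires ≥ 2 shared variants; below 50 a warning is
  logged. Single-variant "pairs" are refused (PP-H3 would be structurally
  zero and the comparison uninformative).
* Non-positive-definite LD matrices are jittered by 1e-8 on the diagonal,
  with a log line.
* The Mann–Whitney comparison uses exact enumeration when both groups have
  ≤ 8 entries, else the tie-corrected normal approximation.
* When a panel of tables carries an identical variant grid (the synthetic
  benchmarks), pairwise harmonization is skipped and each study's lABF
  vector is computed once — an optimisation with no effect on results,
  checked by the tests against the general path.

## Known limitations

Single causal variant per trait per signal (no SuSiE-style multi-causal
decomposition, no conditional analysis); no genome-build liftover or rsID
resolution; no LD-aware masking; no correction for shared controls between
studies; the ethnicity rule is an operationalisation of a narrative
description and deliberately reports evidence rather than proof of
ancestry specificity.
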