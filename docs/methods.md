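# Methods

## The model and its assumptions

`varburden` implements a collapsing (burden) association test for rare
variants when individual-level genotypes exist only for a small case cohort
and controls are a public reference cohort summarized as per-variant allele
counts. Per unit (gene or pathway) and analysis arm (control set × allele
frequency threshold), the dominant-model statistic is a 2×2 contingency
table:

- **case side** — the number of case individuals carrying at least one
  qualifying allele in the unit (each individual counted once, however many
  qualifying variants they carry);
- **control side** — the sum of control alternate-allele counts over the
  unit's qualifying variants, capped at the control cohort size. Summary
  statistics carry no per-individual genotypes, so the summed allele count
  is the carrier-count proxy; at the qualifying frequencies (≤ 1%) the
  probability that one control carries two qualifying alleles of the same
  unit is second-order small, so the proxy is nearly unbiased and, when it
  errs, errs upward (conservative for case enrichment).

The table is evaluated with a two-sided Fisher's exact test. Burden tests
assume the collapsed variants shift risk in the same direction; a unit
mixing protective and deleterious alleles loses power by design.

Assumptions inherited from the study design: cases and the public controls
are ancestry-matched at the level of the allele-frequency stratum used
(non-Finnish European counts); the case and control cohorts do not overlap;
genotype calls are comparable after the joint coverage gate; and qualifying
variants are independent enough that per-gene dosage sums behave additively
(no linkage-disequilibrium modelling).

## Qualifying variants

A variant is counted iff all of the following hold:

1. it lies on a base retained by the **joint coverage gate**: the fraction
   of samples covered at depth **strictly greater than 10×** is **at least
   0.90 (inclusive)** in cases and in controls. The strict depth inequality
   follows the ">10x" convention; the fraction bound is inclusive ("at
   least 90%").
2. its FILTER status is PASS in the cohort it comes from (case VCF records
   with no FILTER entry are treated as PASS, matching joint-calling output);
3. its allele frequency is **≤** the arm threshold (inclusive comparison),
   taken from the first available source in a configured precedence — the
   control-matched European frequency first, then an aggregator (ALFA
   European) fallback; a variant absent from every source is treated as
   novel (frequency 0);
4. it is predicted deleterious: CADD Phred ≥ 20 **and** a high-impact
   consequence (splice acceptor/donor, stop-gain, frameshift, stop-lost,
   start-lost). The conjunction is the default reading; `combine_rule: or`
   is exposed because the phrase "CADD ≥ 20 and high impact variants" is
   genuinely ambiguous, and an unknown consequence term degrades to
   non-impact with a warning rather than an error.

Only genes with at least one qualifying variant carried by at least one case
are tested; the "two or more variant counts" gene subset is selected on the
case **allele** count (≥ 2), which covers both one homozygous case and two
heterozygous carriers.

Variant keys are normalized reference-free: shared trailing bases are
trimmed, then shared leading bases, each while both alleles keep length > 1
(leading trims advance the position). This gives a unique representation for
every edit reachable from VCF records without requiring a reference FASTA;
it matches left-aligned minimal representation for all non-repetitive
contexts, which is sufficient for matching case keys against control summary
keys produced by the same rule. Missing case genotypes (`./.`) count as
dosage 0 — with tens of cases, silently dropping a carrier is the
conservative direction for case counts.

## The exact test

`fisher_two_sided` enumerates the hypergeometric distribution conditional on
the table margins and sums the point probabilities of all tables whose
probability is at most that of the observed table, with a relative tie
tolerance of 1e-7 (floating-point ties are common in near-symmetric tables).
Point masses are built outward from the distribution's mode using the exact
term ratio pmf(k+1)/pmf(k) = (r₁−k)(c₁−k) / ((k+1)(r₂−c₁+k+1)); every factor
is an exact small-integer product, so each weight carries only a few ulp of
rounding regardless of margin size, and sums use compensated (`fsum`)
summation. The test suite verifies agreement with an independent
rational-arithmetic enumeration oracle to 1e-12 relative, exhaustively for
all tables with total ≤ 60 and on random tables with control margins past
100,000, and cross-checks `scipy.stats.fisher_exact` on random tables.

The odds ratio (a·d)/(b·c) is descriptive output only; zero cells yield
infinity (a·d > 0) or NaN rather than a Haldane-corrected value.

## Pathway aggregation

Gene sets (KEGG, Reactome, Biocarta; GMT format) are restricted to genes
present in the arm's SNP map; sets with empty intersection are dropped.
Pathway counts are the plain sums of member-gene counts — a gene in k
pathways contributes to all k, and a case individual with qualifying
variants in two member genes is counted twice, exactly as the source
workflow defines the pathway count. Because the case-side sum can then
exceed the cohort size, the test table caps it at the number of cases and
flags the result. Reactome low-level pathways are the tested units;
high-level hierarchy labels are carried as pass-through annotation. The
multiplicity count `n_tests` pools all databases within an arm, redundancy
included — correction is deliberately conservative.

## Inflation factor and multiplicity

Because only genes with case carriers are ever tested, the classical
median-based genomic control is unusable (the tested p-value set is
conditioned, not a random sample of nulls). The inflation factor
λ₀.₅–₀.₉₅ is therefore the slope of a least-squares line **through the
origin** fitted to (expected, observed) −log₁₀(p) QQ points whose expected
quantile rank i/(n+1) lies within [0.5, 0.95] — the window drops both the
significant tail and the extreme-null end of the plot. A through-origin fit
is used because λ is a slope-inflation measure; an intercept would absorb
part of the signal. With fewer than 20 p-values the estimate is unstable and
λ falls back to 1 with a warning. Exact analytic anchors: the uniform
quantile grid pᵢ = i/(n+1) gives λ = 1 to machine precision, and squaring
the grid (doubling every observed −log₁₀ p) gives exactly 2; scaling
−log₁₀(p) by any c scales λ by exactly c.

Correction order is λ first, Bonferroni second (the operations commute):
p_λ = min(1, p·max(λ, 1)) — deflation (λ < 1) is never applied, since
shrinking p-values would be anti-conservative — and
p_final = min(1, p_λ · n_tests). Units are called significant at
p_final ≤ 0.05 (boundary inclusive).

**A calibration finding worth knowing.** On fully null synthetic cohorts,
the λ of the *tested-gene* p-values is systematically above 1 (≈ 2–3 under
the default panel density): conditioning on ≥ 1 case carrier removes the
large-p outcomes that a=0 tables would contribute, making the tested null
p-values stochastically small. This selection effect alone produces the
"inflation" that the λ correction then removes — no ancestry mismatch is
needed. The estimator itself is calibrated: on p-values drawn under the
exact null (the generator's uniform p-value scenario) λ stays within
[0.8, 1.2] at n = 2,000. The acceptance checks therefore assert the
rejection rate of the end-to-end pipeline over *all* simulated null genes
(which stays below the nominal level plus Monte-Carlo slack — Fisher is
conservative on sparse tables) and the λ band on exact-null draws, while
the tested-gene λ is reported as the motivating phenomenon rather than
asserted inside a calibration band.

## Synthetic cohorts

The generator emulates the target study's shape: 38 cases vs. 56,885
summary controls by default. Per gene (Poisson mean 10 variants, each gene a
disjoint 10 kb block), true allele frequencies are log-uniform on
(10⁻⁶, 0.01] — a stylized rare-variant site-frequency spectrum spanning the
qualifying range. Case genotypes are Hardy-Weinberg draws Binomial(2, f);
control allele and homozygote counts are independent Hardy-Weinberg draws
(non-overlapping cohorts). Risk genes scale the case-side allele frequency
by an enrichment factor (enrichment 1 reproduces the null draw bit-for-bit),
optionally rescaling the gene's qualifying frequencies to a fixed total so
a spiked signal has exact size. 40% of variants are made high-impact with
CADD ≥ 20 — far above the share in a raw exome, deliberately, so that
moderate panels densely exercise the burden stage; 5% of variants are
withheld from every frequency source (novel), 2% fail quality filters, and
5% of genes carry a contiguous mid-gene control-coverage dropout block to
exercise the interval logic of the joint gate. Ground truth (true
frequencies, enrichments, qualifying and coverage flags) is written beside
the outputs and never read by the pipeline.

What the generator does **not** model: linkage disequilibrium, population
structure (inflation from structure is exercised only through a stylized
mean-shifted p-value scenario for the λ estimator), sequencing reads,
genotyping error, and case/control annotation discordance. Passing tests
demonstrate the statistical machinery is correct under the declared sampling
model — not that real joint-called exomes meet that model.

Problem sizes used by the test suite and acceptance script: 2,000 genes for
null calibration, 200 replicates of 50 genes for the spiked-gene detection
rate, exhaustive Fisher sweep to table total 60 plus 1,000 random large
tables — together they run in about a minute.

## Bundled reference counts

`varburden.datasets` carries the per-gene qualifying-variant counts printed
by a familial lymphoid-cancer exome study (38 European cases vs. gnomAD and
ExAC NFE controls, AF ≤ 1% and ≤ 0.1% arms) for its significantly associated
pathways, plus the pathway memberships. Summing these gene counts through
the pathway machinery reproduces every internally consistent published
per-pathway count pair in all four arms. Two printed cells (the
peroxisome-row case counts of EHHADH and PEX7 at gnomAD ≤ 0.1%) contradict
the same table's tryptophan-metabolism row, the ExAC columns, and the
published pathway total; they are flagged and resolved to the consistent
value by default (`resolve_inconsistent=False` keeps the printed cells).
The study's headline *corrected* p-values are not reproducible from printed
data alone: they depend on per-arm inflation factors published only in
un-transcribed supplementary material and on the full tested-unit counts of
the original exome panel; the correction chain is instead verified on
analytic cases.

## Numerical and design choices

- Coordinates: 1-based inclusive for variant keys (VCF convention); coverage
  intervals 0-based half-open internally, converted at the query boundary.
- Control summary rows absent for a case variant are read as allele count 0:
  public summaries omit unobserved alleles, and the coverage gate has
  already certified the region callable in controls.
- The recessive model counts cases with total gene dosage ≥ 2 (covering
  compound heterozygotes) but uses only summed homozygote counts on the
  control side: a compound-het proxy from pooled allele counts would need
  phase information summaries do not carry.
- Output row order is lexicographic by unit everywhere; reruns on identical
  inputs are byte-identical.
- Where the same normalized key arises from two case VCF records, dosages
  are summed and clipped at 2.

## Known limitations

- The control carrier proxy ignores the (rare) double-carrier control and
  any control-side relatedness.
- Ancestry matching is assumed, not estimated; no principal-component or
  kinship machinery is included.
- The λ window regression has no published closed form to compare against
  beyond the analytic anchors; different window conventions (rank vs. value
  quantiles) coincide only under the uniform expected distribution used
  here.
- Annotation is consumed, never computed: consequence terms, CADD scores and
  allele frequencies must be provided, and transcript selection is upstream.
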