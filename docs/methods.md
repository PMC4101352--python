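# Methods

## The repositioning procedure

The analysis treats drug repositioning as set algebra over three inputs: a
unified drug–target–indication table, per-phenotype candidate gene sets, and
a phenotype synonym configuration.

**Source unification.** Three dialects are parsed into one association
schema (`drug_key, gene, source, species, action, indications, status`):
a DrugBank-style export (one drug–gene pair per row, with brand synonyms, a
species flag, indication and status), a PharmGKB-style export (one drug per
row with a `|`-separated gene list and a free-text description carrying the
disease context) and a TTD-style export (drug–target pairs where the target
may be a UniProt accession). Gene identity is normalized by trimming,
upper-casing and a single alias-map hop; the alias map is a static TSV, so
the step is deterministic and offline, and maps whose canonical side is
itself an alias key are rejected to guarantee idempotence. Accession-shaped
target tokens with no alias entry are quarantined to a rejects report rather
than silently dropped. Drug identity is a case-insensitive match on the
whitespace-collapsed name; brand/generic synonyms unify records. Status text
is collapsed to `approved > clinical > preclinical > discontinued > unknown`
("Discontinued in phase I" is discontinued, "Launched" is approved); when
sources disagree about a drug, the most advanced status wins and the
conflict is logged. Species filtering happens *after* parsing so reports can
state pre-filter counts. Cross-source redundancy is summarized as Venn
region counts for targets and for drugs, with the inclusion–exclusion
identity asserted on the underlying sets before any report is returned.

**Classification.** A phenotype is a code plus a synonym list; an indication
"matches" when any synonym occurs in it on whole-word boundaries,
case-insensitively. The synonym config is data, not code, so every verdict
is auditable. The default config covers seven complex-disease phenotypes
(T2D, T1D, RA, HT, BD, CD, CAD); unqualified "diabetes mellitus"
deliberately matches both diabetes phenotypes, since a therapy registered
for unqualified diabetes counts as existing therapy for either. Synonym
overlap across phenotypes is therefore allowed; a check function surfaces
all shared entries.

A predicted target is **replicated** for a phenotype when one of *its own*
drug associations carries a matching indication, and **novel** otherwise.
The definition is gene-local on purpose: a drug registered for the phenotype
through a different gene does not make this gene replicated — it only
disqualifies that drug from the repositioning list. Repositionable drugs
for a phenotype are all drugs hitting a novel target minus drugs indicated
for the phenotype via any of their associations, so the output can never
contain a drug already treating the disease. Status strata count a target
as approved/clinical if *any* of its drugs is; a target can be in both
strata; unknown-status drugs count in neither.

Ratios are reported raw and rounded to two decimals, half-up (computed in
decimal arithmetic so values like 77/200 = 0.385 round deterministically to
0.39). Cross-phenotype ranks use competition ranking (ties share a rank,
the next rank is skipped).

## Validation benchmarks

**Benchmark 1 (search spaces).** Every gene of a phenotype's locus search
space is labelled: TP = predicted ∧ druggable ∧ known target for the
phenotype; FP = predicted ∧ druggable ∧ not known (the novel predictions,
deliberately scored as errors because this benchmark only measures recovery
of existing knowledge); FN = known target in the space but not predicted;
TN = everything else. TN as the partition remainder (it absorbs
predicted-but-not-druggable genes) is the definition under which the four
cells always sum to the search-space size, and that identity is asserted for
every matrix. A prose alternative — TN as "not predicted and not druggable"
— would leave the cells short of the space size and is not used. Known
targets outside the space are excluded from FN with a log note: no predictor
restricted to the space could recover them. One confusion matrix per search
space yields one (FPR, TPR) point per space; the six spaces act as
prediction-stringency thresholds. The weakly-significant (p ≤ 10⁻³) tier
feeds this benchmark for every phenotype.

**Benchmark 2 (literature).** A gene is literature-supported at threshold
`t` when it is co-cited with the phenotype in ≥ t articles (absent record =
0). Thresholds {1, 5, 10, 15} give four operating points over the same
search-space background as benchmark 1 (the widest space; the negative-set
definition is a reconstruction — see Limitations). Thresholds whose
supported set is empty contribute no point; a curve with no points is
flagged undefined rather than given an arbitrary AUC.

**AUC and significance.** Curves get (0,0) and (1,1) anchors, points are
sorted by (FPR, TPR) ascending — vertical segments contribute no area, so
duplicated FPRs integrate from the higher TPR — and AUC is the trapezoidal
area. Replacing curve fitting with the empirical trapezoid keeps the
statistic assumption-free and exactly testable against a hand-summed oracle.
Significance of AUC > 0.5 is the one-sided Hanley–McNeil normal
approximation of the Mann–Whitney statistic, with SE² =
(A(1−A) + (n₊−1)(Q₁−A²) + (n₋−1)(Q₂−A²)) / (n₊n₋), Q₁ = A/(2−A),
Q₂ = 2A²/(1+A); a degenerate SE of 0 maps to p ∈ {0, 0.5, 1} by the side of
0.5. For benchmark 1, n₊/n₋ are the positives/negatives of the widest
space. For benchmark 2 the supported set varies with the threshold, so a
convention is needed: n₊ is the supported count at the *loosest* threshold
(≥ 1 citation), the natural definition of "literature-supported", with
higher thresholds supplying the operating points. The test suite
cross-checks Hanley–McNeil against scipy's exact Mann–Whitney on separable
samples.

## The synthetic study generator

The generator emulates the *structure* of a GWAS-to-repositioning study so
that every pipeline statistic has a planted expected value:

- **Targets and sources.** `n_targets` genes (default 1,600 of a
  20,000-gene universe — 8% coverage) are apportioned to the seven Venn
  regions of three sources by largest remainder; defaults (60/13/5% unique,
  7/9/2% pairwise, 4% triple) mirror the redundancy pattern of real drug
  databases, where the largest source dominates and only a few percent of
  targets are shared by all three. Each source writes its own dialect.
  Drugs attach with multiplicity 1 + Poisson(mean − 1) (default mean 2.5)
  from a shared pool, statuses from a realistic vocabulary, indications from
  a decoy disease list that is asserted not to match any phenotype synonym.
  A configurable fraction of extra rows (default 0.2 of the DrugBank-style
  source) carries nonhuman species flags, and a fraction of TTD-style rows
  (0.3) uses accession tokens to exercise alias resolution.
- **Phenotype studies.** Per phenotype: exactly
  `round(targetable_fraction · n_candidates)` candidates are drawn from the
  target union and the rest from non-targets, so TT and TI are exact by
  construction. A `known_indication_rate` fraction of the targetable
  candidates receives a dedicated planted drug whose indication is the
  phenotype's first synonym (unique to that phenotype), planted into a
  source that already carries the gene so Venn counts stay untouched;
  `n_known_missed` known targets outside the candidate set are placed into
  every search space to create false negatives. Tiers are nested prefixes
  of the prediction ranking (HS ⊂ MHS ⊂ MWS ⊂ WS at fractions
  0.1/0.3/0.6/1.0); the six search spaces are nested supersets with size
  multipliers 2–14 and per-space prediction fractions 0.35–1.0.
- **Citations.** Counts are negative-binomial (mean 2, dispersion 2 —
  overdispersed, variance 4) with the mean multiplied by the enrichment
  ratio (default 5) on true disease genes. True genes comprise the planted
  knowns, 40% of candidates and 2% of the background, with 80% of the
  candidate true genes drawn from the *targetable* subset. That coupling
  models the knowledge bias of real data: well-characterized disease genes
  are simultaneously better cited and more likely to be druggable, which is
  also the published explanation for candidate lists being more targetable
  than the genome at large.
- **Determinism.** All draws flow from one `numpy` generator; a fixed seed
  reproduces every output file byte-identically (content hashes replace
  Python's randomized `hash` everywhere an identifier is derived from a
  name).

The default seven-phenotype demo mirrors the published study geometry —
candidate counts (291, 212, 378, 219, 358, 264, 200), targetable counts
(84, 59, 135, 78, 97, 102, 77), replicated counts (7, 1, 0, 5, 2, 4, 6) and
missed-known counts (9, 6, 0, 15, 9, 8, 9) — so a demo run prints a
correctly shaped report table. Note that its TI column is the mathematically
exact rounding of TT/candidates; three of the corresponding published values
(RA 0.38, HT 0.35, BD 0.27) differ from that by one unit in the last digit
and are not reproducible from their own printed numerator and denominator
under any single rounding rule.

What the generator does **not** emulate: LD structure, SNP positions or
genotypes (it starts at the candidate/search-space level); real synonym
ambiguity in indication text (planted indications match exactly one
phenotype, so replicated counts are exact — real text matching is
noisier); correlated drug multiplicities or target-class structure; and
citation counts correlated across phenotypes. Passing recovery tests
therefore demonstrates the pipeline's bookkeeping and statistics are
correct, not that the matching heuristics would be error-free on raw
database exports.

## Experiment sizes

The calibration experiments run at sizes chosen to give stable Monte-Carlo
estimates in seconds-to-minutes on one CPU: the truth-recovery sweep runs
the full default demo (20,000 genes, 7 phenotypes) over 50 seeds; the
permutation null uses 500 label permutations over a 400-gene space with 100
predictions; the significance-direction experiment uses 200 replicates of a
scaled-down single-phenotype study (4,000 genes, 800 targets, 200
candidates, targetable fraction 0.3, known rate 0.25, 5 missed knowns,
enrichment ratio 5, and known targets concentrated in the top half of the
prediction ranking — the "planted enrichment" condition under which a sound
benchmark should detect signal).

## Known limitations

- Name-based drug identity cannot merge records whose sources use different
  names for the same compound; no structure identifiers are handled.
- The replicated/novel verdict inherits any incompleteness of the synonym
  config; an indication phrased outside the configured synonyms yields a
  false "novel".
- The citation benchmark's negative set (same search-space background as
  benchmark 1) is a reconstruction; other choices (e.g. all druggable
  genes) would shift FPR scales.
- Hanley–McNeil is an asymptotic approximation; with very few positives
  (e.g. a phenotype with one known target) its p-values are conservative to
  unstable, which is why degenerate curves are flagged rather than tested.
- Per-phenotype replicated counts use the gene-local definition; a
  cross-phenotype unique known-target count is also reported, since rows
  can repeat a gene under two phenotypes and the two conventions differ.
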