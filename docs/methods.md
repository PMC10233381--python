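# Methods

This note documents the statistical models, parameter choices and numerical
conventions behind `rbpcoreg`, and what the synthetic benchmarks do and do
not establish about real data.

## Interactor calling from IP-MS LFQ

**Model.** The input is a protein × sample matrix of label-free
quantification intensities with unique-peptide counts, from bait pull-downs
and IgG negative controls (default design: 6 biological replicates per
arm). Missingness is informative in this kind of data, so the reader keeps
the MaxQuant-style distinction: an empty cell is *not detected*, a literal
`0` is *detected at zero* (kept, with a warning).

**Gates.** A protein is called when it (1) carries ≥ `min_unique_peptides`
(2) unique peptides with a present intensity in ≥ `min_bait_detections`
(5) of `n_bait` (6) bait runs; (2) has fold change
`mean(bait detected) / mean(control detected)` above `fc_threshold` (1.5);
and (3) reaches `q < alpha` (0.05) in the permutation ANOVA. The fold
change is computed on raw (not log) intensities, matching how LFQ ratios
are conventionally quoted. A protein with *no* detected control intensity
receives an infinite fold change and passes gate 2: absence from IgG is the
strongest enrichment evidence, and we deliberately do not impute
Perseus-style missing values (any imputation scheme would be an invention
here). Every protein receives a call record with explicit tags for each
failed gate, so filter funnels are exactly reportable.

**Permutation ANOVA and FDR.** The F statistic is one-way ANOVA on detected
intensities, computed in-house so degenerate inputs are well-defined: zero
within-group variance with a between-group difference gives F = +∞ (it must
out-rank every finite permuted F), identical data give F = 0. The p-value
permutes group labels within the protein; when the number of distinct label
assignments is at most `n_permutations` the null is enumerated exhaustively
and p is the exact tail fraction (the identity assignment is part of the
enumeration, so p > 0), otherwise `n_permutations` random shuffles are
drawn and the add-one estimator is used. The FDR is the SAM-style
permutation FDR: for a protein with observed F_i,
`q_i = E_perm[#{j : F_j^perm ≥ F_i}] / #{j : F_j ≥ F_i}`, capped at 1 and
monotonized so a larger F never has a larger q (cumulative minimum walking
up from the smallest F). Proteins with a group entirely missing, or with
fewer than two observations in a group, are skipped with a reason tag
rather than raising.

Under a global-null simulation (1,000 proteins, no effect) the permutation
p-values are uniform and the q < 0.05 gate calls essentially nothing; both
are asserted by tests rather than assumed.

## Ranked-list enrichment

**Statistic.** The weighted Kolmogorov–Smirnov-style running sum of gene
set enrichment analysis: along the ranked list, members contribute
`|s_i|^p / N_R` and non-members `−1/(N − N_H)`. ES is the signed extremum;
rank-at-max is its position as a percentile (one decimal, lower = stronger
top-concentration); the leading edge contains the members at or before the
extremum (strictly after it, for negative ES). The default weight is
`p = 1` (the standard "weighted" mode); `p = 0` gives the classic
Kolmogorov–Smirnov form used in the hand-checkable tests. If every member
scores zero under `p > 0`, hit increments fall back to equal weights.

**Tie-break.** A symmetric excursion (e.g. a single hit preceded by a long
decline) can make the minimum and maximum of the running sum exactly equal
in magnitude; summation order then decides the sign at machine precision.
The extremum is therefore defined as the *earliest* position whose
magnitude is within 1e−9 of the maximum — deterministic and stable across
algebraically equivalent implementations.

**Null and significance.** The null permutes gene-set membership: random
same-size subsets of the list (this, not phenotype permutation, is what a
membership-assignment null means). The null is enumerated exhaustively when
`C(N, N_H) ≤ n_permutations`. Two nominal-p estimators are exposed:

* `tail="same-sign"` (default): the tail fraction among null scores of the
  observed sign — the estimator of the original GSEA method. It is
  uniformly distributed under the null, which the calibration tests verify
  by KS test; the headline gates (p < 0.01, FDR q < 0.25) are meant for
  this estimator.
* `tail="pooled"`: the sign-matched tail count over *all* null assignments.
  It is the more intuitive quantity for tiny exhaustive nulls (the 4-gene
  singleton example gives exactly 1/4) but is bounded by the sign mass
  (≈ 0.5) and therefore not uniform under the null; it is kept for exact
  small-null reasoning, not for calibrated inference.

NES divides ES by the mean magnitude of same-sign null scores. With several
query sets the FDR q follows the NES-pool procedure (pooled null NES tail
over observed NES tail, capped and monotonized within sign); with a single
set it degenerates to the same-sign tail of the normalized null.

**Percentile bins.** `bin_profile` cuts the list into `n_bins` (10)
contiguous rank intervals of size ⌊N/n_bins⌋, the first `N mod n_bins` bins
one element larger, and reports per-bin member counts and fractions. The
per-bin ES re-scores the query against the bin's sub-list re-ranked on its
own (`mode="sublist"`); the alternative reading — the bin-restricted query
subset against the full list — is `mode="subset"`. Neither reading is
claimed to reproduce any published per-bin value; the published phrase
"repeated the enrichment for each bin" is ambiguous, so both are exposed
and the sub-list form is the default. A bin with no members, or consisting
entirely of members, has no defined ES and is flagged instead.

## miRNA arm

**Normalization.** Plain counts-per-million against per-sample library
sizes (column sums by default). No between-sample scaling (TMM etc.) is
applied; with strong asymmetric dysregulation CPM slightly compresses fold
changes, which the recovery benchmarks therefore include.

**Differential expression.** Per sex, KO vs WT on log2(CPM + 1)
(pseudocount 1 avoids log 0). The default test is an empirical-Bayes
moderated t: one linear model over the four genotype × sex cells, residual
variance pooled across cells (df = Σ(n_cell − 1), 7 in the default
3/3/3/2 design) and shrunk across miRNAs toward a scaled
inverse-chi-square prior fitted by moments of log s² (the limma procedure;
the implementation is cross-checked against limma's p-values in the test
suite). At 2–3 replicates per cell a per-gene t-test is underpowered for
2-fold effects at typical small-RNA-seq dispersion, which is exactly the
regime this design sits in; variance moderation is the field-standard
remedy, not a tuning knob. A per-miRNA two-sided Welch t remains available
(`method="welch"`), with an exact mean-difference permutation fallback when
both groups are constant.

**Divergence and selection.** The per-miRNA *divergent* flag requires
strictly opposite fold-change signs between the sexes plus significance.
The significance gate is configurable: the default tests the
sex-by-genotype interaction contrast `(KO−WT)_M − (KO−WT)_F` — the direct
statistical reading of "diverged between male and female" — while
`divergence="per-sex"` requires p < α in at least one sex. *Dysregulated*
selection additionally requires > `pct_threshold` (25) % change of the
linear CPM ratio (100·|fc − 1|) in either direction in at least one sex.

**Co-binding.** The co-binding count of a target is the number of
*distinct* selected miRNAs with an edge to it; multiple prediction sources
for the same (miRNA, target) pair collapse. Prioritization tiers are plain
thresholds (≥ 2, ≥ 4, ≥ 8 in the emulated study). Sex-concordance compares
per-sex change directions of each target against a reference pattern under
a `same` or `opposite` relation; targets missing a sex are unevaluable, not
discordant.

**Read-length filter.** Unique small-RNA reads of 18–26 nt inclusive are
retained.

## Hairpin classifier

Candidates arrive as sequence + dot-bracket + free energy + mature-arm
coordinates (0-based half-open); no folding is performed here. Pairing is
derived by stack matching; only single stem-loops are classified, branched
structures raise a structural error (a pair-free structure is classified —
it simply fails the pair-count criteria). Operational definitions, fixed
because the originating vendor pipeline publishes none: the *terminal loop*
is the unpaired run enclosed by the innermost pair; the *stem* is
everything between the outermost and innermost pair on both strands, loop
excluded (flanking dangles belong to neither); a *bulge* is a maximal
unpaired run inside the stem, its size counting nucleotides on both
strands; a bulge is *biased* when confined to exactly one strand; *errors*
in the mature region are its unpaired positions; "percent of mature region
in stem" counts mature positions inside the stem (paired or in stem
bulges). The eleven thresholds (≤ 12 nt per stem bulge; ≥ 16 stem pairs;
≤ −15 kcal/mol; ≥ 50 nt hairpin; ≤ 20 nt loop; ≤ 8 nt per mature bulge;
≤ 4 nt per biased mature bulge; ≤ 2 biased mature bulges; ≤ 7 mature
errors; ≥ 12 mature pairs; ≥ 80 % mature in stem) are all inclusive, and
every verdict reports the observed value alongside its threshold.

The fixture generator builds hairpins arm-by-arm from explicit pairing
plans — one all-pass plan and one plan per single-criterion violation —
renders them to dot-bracket, assigns complementary bases with a seeded RNG,
and verifies its own intent against the classifier before returning, so
generator and classifier cannot drift apart silently. Free energy is an
assigned attribute, not computed; several violation plans need compensating
structure elsewhere (e.g. a 15-pair stem padded with legal bulges to stay
over the 50-nt floor), which is why plans are explicit rather than
procedurally perturbed.

## Quantification

The co-IP western fold change is a ratio of ratios per specimen,
`(IP_x ÷ Input_x ÷ loading) ÷ (IP_ref ÷ Input_ref ÷ loading)`, subject over
control. The printed linearization of this formula is
parenthesization-ambiguous; we evaluate the division chain
left-associatively, under which the loading control cancels algebraically
within each specimen's ratio. That consequence is documented and tested
(doubling the loading band changes nothing) rather than hidden behind a
different bracketing we would have had to invent. Comparative-CT qPCR
averages replicate CT values per condition first, then
`ΔCt = Ct_target − Ct_housekeeping`, `ΔΔCt = ΔCt_test − ΔCt_calibrator`,
expression `2^(−ΔΔCt)` with amplification efficiency fixed at 2 (no
Pfaffl-style efficiency calibration). CT values outside [0, 45] warn.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (config, seed); the single seed fans
out to fixed per-generator substreams, so adding a generator never perturbs
another, and every truth table is sufficient to score recovery directly.

* **IP-MS LFQ** — per-protein base intensities log-normal
  (μ = ln 1e7, σ = 1, spanning a typical LFQ dynamic range; the magnitude
  is arbitrary), multiplicative replicate noise at CV 0.2, planted
  interactors multiplied by 3 in the bait arm, IgG intensities masked
  missing at rate 0.3, 6 bait vs 6 control. Not emulated: intensity-
  dependent missingness, peptide-level quantification, shared peptides,
  batch effects.
* **Ranked overlap** — strictly decreasing exponential scores;
  ⌈fraction·|S|⌉ members planted uniformly in the top percentile (default
  54 % in the top decile, mirroring the emulated study's headline overlap),
  the rest uniform below it. The score *values* are arbitrary; only the
  ranking carries information, which is also all the statistic uses at
  p = 0.
* **miRNA counts** — negative binomial with dispersion 0.1 (small-n
  RNA-seq-like overdispersion; no noise figure is published for the
  emulated study, so this is a stated stand-in), per-miRNA abundances
  log-normal around 200 CPM, library sizes within 2×, 3/3 KO/WT males and
  3/2 females; planted miRNAs change 2-fold up in males and 2-fold down in
  females. Not emulated: isomiRs, mapping artefacts, sequence content.
* **Edges** — each planted target gets exactly its multiplicity of distinct
  selected-pool miRNAs; background targets get Poisson(1) edges to
  arbitrary miRNAs.
* **Hairpins** — see above; fixtures are structural, not thermodynamic.

Passing the recovery benchmarks therefore shows the *procedures* are
correctly implemented and have the expected operating characteristics under
the stated noise models — it does not certify performance on real
proteomics or sequencing data, whose noise is richer than these models.

## Problem sizes and runtime

The default test and acceptance runs use reduced but structure-preserving
sizes — 50–1,000 proteins, 100–1,000-gene lists, 200–600 miRNAs, 20-seed
replication for recovery rates, 300–1,000 permutations — chosen so the
whole suite completes in well under a minute on one CPU while every
statistic still operates in its intended regime (exhaustive nulls where the
design allows, sampled otherwise).

## Known limitations

* Published enrichment values from the original HITS-CLIP comparisons
  (e.g. ES 0.93 against specific external datasets) depend on those
  datasets' ranking metrics and list lengths and are not reproducible from
  synthetic data; the package reproduces the *procedure* and its
  calibration, not those numbers.
* The per-bin ES semantics and the "biased error" hairpin glosses encode
  one explicit reading of underspecified upstream definitions; both are
  isolated behind options/hooks so alternative readings are one predicate
  away.
* The pooled-tail nominal p is intentionally non-calibrated (see above);
  use the default same-sign estimator for inference.
* `fold_change = +∞` for proteins absent from IgG makes gate ordering
  matter when summarizing funnels: such proteins can still fail the
  detection or significance gates.
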