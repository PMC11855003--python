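# Methods

## The model

The package analyses the second hit of tumor suppressor gene inactivation in
paired tumor/normal cohorts by combining three independent calls per
gene × sample and joining them into classes A–F.

### Regional methylation: the Methylation Z-Score

Per-CpG methylation ratios *m*<sub>*i*</sub> ∈ [0, 1] (methylated reads /
total reads at CpG *i*, as emitted by a bisulfite methylation caller) are
summed over a *gate* — a genomic window chosen where tumors and normals
differ. The sum runs over a CpG set common to every sample in the cohort
(intersection policy by default), so all grand sums are comparable. Normal
samples define the reference distribution of the sum; a tumor's score is the
z-score of its sum against that reference, using the sample (n−1) standard
deviation. Assumptions worth stating:

- The normal grand sums are treated as an adequate reference distribution;
  no distributional form is assumed beyond mean and sd. With 32 normals the
  z-score is an estimate, not an exact quantile.
- Normals are scored against the cohort including themselves (no
  leave-one-out). Their self-scores therefore standardize to mean 0, sample
  sd 1 exactly — a property the tests assert — but each normal's own sum
  slightly shrinks its own z-score; with n = 32 the effect is ~3%.
- Hypermethylation is one-sided: negative scores (hypomethylation) are never
  banded.

Bands are half-open: H = [2, 5), VH = [5, 10), EH = [10, ∞). The verbal
definition ("2 to 5 … 5 to 10 … greater than 10") overlaps at the joins;
half-open intervals make the map total and deterministic, with the boundary
values 5 and 10 assigned to the higher band. A gene is called
hypermethylated at band H or above (MZS ≥ 2), matching how the band tables
annotate entries only from H upward.

### Gate search

`optimize_gate` scans every contiguous window of *min_cpg* to *max_cpg*
common CpG sites inside a search region and returns the window maximizing
either the mean tumor MZS (default) or the maximum tumor MZS. Prefix sums
make each window a vectorized difference, and a brute-force double loop is
kept as a test oracle — the scan must match it exactly on every instance up
to 200 CpGs. Ties go to the smaller window, then the leftmost start; windows
whose normal sums have sd below the floor are skipped.

Two caveats are inherent to the statistic, not the implementation:

- **Selection bias.** The gate is tuned on the same cohort it scores, so
  optimized MZS values are biased upward. Scores at a pre-registered gate do
  not have this problem.
- **Localization precision is cohort-limited.** The window argmax depends on
  the normal-cohort sd estimated per window. With 32 normals the relative
  fluctuation of that estimate across overlapping windows (~1/√(2·31) ≈ 13%)
  exceeds the share of the objective contributed by a single boundary CpG of
  a ~20-CpG event (~2.5%), so the selected window jitters by a few CpGs
  around the true event regardless of read depth or effect size. In the
  simulation suite, median Jaccard overlap with a planted 20-CpG window is
  ~0.85 at 32 normals and reaches 1.0 at 128 normals. Interpret optimized
  gate *boundaries* at single-CpG resolution with caution when the normal
  cohort is small.

### LOH from variant allele frequencies

In an impure tumor sample, a clonal heterozygous variant sits near
VAF = purity/2 and a clonal hemizygous variant (after loss of the wild-type
allele) near the purity. LOH is therefore called when a single VAF reaches
0.5, or when the best pair of variants in the same gene presumed *trans*
sums to 0.5. Choices:

- **Inclusive threshold (≥ 0.5).** The cohort tables mark LOH at VAF exactly
  0.50; the inclusive rule reproduces every printed call and flips none of
  the negative calls (no negative entry sits at exactly 0.50).
- **Phase.** Unphased variants are presumed *trans*; only pairs in which
  both members carry an explicit *cis* annotation are excluded from
  summation. With more than two variants only the best pair is summed,
  never triples — the rule as stated concerns two different variants.
- LOH is derived solely from variants; "LOH without a variant" is
  unrepresentable and raises rather than being coerced.
- VAFs are not deconvolved for purity or subclonality; the rule is
  deliberately the simple screen used in practice.

### Variant consequence and oncogenicity

Consequences are parsed from HGVS-like change strings when no explicit
column is given: trailing `*` → nonsense, `fs` → frameshift, intronic
offsets (`c.835-8A>G`, `1731+2T>C`) → splice, `c.-N`/`c.*N` → UTR,
protein-level `del`/`dup`/`ins` without `fs` → in-frame indel, `X123Y` →
missense, trailing `=` → synonymous. A variant is *null* (complete
loss-of-function) when it is nonsense, frameshift, or a splice change at a
canonical ±1/2 site or annotated as a known splicing variant. Deep-intronic
candidates that merely pass the splice score filter (max of the four
donor/acceptor gain/loss scores > 0.5 and population AF < 1e-4) are
reported but not auto-null.

Oncogenicity uses the five evidence-point bands (benign ≤ −7; likely benign
−6…−1; VUS 0…5; likely oncogenic 6…9; oncogenic ≥ 10). Because a null
variant in a tumor suppressor gene alone scores 8 points, null variants
short-circuit to likely oncogenic unless an explicit category is attached;
unannotated non-null variants default to VUS. The full evidence-code
aggregation engine is out of scope — only the band map and the shortcut.

### Classes A–F and cohort summary

Per gene × sample, the flag triple (variant, LOH, hypermethylation) maps
bijectively onto A–F (LOH without variant being invalid). Gene-specific
gating: *APC* is hypermethylated if either promoter gate (exon 1A or 1B)
bands ≥ H; *MSH2* is judged on the EPCAM–MSH2 intervening 5′UTR gate only —
its intron 1–2 gate is reported but not class-determining, the unique rule
that reconciles the per-sample band table with the published class matrix.
*PMS2* is excluded from classification (not captured for methylation) and
counts only toward mismatch-repair variant concordance.

The packaged fixture is the published 32-patient cohort transcribed into
TSVs (clinical/MSI labels; 41 *APC*, 28 *TP53*, 8 *SMAD4* and 14
MMR-gene variant records with VAFs, phase and annotation tags; per-gate MZS
bands), with sha256 integrity checks at load. Because the raw per-CpG
tracks were never published, the fixture carries the band labels as
printed; the methylation arithmetic itself is exercised on simulated tracks.
The published class-row totals for B and C (28 and 30) disagree with their
own cells (both sum to 29); the package reproduces the cells and does not
assert those two printed totals.

## The simulator

`synthdata` emulates the structure of the real data: an 80-CpG hypomethylated
promoter gap (latent ratios Beta(2, 20)) inside an otherwise methylated
region (Beta(20, 2)), a focal hypermethylation event (+0.5 per CpG over 20
CpGs, clipped at 1) planted in 25% of tumors, and binomial sampling at
Poisson(50) read depth — the standard bisulfite sampling model, which keeps
ratios in [0, 1] with depth-dependent variance. Cohort sizes default to 32
normals and 32 tumors, matching the study design the fixture comes from.
Variant tables draw per-gene event probabilities shaped after the real
cohort (e.g. *APC* variants in ~75% of tumors, mostly null; *MLH1*
hypermethylation in ~31%), at tumor purity 0.7 with Gaussian VAF jitter
(sd 0.03, clipped to [0.01, 0.99]); LOH cases emit one hemizygous variant at
~purity or a trans pair summing to ~purity. All randomness flows from one
seed; outputs are byte-identical across runs.

What the simulator does **not** emulate: position-specific methylation
propensities shared across samples (each sample draws its own latent track),
bisulfite conversion failure, copy-number change, subclonal variant
populations, and correlated methylation between neighboring CpGs. Passing
recovery tests therefore show the estimators behave correctly under the
stated sampling model — not that real cohorts meet that model.

## Numerical choices

- Sample (n−1) standard deviation throughout; sd floor 1e-9 with a hard
  `DegenerateCohortError` rather than capping — a zero-variance normal
  cohort means the gate is uninformative, and silently huge z-scores would
  corrupt downstream class calls.
- bedGraph values auto-scale: any value > 1 anywhere in a file marks the
  whole file as percent-scaled (0–100 → 0–1), overridable per call. All
  coordinates are 0-based half-open end to end.
- Duplicate bedGraph positions with identical values are deduplicated;
  conflicting values are an error. Symmetric CpG strand merging is off by
  default (`MethylationProfile` takes forward-strand C coordinates as
  given).
- Gate-search ties: smaller window, then leftmost start; exact ties occur
  with dyadic inputs and are covered by a test.
- Empty common CpG set, fewer than two normals, and coverage gaps at
  required positions are all hard errors naming the offending site/sample.

## Problem sizes in the test suite

The simulation-backed suites use 100-replicate runs of the default 64-sample,
200-CpG cohort for window-recovery and band-sensitivity properties, 6
simulated variant tables (1152 gene × samples) for LOH recovery, 50
replicates for the analytic-expectation check, and exhaustive-oracle
comparisons up to 200 CpGs — sizes chosen so the full suite runs in well
under a minute on one CPU while keeping Monte-Carlo tolerances meaningful.

## Known limitations

- The MZS is a regional grand-sum statistic: no per-CpG differential
  testing, no beta-binomial dispersion modeling, no smoothing.
- Gate optimization on the scoring cohort inflates scores (see above); the
  package reports it as the exploratory tool it is.
- LOH calls ignore tumor purity variation between samples; a low-purity
  tumor with true LOH can sit below the 0.5 screen.
- The A–F classes treat hypermethylation as binary (band ≥ H); graded
  effects on expression are out of scope, and no mRNA-level validation is
  implied.
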