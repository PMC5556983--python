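# Methods

## The analysis model

The pipeline analyzes a dense, normalized FPKM matrix over twelve named
samples: one pre-starvation reference (`N_0`) and eleven treatment time
points grouped into three stages of nitrogen availability — e−N
(`N_2, N_4, N_8`), l−N (`N_24, N_48, N_56, N_96`) and r+N
(`R_2, R_4, R_8, R_14`). There are no replicate columns: each sample is
one (pooled) library, so no per-gene significance testing is done;
responsiveness is a pure fold-change criterion.

**Fold changes and the reliability floor.** log2-FC(t) =
log2(FPKM_t / FPKM_N0) is computed only when both values are ≥ 1.0
FPKM; below that floor abundance estimates are unreliable and the cell
is masked NA. The NA state is carried as an explicit boolean mask, never
a sentinel value, so each downstream consumer states its own NA policy.
A gene is responsive at a time point when |log2-FC| > 1 (strict); the
class is `up`, `down`, `none` or `NA`. For display only, fold changes
are clamped to [−4, 4] and values beyond flagged "highly regulated";
clamping never changes the responsiveness class because the cap exceeds
the threshold.

**Stage classes.** A_stage is the arithmetic mean FPKM over a stage's
time points and R_stage = A_stage / FPKM(N_0); |log2 R_stage| > 1
classifies the gene per stage, yielding six gene sets. The FPKM floor
is stated only for single-point fold changes in the original design; we
apply it analogously to the pair (FPKM(N_0), A_stage) for consistency,
with a switch (`apply_floor=False`) to disable. Genes masked NA in a
stage are excluded from that stage's sets rather than treated as
non-responsive.

**Housekeeping stability.** A profile is "stable" when |log2-FC| > 1 at
no more than one starvation time point. Seven −N samples exist
(N_2..N_96); the stability window is exactly those seven points, and NA
points never count as exceedances.

**Fragment pairs.** On a draft assembly split into thousands of
scaffolds, one true gene can be annotated as two gene models at two
scaffold margins; both halves are transcribed identically, so their
profiles are near-perfectly correlated. Detection requires, jointly:
Pearson r > 0.9 between the log2(FPKM+1)-transformed profiles over all
twelve time points; both gene models within 500 nt (inclusive) of a
scaffold margin, measured as min(start − 1, scaffold_length − end); and
a shared domain id hit with complementary truncations (one C-terminally,
one N-terminally truncated). Correlation is computed on log2(FPKM+1)
rather than on log2-FC to avoid NA holes from the floor; a
pairwise-complete FC-based variant was considered and rejected because
the candidate filter already conditions on margins and domains, and the
full-profile transform keeps the correlation estimate well defined for
every candidate. Matching is greedy by descending correlation with
lexicographic tie-breaks, so no locus joins two pairs and detection is
independent of input row order. Of each pair only the 5′ member is
retained — the one with the start codon, since it encodes the putative
targeting peptide; if neither or both carry one, the member whose shared
domain is N-terminally intact (a C-truncated hit) wins, then the
lexicographically smaller id.

**Sample clustering.** Each sample column is normalized to a probability
distribution over loci, and pairwise Jensen–Shannon distances (square
root of the JS divergence, base-2 logs so the maximum is exactly 1) are
clustered hierarchically. Complete linkage is used as the package-wide
convention — the linkage used for profile clustering — not as a claim
about the original study, which delegated this plot to a package's
defaults.

**Gene-family clustering.** Candidates are selected when the defline
contains "lipase", or both "hydrolase" and "beta" (case-insensitive),
or the GO annotation includes lipase activity (GO:0016298), or both
hydrolase activity (GO:0016787) and lipid catabolic process
(GO:0016042). Their log2-FC profiles are clustered with Euclidean
distance and complete linkage (scipy's deterministic implementation;
its ordering convention resolves equal-distance merges). NA cells are
imputed as 0 for distance computation — an unreliable point is treated
as "not responsive" — while the mask is preserved for display; a
pairwise-complete alternative can be obtained by dropping masked
columns before calling the clusterer. The cut is chosen by the average
silhouette width over k = 3..7: s(i) = (b−a)/max(a,b) with singleton
clusters contributing 0 and the 0/0 case defined as 0; ties go to the
smallest k. An explicit `k` override supports fixing the cut (e.g. the
four-cluster cut of the motivating analysis).

**GO enrichment.** Direct annotations are propagated along `is_a` edges
(true-path rule) and each biological-process term with at least one
annotation in the query set is tested with the one-sided hypergeometric
upper tail P(X ≥ k). The universe defaults to all loci with at least
one propagated BP annotation (configurable). No multiple-testing
correction is applied and terms are flagged at p < 10⁻⁴, as in the
original design. Note this is the *classic* Fisher test on propagated
annotations; decorrelation heuristics (weight01/elim) are out of scope,
so p-values on real data will differ from tools that apply them — the
planted-truth tests quantify recovery for this classic variant only.

**Pathway-candidate validation.** Per enzymatic step, forward-hit
candidates survive only if the best reverse hit (rank 1 by ascending
e-value, ties by descending bit-score, then subject id — tie handling
is our own convention) maps to the step's template enzymes in *both*
model organisms (an "either" mode is available, since the original
wording is ambiguous), and if their domain hits include a required
domain (truncated hits count). Fragment pairs inside the surviving list
are collapsed with the detector restricted to that list. Provenance is
total: every candidate is exactly one of retained / failed-reciprocal /
failed-domain / collapsed-into-pair.

**Abundance categories and pictograms.** Category boundaries are the
50th/75th/90th/99th percentiles of the `N_0` FPKM distribution
(linear-interpolation quantiles, the numpy default; the original design
names no method). A value equal to a cut point goes to the *higher*
category, reconciling the overlapping printed ranges of the original
figure legends. Boundaries are computed over all loci (a switch
restricts to non-fragmented loci). The SVG pictogram encodes: the
localization letter (C/M/S/O/NA); the category Roman numeral, bold when
the gene is not fragmented; three stage-framed boxes (orange e−N, brown
l−N, green r+N) of per-time-point bars colored by capped log2-FC —
white for |FC| ≤ 1, linearly interpolated to saturated red/blue at the
±4 cap, and an "NA" tag for masked cells. Exact hex values are
configuration, not science.

## The synthetic-data generator

The generator emulates the *structure* of such a study, not its
sequencing physics. Latent log2 abundances are: a per-locus lognormal
baseline (log2 FPKM ~ N(3.5, 3.3), spanning over four orders of
magnitude, matching the reported dynamic range of deep mRNA-seq);
plus a stage-sign effect pattern of magnitude `effect_log2fc`
(default 2.0) for planted responsive genes, fragment-pair members and
cluster members; plus additive Gaussian noise (default sd 0.1 in log2
units, i.e. multiplicative on FPKM). Defaults: 500 loci on 40 scaffolds
of 1 Mb, 20 fragment pairs (8 % of loci), 25 up + 25 down per stage,
40 housekeeping genes (half with a planted transient +1.5 excursion at
`R_2`, mimicking observed transient resupply responses), and four
profile clusters of sizes 12/15/18/10 inside a lipase-annotated family.
Planted loci have their baseline floored at effect + 1 log2 units so a
down-regulated value never falls below the FPKM floor — planted classes
are recoverable by construction in the zero-noise limit. Pair members
share one latent profile (identical baseline and pattern), sit within
500 nt of scaffold margins, and carry complementary C-/N-truncated hits
to one pair-specific domain; margin decoys with same-side truncations
or no domains exercise the detector's negative paths. One designated GO
term per up-set is planted on 80 % of that set's responsive members
against a 5 % background rate inside a ~50-term synthetic `is_a` DAG
(one BP root, seven mid-level terms, forty leaves, two diamonds, plus a
molecular-function branch to exercise the BP restriction). Hit tables
plant, per step, valid reciprocal candidates plus a configurable
fraction (`frac_reciprocal_fail`, default 0.25) of candidates whose
best reverse hit is a different enzyme; one step's candidates are a
fragment pair, so the full filter chain including the collapse is
exercised end to end.

What the generator does **not** emulate: read-level noise, gene-length
and GC bias, isoforms, count–dispersion relationships, correlated
co-expression beyond the planted patterns, or realistic GO term
frequencies. Passing recovery tests therefore demonstrates algorithmic
correctness on the stated structure — thresholds behaving as specified,
planted signal recovered at the planted effect size — not performance
on real libraries.

## Numerical and design choices

- Seeding: a single `numpy.random.default_rng(seed)` drives the whole
  generation; identical config + seed gives byte-identical output files
  (floats are written as `%.17g` and read back with round-trip parsing).
- Problem sizes: tests and the acceptance script run at the generator's
  default study size (500 loci) or smaller; the whole suite completes in
  well under a minute on one CPU.
- Degenerate inputs: constant profiles make Pearson correlation
  undefined — such candidates are skipped (and an error is raised when
  correlation is requested directly); all-identical points yield
  silhouette 0 by the 0/0 → 0 convention; a degenerate (constant)
  abundance distribution triggers a warning and puts every locus in the
  top category; tree cuts that cannot produce k distinct clusters (tied
  merge heights) are skipped during k selection.
- The CLI (`fragtx`) is a thin layer over the library; every subcommand
  reads and writes the same text formats the library exposes, and
  `run-all` writes a manifest of SHA-256 hashes for all artifacts.

## Known limitations

- The enrichment test is the classic Fisher variant; decorrelated
  p-values (weight01) are intentionally not reproduced.
- Fragment detection considers pairs only; a gene split into three or
  more fragments would be merged partially (greedy 1-to-1 matching).
- Stage classes at real-data noise levels inherit all caveats of
  unreplicated fold-change thresholds; the package deliberately offers
  no significance testing.
- Venn counts and enriched-term lists from the original deep-sequencing
  dataset are not reproducible from synthetic data and are not targets
  of the test suite.
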