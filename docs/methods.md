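# Methods

This note documents the models, parameter choices, and limitations of
sdmrkit: what each stage assumes, why the defaults are what they are,
and what passing the test suite does and does not establish about real
data.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) in every data
structure; 1-based values appear only in rendered text. Peaks and
s-DMRs are unstranded ('.') because enrichment-based methylation signal
carries no strand information. Every interval intersection in the
pipeline uses the ≥ 1 bp overlap rule unless a fractional threshold is
stated (island/shore counting uses ≥ 0.5 of the *query region's*
length, inclusive — the query-side `-f` semantics of the standard
intersection tools).

## Peak calling

**Poisson sliding-window caller.** Fragment midpoints (equivalent to
shifting reads by half a fragment) are binned at 50 bp; windows of one
fragment length (default 200 bp, i.e. 4 bins) step one bin at a time.
The background is a single genome-wide rate λ = library_total /
genome_length × fraglen. A window with count k is significant when the
upper-tail probability P(X ≥ k | λ) < 10⁻³; significant windows within
one fragment length merge into a peak scored −10·log₁₀(min p) (capped
at 10⁴ where the tail underflows), with the summit at the centre of the
leftmost best window. Using only the global λ — no local background —
is a deliberate simplification: the synthetic background is homogeneous
by construction, and the global-λ caller is fully auditable against
direct tail summation (the suite checks agreement to 10⁻¹²). On real
data with copy-number or accessibility structure a local-λ correction
would be needed. Because genuinely enriched regions absorb a
substantial share of the library, the global λ *over*-estimates the
background rate, making the caller conservative.

**Mixture-posterior caller.** The second, independent caller fits a
two-component Poisson mixture (background, enriched) to the bin counts
by EM with deterministic moment-based initialization (background ←
median count; enriched ← mean of the top 5%; mixing weight 0.05), so a
fixed input always yields identical output. Runs of bins with enriched
posterior > 0.5 become peaks scored −10·log₁₀(1 − posterior), capped at
1000. If the fitted enriched mean is less than twice the background
mean the fit is considered degenerate and no peaks are returned. This
caller is a stand-in for an HMM-based second caller: the pipeline needs
an *independent* confirmation track for the consensus step, not a
specific algorithm; it shares no statistics with the Poisson caller.

**Score convention.** Scores default to −10·log₁₀ p (the convention of
the transformed-p peak callers this mirrors); a `-log10` switch exists
because published tables are ambiguous between the two. All internal
logic uses only score *ordering*, so the choice affects display, not
calls.

## Liftover

Chain files are parsed and validated (block sums must equal the
declared spans). Region mapping is exact per-base arithmetic through
the ungapped segments: mapped_fraction = mapped bases / region length,
target span = [min, max+1) of mapped target positions, converted to
forward-strand coordinates for reverse-strand chains. minMatch is
inclusive (≥ 0.7 passes at exactly 0.70). Regions whose mapped bases
span more than one chain are failures ("split"), never stitched,
mirroring the standard region-mode liftover behaviour; the handling of
such ambiguities is a documented default, not an inference from any
published description. The reciprocal filter lifts forward, lifts
back, and requires ≥ 1 bp overlap with the original region (exact
coordinate equality available as a strict mode); the same minMatch is
applied on both journeys.

## The synthetic trio

The simulator generates a reference genome (uniform base composition;
CpG islands created by emitting the CG dinucleotide with token
probability 0.22, giving ~18% CpG density against ~6% background) and
derives the two non-reference genomes by substitutions and indels on
each branch. Defaults: 2 chromosomes × 1 Mb; substitution rates 0.014
(chimpanzee) and 0.065 (macaque) per bp, echoing the ~98.6% and ~93.5%
primate sequence identities; indel rates 0.0005 and 0.002 events/bp
with geometric lengths (mean 3 bp). Chains are built exactly from the
edit log and emitted in both directions. Indels are excluded from a
300 bp halo around planted regions so every planted region remains
fully liftable; substitutions are not excluded (they drive the
sequence-identity and motif analyses).

**Planted truth.** 120 regions of 400–700 bp in five classes (30
human-hypo, 30 human-hyper, 20 chimpanzee-only, 20 shared-methylated,
20 unmethylated background), placed ~30% in islands, ~30% in shores,
~40% in open genome, with a 700 bp spacing halo so the called peaks of
neighbouring regions cannot merge. Class semantics set per-species
methylation levels to 0.85 (high) or 0.005 (low); the background level
is also 0.005. Three "linked" genes receive a promoter-island
human-hypo region plus a first-exon human-hyper region — the
promoter/gene-body inversion pattern the ranking stage is designed to
surface. Five island-placed human-hypo regions carry a planted
motif-difference: a consensus motif site written into the reference
with one central base substituted on both non-human branches.

**MeDIP model.** Fragment midpoints are drawn with weight 1 + e·C(m),
where C(m) is the *expected* methylated-CpG content (sum of per-CpG
methylation levels) within one mean fragment length of the midpoint and
e = 4. Using expected content rather than a sampled binary state per
CpG is intentional: permanently "on" background CpGs would act as point
coverage attractors, an overdispersion that a global-λ caller cannot
distinguish from signal; the expected-content model keeps the
background locally Poisson while preserving the
enrichment-tracks-methylated-CpG-content property. Fragment lengths
are normal (200 ± 30, floored at 50); libraries include 2% exact
duplicates, 2% low-quality (q < 10) and 1% improperly paired fragments
to exercise filtering; per-species coverage multipliers (1.0/1.1/1.2 ×
30×) make library totals differ so normalization code is always
exercised. The background methylation level 0.005 is calibrated so
CpG-rich islands at background methylation stay well below the Poisson
significance threshold; at 0.01–0.02 the island windows approach the
threshold and produce sporadic false peaks — a realistic phenomenon,
but one that would conflate caller behaviour with generator noise in
the recovery tests.

**What the simulation does not model.** Read-level errors and FASTQ
simulation; inter-individual variation within a species (one pooled
landscape per species); CpG-density–dependent background methylation;
repeat-driven mappability structure; local copy-number variation. A
perfect recovery score on the synthetic trio therefore demonstrates the
*set logic and statistics* are correct under the stated model, not that
the caller parameters are optimal for real MeDIP data.

**Determinism.** All randomness derives from one master seed through
named substreams (genome, features, planting, per-branch edits,
per-species fragments), so a fixed seed reproduces every output file
byte-identically.

## Motif affinity

The occupancy model uses λ = 0.7 and ln R₀ = 0.584·W − 5.66 (the
parameterization of the published affinity-prediction method this
follows), exposed in `AffinityModel`. Windows containing N are skipped;
both strands are summed, making occupancy invariant under
reverse-complementation. The aggregate statistic for a region set is
the occupancy sum; its null distribution resamples length-matched
substrings from a background pool, with p = (r+1)/(B+1) and ties
counted against significance, so p is never 0 and never smaller than
1/(B+1). The per-motif "single total binding p-value" aggregation is a
documented stand-in — the exact aggregation used with the original tool
is not fully specified anywhere we could follow. Regions over 5 kb are
rejected at the type level. The repository ships 22 synthetic
JASPAR-style demonstration matrices (CTCF-like, SP1-like, RFX-like,
MeCP2-like and generic shapes); licensed motif libraries are accepted
as user-supplied count-matrix files. The divergence-map threshold
defaults to one log₁₀ unit of p-value change on both axes with
consistent sign.

## Enrichment statistics

Chi-square tests are Pearson 2×2 without continuity correction; when
any expected cell is below 5 the result comes from Fisher's exact test
and is flagged as such. Shuffle controls preserve the region count and
exact length multiset, placing regions uniformly (non-overlapping,
blacklist-excluded); the empirical p uses the same (r+1)/(N+1)
convention. Feature sizes (the per-Mb denominators) are always computed
from the merged union of the annotation, never taken from metadata.

## Gene-body ranking

A transcript's per-species score is the *maximum* transformed-p peak
score over peaks overlapping any exon, with 0 when no peak overlaps and
0 (with a logged warning) when an exon cannot be lifted to a species.
Max was chosen over sum because the motivating case is a single-exon
dominance pattern and max is robust to differing exon counts; sum is a
reasonable alternative and trivial to substitute. Promoters are
TSS ± 1 kb intersected with the associated 5′ CpG island when present.
Ranking uses H − mean(C, M), descending for hypomethylated-promoter
sets, ascending for hypermethylated; ties break on transcript id. Tests
against printed tables use an absolute tolerance of 0.11 because
published differentials were computed from scores with hidden decimals.

## Pipeline

Stages run in a fixed order and communicate only through files in the
run directory (BED/chain/FASTA/TSV/JSON), so any stage can be rerun
from persisted inputs and partial outputs survive a failure. The
default synthetic run (2 Mb trio) completes in well under two minutes
on one CPU; the problem sizes in the test suite (200 kb unit-test trio,
10–20 seed batteries at 2 Mb) were chosen to keep the full suite fast
while leaving the statistics well-powered. In user-data mode the
pipeline consumes user-supplied fragment tables, chains and
annotations; stages that need genome sequence (motif divergence) or
gene models (ranking) skip with a recorded status when those inputs are
absent.

## Known limitations

- The global-λ Poisson caller and the mixture caller are calibrated for
  the simulator's homogeneous background; real MeDIP data needs local
  background modelling and CpG-coupled normalization before the
  downstream logic applies.
- Liftover handles single-chain region mapping only (no net/axt, no
  chain stitching).
- The empirical directional randomization test takes a user-supplied
  statistic; it does not itself re-run the full affinity pipeline per
  draw.
- Aggregate motif p-values depend on the background pool supplied;
  the bundled island-sequence background is a convenience, not a
  curated promoter model.
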