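# Methods

This note documents the models and procedures implemented in `csslmap`,
the assumptions behind them, the parameters that matter, and the design
choices made where the methodology was genuinely open.

## The population model

A CSSL panel is simulated as a pedigree of meioses.  The F1 carries one
complete donor haplotype and one complete recurrent haplotype.  Each
backcross generation replaces the plant by (gamete from current plant) ×
(pure recurrent gamete); each selfing generation draws two independent
gametes from the same plant.  Defaults are `n_backcross=2, n_self=3`
(emulating a lightly backcrossed panel; `n_backcross=4` emulates a highly
backcrossed one).  Under this scheme the expected donor-genome fraction
after n backcrosses is 2^−(n+1) and selfing halves the heterozygous
fraction per generation — both laws are used as analytic oracles in the
tests.

**Crossover model.**  Per chromosome, the crossover count is
Poisson(length_cM/100) with positions uniform in cM and no interference —
i.e. the Haldane mapping function, under which the recombinant fraction at
distance d cM is (1 − e^(−2d/100))/2.  This is the standard assumption
when no empirical recombination map is available, and it is analytically
checkable.  An obligate-crossover flag (`SimConfig.obligate_crossover`,
off by default) forces at least one crossover per bivalent for users who
prefer that model.  The bp↔cM map is linear by default; piecewise-linear
anchors support nonuniform maps.  Real rice recombination hot/cold spots
are *not* emulated: simulated breakpoints are uniform in genetic distance,
so tests exercise the callers' logic, not their behaviour in recombination
deserts.

**Randomness.**  One master seed; per-line generators are spawned from a
`SeedSequence` by line index, so populations are bit-reproducible and
order-independent.  Marker-assisted selection is emulated by rejection
sampling on the per-line homozygous-donor segment count, capped at 10,000
attempts per line (explicit failure beyond that).

**Marker observation.**  Markers are placed uniformly at random per
chromosome.  The true call is the diploid state at the marker; with
probability `missing_rate` the call becomes missing, else with probability
`call_error_rate` it is replaced by one of the two other states uniformly.
Defaults used throughout the validation runs are 0.5% error and 2%
missing — representative of a targeted-sequencing SNP panel after standard
filtering.  Sequence-level read simulation and probe design are out of
scope.

**Phenotypes.**  y = μ + Σ a·x + N(0, σ²) with donor dosage
x ∈ {0, ½, 1}.  When per-locus PVE targets are given, σ is derived from
the *realized* genetic variance so the planted PVE is met in expectation
on that population.  Dominance is deliberately omitted: CSSLs are
near-homozygous, so an additive dose model is the appropriate
approximation.

## Window genotyping and segment calling

The classifier transcribes the published ratio rule in integer arithmetic:
in a 15-SNP window with `n_rec` recurrent and `n_don` donor calls,

- REC when `4·n_rec > 11·n_don` (ratio strictly larger than 11:4),
- DON when `13·n_rec < 2·n_don` (ratio strictly smaller than 2:13),
- HET otherwise;

windows with fewer than `min_informative = 8` informative (non-HET,
non-missing) calls are UNKNOWN.  Both comparisons are strict: the boundary
counts (11,4) and (2,13) fall to HET, the conservative reading of "larger
than"/"smaller than".  The thresholds apply to informative calls only, so
windows containing HET or missing calls remain classifiable.  Windows
slide with step 1 (abutting windows are supported via `step`); each marker
takes the plurality state of its covering windows, ties to HET.

**Why a refinement pass exists.**  The two ratio thresholds are strict
enough that windows straddling a clean homozygous→homozygous breakpoint
(2–11 recurrent calls of 15) are classified HET, truly heterozygous
regions produce UNKNOWN windows (almost no informative calls), and donor
segments shorter than ~14 markers never dominate any window.  All three
situations therefore surface as consensus HET/UNKNOWN zones.  Each maximal
such zone is re-segmented directly from the raw marker calls by a
penalized three-state changepoint fit (dynamic program over {REC, DON,
HET}; one unit per disagreeing call, missing neutral, `switch_penalty = 3`
per state change, deterministic tie-breaks).  The penalty means a new
segment needs more than 3 net supporting calls at a zone edge and more
than 6 in the interior — large enough that isolated call errors (0.5%
rate) never open segments, small enough that an 8-marker donor segment is
recovered.  This is a segmentation method, not hidden-Markov smoothing
(which remains out of scope); the window rule stays the primary caller and
the changepoint pass only arbitrates zones the window rule itself marks
ambiguous.

**Breakpoints.**  Every boundary between adjacent runs is then re-fit by a
minimal-mismatch changepoint on the raw calls of the two runs.  The *set*
of optimal split points defines the reported uncertainty interval: its
left edge is the last marker surely in the left segment, its right edge
the first marker surely in the right segment, and the breakpoint is placed
at the integer midpoint.  With clean flanking calls the interval is the
two markers bracketing the true breakpoint; a call error near the boundary
creates ties and the interval widens to cover them.  Positions between
markers are unobservable, so no narrower claim is made.

On a 200-line, 12-chromosome population at ~10,000 markers with 0.5% call
error and 2% missing data, the pipeline recovers ≥ 99% of 100-kb tile
states, and every true breakpoint that is detectable in principle (≥ 15
markers of matching origin per flank, error-free nearest flanking calls)
falls inside its reported uncertainty interval — both properties are
asserted by the test suite at exactly this scale.

## Recombination bins

Tiles are `[0, t), [t, 2t), …` with the trailing remainder merged into the
previous tile, so every tile is at least `tile_size` (default 100 kb).
A tile's state per line is the state covering most of its bases (exact
ties → HET); lines with no called segments on a chromosome are MISSING
there.  A single imputation pass fills a MISSING tile whose immediate
neighbours agree; afterwards MISSING is treated as a distinct state during
merging, preventing spurious over-merging.  Adjacent tiles whose full
across-line state vectors are identical collapse into one recombination
bin (idempotent, order-preserving, provenance retained).

Population summaries follow graphical-genotype conventions: per-line
recurrent fraction counts heterozygous bases half; a *substitution
segment* is a maximal run of homozygous-donor bins (HET excluded); segment
sizes are reported in cM through the genetic map; donor coverage is the
union of donor segments over lines.  Note that the per-line segment count
scales with total map length and generation number — a panel with more
residual donor genome or a longer map yields proportionally more segments.

## QTL scan

Model per bin j: y = μ + a·x_j + Z·γ + e with x_j the bin's donor dosage
and Z optional cofactor bins.  LOD = (n/2)·log10(RSS0/RSS1) =
LRT/(2 ln 10) under Gaussian residuals; PVE = (RSS0 − RSS1)/TSS.  Missing
phenotype or genotype is handled by per-bin pairwise deletion with
`n_used` reported; monomorphic bins are skipped and listed.  RSS1 = 0 is
capped at LOD 300.

**Cofactors.**  Forward stepwise selection by partial-F p-value
(`p_enter = 0.001`, cap n/10, ties broken by p-value then genomic order),
a stepwise-additive stand-in for composite-interval-style scans whose
published tool internals are not public — reproduced in spirit, not
bit-compatibly.  During the stepwise search missing dosages are
column-mean imputed (determinism and speed); the scan itself uses pairwise
deletion.  Cofactors within `window_cm = 10` of the tested bin are
excluded from the background.  One caveat documented from the validation
runs: in populations whose linkage blocks span tens of cM, a selected
cofactor a block away can absorb part of the causal signal and shift the
LOD argmax along the block.  Detection (a flagged bin near the causal
locus) is unaffected — which is why power is assessed as "supra-threshold
bin within 5 cM", matching the single-bin noncentral-χ² oracle
λ = n·PVE/(1−PVE) — but users localizing QTLs should read the 1.5-LOD
support interval, not the argmax alone.

**Thresholds.**  The conventional fixed LOD 2.5 is the default flag; a
genome-wide permutation threshold (max-LOD null distribution over
phenotype permutations, no-cofactor scan, seed-reproducible) is offered
alongside, and its 5% version is verified to control the genome-wide
false-positive rate.  The three environments of a multi-environment trial
are handled as independent scans; multi-QTL interval models and epistasis
are out of scope.

The scan is organised as a model/results pair (`BinQtlScan` → `fit()` →
`QtlScanResults` with `summary()`, `plot()`, peak table with 1.5-LOD drop
support intervals), the idiom of statistical-modelling packages; the other
pipeline stages are plain transforms and keep a functional surface.

## SV annotation

Five categories: coding (CDS when the GFF3 provides it, else exons — the
choice is logged), intron, strand-aware upstream 2 kb, downstream 2 kb,
and intergenic (complement of gene spans plus flanks).  "Intron" is
implemented as gene body minus coding blocks, so UTR exon parts fall into
the gene-body category rather than no category — this guarantees every SV
a non-empty category set (the four-category reading leaves UTRs
uncovered).  The ±2-kb flank is split by strand into upstream/downstream
to reach five categories; a merged-flank variant is available via
`merged_flanks=True`.  Flanks are clipped at chromosome ends but *not*
truncated by neighbouring genes: multi-assignment (an SV takes every
category it overlaps by ≥ 1 bp, so category percentages may total over
100%) makes truncation unnecessary and avoids inventing a precedence rule.
Insertions are classified at their 1-bp anchor; translocations contribute
one breakend per end, unioned per variant.  An SV is linked to every gene
whose span or flank it touches.  Classification is verified against a
per-base brute-force oracle on random fixtures.

## Telomeres and satellites

Telomere search is a direct motif scan: the 7-mer CCCTAAA at the 5′ end
and its reverse complement TTTAGGG at the 3′ end, within a 10-kb terminal
window, chaining tandem matches that are interrupted by at most one
non-motif heptamer, reporting an end as telomere-bearing at ≥ 10 copies.
The two thresholds are package choices (no published values exist for
them): permissive enough for genuine arrays, strict enough that random
sequence never qualifies.  The source literature is internally
inconsistent about the 5′ motif (CCCATTT in one place, CCCTAAA — the true
reverse complement of TTTAGGG — in another); CCCTAAA is the default and
both are accepted via the `motifs` parameter.

The satellite scan compares a monomer consensus (e.g. the ~155–165 bp rice
centromeric repeat) ungapped against every sequence offset in both
orientations; offsets at ≥ 80% identity mark their footprint, and 10-kb
windows with ≥ 50% marked bases merge into maximal spans (trimmed to
marked bases; copy estimate = marked bases / monomer length).  This is a
consensus-matching method suited to dense, near-identical arrays — it is
*not* a profile-HMM search and will not detect highly diverged monomers or
phase higher-order repeat structure.  A random 160-mer matches a random
window at ≥ 80% identity with probability ≈ 10⁻³⁵, so the null
false-positive rate is effectively zero (verified on megabase null
sequences).

## Numerical and interface conventions

Internal coordinates are 0-based half-open everywhere; conversion happens
only at format boundaries (GFF3/VCF 1-based closed, BED 0-based
half-open).  The marker-call alphabet is A/B/H/− with A the recurrent
parent.  Floating-point outputs are written at fixed precision for
diffability.  All stochastic stages are driven by explicit generators or
seeds and are bit-reproducible; the test suite asserts this end to end.

## What the synthetic data does and does not show

The generator reproduces the *genetic* structure of a CSSL panel —
segment-number and donor-fraction laws, breakpoint geometry, residual
heterozygosity, marker noise — so passing tests demonstrate that the
callers, bin builder, and scanner recover known truth under realistic
noise at realistic scale.  It does not reproduce recombination-rate
heterogeneity, segregation distortion, marker ascertainment bias, or real
trait architectures; conclusions about performance on a specific real
panel should be re-checked by rerunning the simulator with that panel's
map, marker density, and noise estimates.

Validation problem sizes (chosen once, as the package's study conditions):
5,000 gametes for the crossover-model checks; 1,000 lines per backcross
generation for the donor-fraction law; 200 lines × 12 chromosomes ×
~10,000 markers for genotype recovery; 200 lines and 1,000 permutations ×
200 null replicates for scan calibration; 100 phenotype replicates for
power and bias; 1,000 random SVs for the classifier oracle; megabase null
sequences for the satellite false-positive check.
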