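# Methods

`seqdap` reimplements the downstream comparative analysis of sequential
DNA-affinity-purification sequencing (seq-DAP-seq) for MADS transcription-
factor complexes: given replicate peak calls and coverage tracks for a
tetramer-competent complex and a tetramerization-deficient dimer, it asks
where the two complexes bind, how binding strength differs, what sequence
model explains the bound regions, whether the tetramer prefers particular
CArG-box intersite spacings, and which genes are both bound and
differentially expressed. Everything upstream of peak calls (read QC,
alignment, MACS2) is out of scope; peaks, coverage and DE tables are inputs.

## Consensus peaks

Replicate narrowPeak calls are merged into overlapping candidate regions. A
region survives when (i) at least `min_replicates` (default 2) distinct
replicates contribute a peak and (ii) the Fisher combination of the
per-replicate best −log10 p-values (χ² with 2k degrees of freedom) gives a
combined p ≤ `reproducibility_alpha` (default 10⁻⁴). This is a
dependency-free stand-in for external multi-sample peak-calling tools such
as MSPC, built from the same two ingredients they use — cross-replicate
support and the MACS2 p-value — with the 10⁻⁴ reproducibility cutoff.

Surviving regions are scanned for sub-peaks by single-linkage clustering of
the contributing summits with a 200-bp merge distance (two summits closer
than half a window cannot yield disjoint informative peaks); each cluster
becomes one peak at the round-half-down mean summit, width-normalized to
summit ± 200 bp — a 401-bp half-open window including the summit base.
Every peak carries the mean across replicates of its window's mean per-bp
coverage in reads-per-million (RPM = raw × 10⁶ / library size; the source
texts say "normalized" without a formula, RPM is our choice). Windows
clipped at a chromosome edge use the covered width as divisor and are
logged.

## Union catalogue, specificity, CFR

Two consensus sets are joined into one catalogue. A pair of peaks collapses
into a single entry when the overlap covers ≥ 80% of the smaller peak AND
each peak is less than 50% non-overlapping ("80% of two peaks overlapped"
is ambiguous in isolation; we enforce both printed clauses, which coincide
for equal-width normalized peaks). One-to-many overlaps resolve to the
largest-overlap pairing, ties to the lower coordinate (logged). A matched
entry keeps the summit of the higher-coverage experiment, re-windowed to
± 200 bp; unmatched peaks enter as they are. Both experiments' coverages
are then recomputed over every entry's window.

An entry is A-specific iff cov_A ≥ 2·cov_B, B-specific iff
cov_B ≥ 2·cov_A, otherwise common; the three labels partition the
catalogue, and swapping the experiments swaps the specific labels. The
coverage fold reduction CFR = cov_A / cov_B (conventionally
tetramer/dimer) ranks entries; entries with cov_B = 0 are flagged infinite
and excluded from ratio-ranked outputs (a pseudocount option exists but
defaults off). Deciles are equal-count bins of the descending CFR order,
remainders to the earliest deciles, ties broken by coordinate: decile 1
holds the regions most dependent on tetramerization. Heatmap matrices
(entries × 1000 bp, summit-centered, CFR-sorted) and mean intensity curves
are exported as TSV; rendering is left to the caller.

## Binding-site models

Both model classes score a 16-bp window by the likelihood ratio LR between
motif and background, mapped to s = LR/(1+LR) ∈ [0,1] — 0.5 means
indistinguishable from background, 1.0 is the ceiling of the scale. Both
strands are scored and the max taken; windows containing N score 0 so that
offsets remain comparable.

**PWM.** The 0-order model is trained by multi-start ZOOPS
expectation-maximisation (zero-or-one site per sequence, both strands),
standing in for MEME-chip: starting points are W-mers drawn from the data —
biased toward window centers, since peak windows are summit-centered and
summits sit on the motif — plus a start built by aligning occurrences of
the most background-enriched core 8-mer; each start runs a short EM burst
and the best likelihood continues to convergence (ΔlogL < 10⁻⁴, ≤ 200
iterations). Because the CArG flanks are weakly informative the window
phase sits on a likelihood ridge; for quasi-palindromic training
(`palindromic=True`, the analogue of `-meme-pal`) the fitted matrix is
re-phased to the shift that minimizes its distance from its own reverse
complement, refined briefly, and then averaged with its reverse complement,
making it exactly strand-symmetric. `site_prior=1` switches ZOOPS to OOPS
(exactly one site per window); a Gaussian positional prior on the site
location (`center_prior_sd`, used at 50 bp in the pipeline) exploits summit
centering and suppresses the ascertainment sharpening that otherwise
inflates strong columns.

**TFFM.** The first-order model keeps P(x₁) and a 4×4 conditional
P(xᵢ|xᵢ₋₁) per position, against a first-order background chain (strand-
symmetrised dinucleotide frequencies of the training set, started at its
stationary distribution). Training is the same EM over the hidden site
location, initialised from the PWM (identical rows = no dependency). After
convergence each position's transition table is G-tested (9 df) for a real
dependency on hard MAP-assigned site counts; positions that do not reject
at α = 0.01 collapse to identical rows. The counts for this test read each
window in a seeded coin-flip direction rather than the MAP strand —
content-dependent strand selection would itself fabricate dependencies
(verified: with MAP-strand reading the test rejected at most positions on
0-order data; with coin-flip reading all 15 positions collapse). The
collapse is what lets the TFFM beat the PWM out of sample: without it the
extra 45 parameters per null position are pure variance.

Training is selection: peaks are the regions a model was able to bind, so
fitted core columns run slightly sharp of any "planting" distribution. The
positional prior removes most of this at desk scale (recovery error
~0.03–0.04 against a known truth, versus 0.05–0.08 without).

## Evaluation

Models train on the 600 best peaks by mean coverage and are evaluated on
the held-out remainder against a matched unbound set: per positive region,
one region of identical length, same origin class (exon > intron >
promoter > intergenic, classified at the region midpoint; promoter =
TSS − 3 kb, strand-aware; the precedence order is our declared convention)
and same GC bin (width 0.05, widened stepwise when a stratum exhausts,
logged), never overlapping any peak, sampled without replacement with a
recorded seed. AUROC uses the Mann–Whitney rank statistic with mid-ranked
ties; the ROC points are exported, and the rank value equals trapezoidal
integration of the curve by construction (tested to 10⁻⁹). Best-score
distributions between two region sets are compared by Welch's t-test.

## Intersite spacing

Within each region every unordered pair of site hits at or above the score
threshold (default 0.7; the original analysis chose thresholds
empirically) contributes one count C_n at its center-to-center distance
n ≤ S_max (default 100 bp). Center-to-center is our declared convention —
the sources never define the origin, and this choice reproduces the
printed KNU probe values (45–46 bp); for equal-width sites it equals the
offset difference, and an edge-to-edge variant is available. Orientation
is deliberately ignored (the models are quasi-palindromic), and
overlapping pairs (n < W) are counted because the KNU weak boxes overlap
each other; a minimum-spacing flag exists. Frequencies are
f_n = C_n / ΣC, and the normalized enrichment against a background set is
N_n = f_pos,n / f_neg,n, undefined (NaN, logged) where f_neg,n = 0 —
never infinity.

The background set is the matched negative set, sampled at five regions
per bound region: at a few hundred bound regions a same-size background
leaves many spacing bins with zero or one pair, which makes N undefined or
wildly spiky exactly where it matters. The per-decile statistic is the
percentage of regions in each CFR decile containing at least one pair at a
preferred spacing (default {36, 37, 46, 47, 57} bp), with the decreasing
trend across deciles summarized by Spearman's ρ.

`annotate_probe` is the worked-example utility: exact string search (or
model scan) over a probe sequence, reporting box positions, centers
((start + end − 1)/2) and all pairwise center distances. The five 96-bp
KNU promoter probes ship in `seqdap.datasets`.

## Target genes

A gene's regulatory region spans TSS − 3 kb to TTS + 1 kb, strand-aware,
clipped at chromosome bounds (logged). A gene is bound when any peak
overlaps that region by ≥ 1 bp; a peak overlapping two genes' regions
counts for both. DE tables are filtered at |logFC| > 1 and FDR < 0.05 and
combined by set union ("concatenating" lists); with two regulators an
optional filter keeps only genes regulated in the same direction by both,
while conflicting directions within one regulator keep the gene flagged
ambiguous. Overlap significance is the hypergeometric upper tail
P(X ≥ k), computed in log space so −log10 p survives far beyond double
underflow; the universe defaults to all genes in the annotation and is
recorded in the output.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any real genome. Defaults (the study conditions for all tests): a 400-kb
genome in 2 chromosomes with per-window GC targets oscillating between
0.32 and 0.48; a 16-bp exactly palindromic CArG-like truth motif
(CC-(A/T)₆-GG core with A-tract/T-tract polarity, weak 3-bp flanks); 150
single sites and 100 site pairs planted at center-to-center spacings
{36, 46, 57} with cooperativity ω(d) = 1 + 7·exp(−(d−d₀)²/(2·1.5²))
(optionally repeated at +10.5-bp harmonics to mimic helical phasing); and
1000 decoy motif instances that receive no binding signal — the unbound
motif occurrences every real genome has, which give background regions
realistic motif content. Genes (1.5 kb, two exons, alternating strands
every 5 kb) tile the genome; a gene with a planted site in its regulatory
region is truth-regulated with probability 0.6, others 0.02, and the DE
table passes truth-regulated genes at sensitivity 0.9 with a 0.02 false-
positive rate among the rest.

A locus's expected binding signal is the likelihood ratio of its best
single site for a dimer, plus LR₁·LR₂·ω(d) for a pair when the complex
tetramerizes. Signal maps to coverage amplitude through
amp = 5·log1p(signal/50) reads/bp: LRs of sampled 16-mers span orders of
magnitude, so raw proportionality would be dominated by a handful of
sites, while a saturating map would erase the tetramer/dimer contrast the
CFR analysis measures; the log response is monotone and preserves every
ordering the module contract states. Coverage is drawn negative-
binomially (variance = μ + μ²/20) in 10-bp windows around a triangular
summit kernel (half-width 200 bp); peaks are emitted wherever the expected
amplitude clears a calling floor (1 read/bp), with the summit jittered
N(0, 10 bp) per replicate and a −log10 p from the Poisson tail of the
simulated counts — a thresholded-expected-signal rule, not a MACS2
reimplementation. All draws derive from a single seed; identical
configuration and seed reproduce byte-identical fixtures.

What the generator does not emulate: read-level artefacts (fragment-size
distributions, GC amplification bias, mappability), chromatin (the DAP
assays are on naked DNA, but decoy "unboundness" is imposed, not
emergent), peak-caller idiosyncrasies, and genome-scale motif
heterogeneity. Tests passing on these fixtures show the pipeline's rules
and statistics are implemented correctly and recover planted structure;
they do not show the biological conclusions would reproduce on the
archived sequencing data.

## Problem sizes and numerical choices

Test fixtures are scaled for a laptop-class run: recovery tests use a
400–800-kb genome, ~250–550 peaks, 10 seeds where a frequency claim is
made ("≥ 9/10 seeds"); the TFFM dependency oracle uses 800 sampled
instances (at 500 the dependent-row estimation noise alone approaches the
0.1 TV bound). EM convergence is ΔlogL < 10⁻⁴ with iteration caps (200
PWM, 100 TFFM); probability columns carry a 0.01 pseudocount; N-containing
windows score 0; spacing profiles with ΣC = 0 are an error rather than a
silent zero; CFR with cov_B = 0 is excluded rather than imputed; decile
remainders go to the earliest deciles; fractional mean summits round half
down. The pipeline manifest records config, seed, package version and
per-file checksums; a rerun with the same config reproduces identical
checksums.

## Known limitations

The EM trainers fit one motif; multi-motif discovery and spaced-dimer
motif models are out of scope (spacing is measured downstream instead).
The TFFM score is a normalized likelihood ratio on [0,1]; it matches the
published scale's anchors but not the original framework's scoring
internals, so absolute score values are not comparable across
implementations. The G-test collapse is calibrated for training sets where
site alignment is confident; on very noisy regions it may keep spurious
dependencies (the cost is mild overfitting, equivalent to never
collapsing). Genome-scale numbers from the archived datasets (thousands of
bound regions, the printed AUROC and CFR ranges) require those datasets
and are not reproduced here.
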