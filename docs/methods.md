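# Methods

## Scope and model

`larpmap` implements the desk-scale computational core of a PAR-CLIP /
ribosome-profiling analysis for polysome-associated RNA-binding proteins.
Upstream steps (adapter trimming, genome alignment, de novo motif
discovery, negative-binomial differential expression, GO enrichment) are
out of scope; alignments enter as a BED6+1 table of reads with per-read
T→C conversion offsets, and the discovered consensus motif enters as a
fixed IUPAC pattern. All coordinates are 0-based, half-open, in transcript
space; the simulator works on the plus strand only, while the I/O layer and
caller handle minus-strand reads (conversion position = end − 1 − offset,
sense-T = reference A).

## Site calling

Reads shorter than 13 nt are discarded. Same-strand reads overlapping
transitively form groups; groups with < 5 reads are dropped. Within a group
spanning positions [g₀, g₁):

- **signal events** — one event per conversion per read, at its transcript
  coordinate;
- **background events** — one event per covered position eligible for a
  non-conversion observation. By default every covered position is
  eligible; passing sequences restricts eligibility to sense-T positions
  (the photoreactive base). A position converted in *every* covering read
  carries no background event.

Both event sets are smoothed with a Gaussian kernel (bandwidth h = 3 nt,
the upstream tool's documented default, exposed as a parameter) and each
density is normalized to unit mass over the group span. The per-position
ratio is s/(s + b), undefined (masked) where read depth < 5. Candidate
clusters are maximal unmasked runs with s > b; they are retained when they
carry ≥ 2 conversion events from ≥ 2 distinct reads and are 11–100 nt wide.
The **mode location** is the in-run argmax of the ratio, ties broken
leftmost. All thresholds live in `SiteCallParams` and are echoed into the
run provenance.

Two deliberate design choices, made where the published parameterization
leaves room:

1. *Unit-mass normalization before comparison.* Signal and background event
   counts differ by orders of magnitude (a handful of conversions against
   every covered position), so raw count-scaled densities would make
   s > b unreachable; the normalized comparison asks where conversions
   *concentrate* relative to the extent of the locus, which is the quantity
   the cluster definition is after.
2. *Uniform background support by default.* The mode is the argmax of
   s/(s + b) and therefore of s/b, so any high-frequency structure in the
   background transfers directly into mode placement. A T-restricted
   background at 3-nt bandwidth carries the local presence/absence pattern
   of T's and displaces modes by up to ~10 nt on benchmark data; one event
   per covered position keeps the background smooth and the mode at the
   conversion peak. The T-restricted variant remains available by supplying
   sequences. Depth support is enforced separately by the KDE depth mask,
   and per-read background weighting was rejected for the same reason in
   stronger form (it reproduces the coverage pyramid, which peaks exactly
   at the crosslink and throttles cluster width).

The caller is verified exactly — intervals, read/conversion counts, modes —
against an independent brute-force implementation (union-find grouping,
plain-loop kernel sums, exhaustive run scanning) on hundreds of randomized
instances, and on a planted-site benchmark recovers 100% of sites with
zero mode error and no false calls across ten seeds.

## Annotation, targets, quantification

Sites are labelled by the region containing their mode (a site's point
summary), so boundary-spanning sites follow the mode; non-mRNA transcripts
collapse to a single `ncRNA` label. Targets are transcripts with ≥ 1
accepted site. CLIP counts include only reads overlapping accepted
clusters.

rpkm = (count / library total × 10⁶) / CDS length in kb. Ratio statistics
(CLIP enrichment, TE, disome abundance) exclude transcripts whose RNA rpkm
falls below a floor of 0.1 — the handling of low-abundance denominators is
not otherwise pinned down, and unstable ratios would dominate rank tests.
Excluded entries are NaN, never silently zero.

The polysome:monosome statistic is a deliberate simplification of a full
negative-binomial differential model: median-of-ratios size factors
(geometric mean over transcripts positive in both libraries), then
log₂((poly/s_P + c)/(mono/s_M + c)) with pseudocount c = 0.5.

`rank_compare` enumerates all label assignments exactly for n_A + n_B ≤ 12
(ties handled by half-counting; two-sided p = probability of a U at least
as far from n_A·n_B/2 as observed) and uses the tie-corrected normal
approximation above that. External score tables (e.g. RQC-factor binding
strength) are ranked into five equal-count bins with stable ties, bin 5 =
highest score; unscored targets are reported separately, never dropped
silently.

## Metagene profiles

Centile profiles use centile = ⌊100·(pos − orf_start)/orf_len⌋ clipped to
99, normalized to unit mass. Anchored profiles report offsets from the
start codon or the first nucleotide of the stop codon, normalized by the
number of contributing transcripts.

Mode-centered footprint profiles assign each read to its **center**
nucleotide by default. Footprints are long relative to the positioning
signal (57–63 nt for disomes), so span-coverage windows are flat-topped
plateaus whose argmax is set by noise; the center is the point statistic
that localizes a ribosome relative to the site. Coverage-style (`span`) and
5′-end assignment are available via the `assignment` flag. Each window is
normalized to its own mean defined coverage before averaging so deep sites
do not dominate; windows with zero coverage are excluded, and windows
truncated at transcript ends contribute only their defined offsets. Global
(unnormalized) aggregation is available by flag. Footprint class filters
are exact partitions of read length: 20–22, 28–30, 57–63 nt.

## Framing and structure

Motif scanning supports arbitrary IUPAC patterns and reports every
(possibly overlapping) match; for YGSU-like patterns the consensus G is
match_start + 1 and its codon frame is (g_position − orf_start) mod 3.
The framing statistic is reported per hit by default; a per-site mode
(first in-ORF hit per transcript) is available, since sites can contain
multiple motif copies. The ORFome-wide scan of the same pattern is the
null; note that even random-codon ORFs show a mild intrinsic frame bias
(≈ 0.42/0.29/0.28 here), as real ORFomes do — the planted-site signal is
judged against that baseline, not against exact uniformity.

PARS-style tracks are per-nucleotide scores with an undefined mask. PARS30
is the sum over a 30-nt window; windows leaving the track or touching an
undefined position are flagged NaN and excluded from aggregates (a partial
footprint window is not comparable to a full one). Around a mode the three
half-open windows [−45,−15), [−15,+15), [+15,+45) tile [−45,+45), the mode
belonging to the central window.

## Reporter and qPCR arithmetic

Dual-luciferase percentages are computed per replicate —
100 × (Fluc/Rluc)_test / (Fluc/Rluc)_control with the CAA reporter as the
stop-codon control and the frame-0 reporter as the frameshift control —
then summarized as mean ± sem. Per-replicate pairing keeps replicate
variance honest; pooled-control normalization is available by flag.
Primer efficiency follows the dilution-slope form
eff% = (10^(−1/slope) − 1) × 100; relative amounts are
E_t^(−Cq_t) / E_s^(−Cq_s) against a constant spike-in, reducing to
2^(−ΔΔCt) at perfect doubling. Two-way ANOVA with Tukey post hoc is a thin
wrapper over standard statsmodels routines, not re-derived.

## Synthetic data: what it emulates, and what it does not

The generator produces transcripts (5′UTR + ORF + 3′UTR, ORFs ATG…stop
with no internal frame-0 stop), crosslink sites sampled inside ORFs with
density ∝ ((pos − orf_start)/orf_len)^bias (bias 3 by default, matching a
strong 3′-ORF skew; bias 0 is uniform), CLIP reads (Poisson depth 50 per
site, lengths uniform 13–40 nt, conversion probability 0.5 at the
crosslink, 10% background reads that never convert), footprints per class
(centers at the site plus a class offset — 0 for standard/short, +30 nt
for disome, i.e. the stalled ribosome ahead of the crosslinked protein —
with 2 nt Gaussian jitter), RNA-seq counts (gamma-Poisson), structure
tracks (baseline + boost within ±15 nt of sites), and zero-/low-noise
reporter and qPCR tables. Planted sites keep ≥ 120 nt apart by default so
ground truth stays separable; the spacing is configurable and the bias
analyses relax it. Everything derives from one integer seed;
identical configurations are byte-identical.

Deliberately absent: rRNA contamination, multimapping, PCR duplicates,
4TU labeling chemistry, conversions at secondary T positions within a
site, non-uniform fragment-length distributions, and overdispersed CLIP
counts. Passing tests therefore demonstrate correctness of the
*computations* under a clean generative model — recovery rates on real
libraries, where conversions spread over several T's and background is
structured, will be lower and should be assessed per dataset.

## Problem sizes and numerics

Default validation sizes: 20 transcripts × 20 sites for caller benchmarks
(ten seeds), 50 × 2000 for positional-bias checks, 200 instances of ≤ 50
reads for oracle equivalence, 10⁴ background reads for flatness nulls —
sizes chosen so the full suite and the acceptance script each run in
seconds while keeping Monte-Carlo error well inside the asserted margins.
Kernel sums are computed in float64 directly (no FFT approximation);
density normalization divides by the span total only when positive;
argmax ties break leftmost everywhere; degenerate inputs (empty groups,
all-masked ratios, all-zero libraries, zero control ratios) raise typed
errors rather than returning sentinel values.
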