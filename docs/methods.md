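# Methods

## The synthetic maternal-transcriptome cohort

The generator (`matdosage.simulate`) emulates a two-stage, two-genotype
expression study of mouse oocytes — GV and MII stages crossed with a
control (CTL) and a maternal conditional knockout (mCKO) of an m⁶A
reader — together with the sequence and epitranscriptome structure the
downstream analyses consume.

**Expression model.** Per gene g with maturation class c(g) ∈
{stabilized, destabilized, unchanged}:

* GV log₂ abundance: `gv_g ~ Normal(8, 1.5)` (arbitrary microarray-like
  scale; only differences matter downstream);
* MII control: `mii_g = gv_g + log2(r_c(g) · j_g)`, where r_c is the
  class retention mean (defaults 1.10 / 0.33 / 0.84) and j_g a per-gene
  lognormal jitter with sd 0.25 on the log₂ scale, **mean-one on the
  linear scale**, so E[Σ2^mii] / E[Σ2^gv] = Σ_c f_c·r_c exactly;
* MII knockout: `mii_g + log2(boost)` for target genes only (default
  boost 2.0); GV is genotype-independent (the knockout transcriptome is
  normal before maturation begins);
* every sample value gets independent `Normal(0, 0.2)` replicate noise
  (3 replicates per stage × genotype).

With class fractions 0.08 / 0.12 / 0.80 the expected MII/GV mass ratio
is 0.08·1.10 + 0.12·0.33 + 0.80·0.84 = 0.7996, i.e. a ~20% degradation
wave. The retentions deliberately encode *relative* classes: after the
global 20% loss, a gene retaining 84% of its RNA is unchanged *in
relative dosage*, and 1.10 is "relatively stabilized" without absolute
accumulation (impossible without transcription). A consequence worth
stating: a symmetric 2-fold significance gate on the GV→MII contrast
recovers only the destabilized class (0.33 retention crosses the gate;
0.84 and 1.10 do not), so generator class labels and threshold classes
coincide only for "destabilized" — which is also how the class-recovery
tests are phrased.

**Knockout targets** are a fraction (default 0.04) of the destabilized
+ unchanged pool; stabilized genes are never targets. At 6000 genes
this yields ~220 targets whose class composition (~87% unchanged, ~13%
destabilized) drives the observed gate pattern. The default 2-fold
boost places the true knockout log₂FC exactly on the 2-fold calling
threshold, so with symmetric replicate noise ~half the targets are
called up; the calling power tests therefore assert near-complete
recovery at a clearly supra-threshold boost (2.5) and ~50% recovery at
the on-threshold default.

**Sequences.** One single-exon transcript per gene on its own contig
(offset 1000 nt from the contig start): 5′UTR 30–300 nt, CDS 300–1500 nt
(AUG and a stop codon written in), 3′UTR ~Exp(450) clipped to
[20, 1500] nt so a substantial fraction is shorter than the 400-nt flank
and exercises N-padding. Targets get Poisson(3) motif instances planted
at Normal(stop, 50 nt) positions clipped to the stop window; non-targets
get Poisson(0.5) uniform instances. Plants are spaced at least one
pattern-length apart and never overwrite the start/stop codons, so every
recorded plant is recoverable by scanning; random sequence additionally
contains chance matches (a 4-nt pattern with one two-letter position
matches at 1/128 per position, ~6 expected per 800-nt window), so
scanned matches are a strict superset of plants.

**Peaks.** Each of 12 emulated public m⁶A samples contributes one
150-nt peak per target gene centered Normal(stop, 50 nt) with score
U(4, 10), plus Poisson(0.1) background peaks per contig per sample with
score U(0.5, 3).

**What the generator does not emulate:** probe-level microarray
artifacts and normalization, multi-isoform genes and splicing,
transcription, polyadenylation state, sequence composition biases
(uniform base usage), correlated replicate noise, and genome-scale
contig structure (every gene sits alone on its contig). Passing tests
therefore demonstrate correctness and calibration of the *analysis*
under the stated statistical structure, not robustness to real-data
artifacts.

## Dosage statistics

`moderated_t` follows the standard empirical-Bayes variance-moderation
scheme. Hyperparameters are moment-matched on z = log s²: with
e = z − ψ(d/2) + log(d/2), solve ψ′(d₀/2) = var(e) − ψ′(d/2) for d₀
(Newton iteration on the trigamma inverse, tolerance 1e-12) and set
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When var(e) ≤ ψ′(d/2) the
log-variances are under-dispersed relative to pure χ² sampling, one
common variance explains the data, and the estimator returns d₀ = ∞
with s₀² = mean(s²) (the field-standard convention); posterior
variances then all equal s₀² and p-values use the standard Normal.
The implementation is verified against R limma's `lmFit`/`eBayes` to
~1e-9 on t and p and ~1e-7 relative on (d₀, s₀²) in the finite case.

Benjamini–Hochberg is implemented as the literal step-up rule
(vectorized cumulative minimum over the sorted p·m/rank sequence,
capped at 1) and property-tested against brute-force enumeration and
statsmodels. Calling uses fold change ≥ 2 and **raw** p < 0.05 by
default (adjusted p and inclusive ≤ available by flags); the knockout
contrast defaults to strict `<`, the maturation contrast to inclusive
`≤`, both configurable. Fold change is defined as 2^(difference of
mean log₂ values), the natural definition on RMA-style matrices.
2^−ΔΔCt uses the mean Ct of the reference genes within each sample and
the mean ΔCt of the reference condition as baseline.

## Maturation gates

`classify_maturation` applies the same tri-state rule to the GV-vs-MII
control contrast; `gate_crosstab` is an exact 3×3 contingency with
margins and up-row fractions. Gene universes must match exactly;
mismatches raise with the symmetric difference.

## Motif profiling

Windows are anchored at the **first nucleotide** of the codon
(0-based, half-open), so the downstream half contains the codon itself;
out-of-transcript positions are 'N', which never matches. Matching
scans every offset (overlapping occurrences all count) via a regex
lookahead. The "center of the gene list" is the block of `set_size`
ranks centered at floor(L/2), which tiles exactly against the top and
bottom blocks when L = 3·set_size. Deduplication keeps, per gene, the
transcript with the highest |log₂FC| (ties to the lexicographically
smallest id), then drops later-ranked duplicates of an identical
sequence.

The default pattern is `GAC[UA]`, the reader's published binding
consensus; the permuted literal `GCA[UA]` that sometimes appears in
method listings is available by configuration but is almost certainly a
typo of the same consensus — the package does not silently correct
either way, it just defaults to the consensus.

**Smoothing.** The positional profile is the raw column sum; the
default smoother is a cubic smoothing spline with its penalty chosen by
generalized cross-validation (`scipy.interpolate.make_smoothing_spline`),
with loess (statsmodels `lowess`, span 0.15) as the alternative.
Smoothed values are clipped at ≥ 0 for reporting. Enrichment statistics
never depend on the smoother.

**Enrichment test and its region.** A transcript is a "hit" if ≥ 1
match starts inside the tested band; the universe is test ∪ reference
(2·set_size transcripts) and p is the upper-tail hypergeometric
survival function evaluated in log space (verified against exact
rational enumeration to 1e-12 relative for N ≤ 60). The band matters:
with a ~1/128 per-position background rate the hit indicator saturates
as the band grows (P(hit) ≈ 0.53 at ±50 nt, ≈ 0.80 at ±100 nt, ≈ 1
for the full ±400-nt window), and a saturated indicator cannot detect
enrichment however strong the planted signal. The default band is
therefore **±50 nt around the anchor**, where the background indicator
is near 0.5 and the stop-proximal planted signal (position sd 50 nt)
concentrates; the band and the full window are configurable, and the
count-based profile comparison (up-profile exceeding the unchanged
profile across a ±100-nt band) is tested separately on the raw
profiles.

## Metagene profiling

Peaks are merged per contig into disjoint intervals (merge rule: max of
contributing scores by default; mean and count available; optional
minimum-score pre-filter). Occupancy is binary prevalence (covered-base
fraction per bin) by default, or the per-base score mean. The body
(start codon up to the stop codon) is split into 100 equal-width bins
with the last bin absorbing the integer remainder; flanks are 400 nt in
fixed 10-nt bins. Genomic codon positions refer to the lowest genomic
base of the codon; minus-strand genes are processed on the mirrored
span and reversed so columns always run 5′→3′ (property-tested by
mirror-image gene pairs). Genes with bodies shorter than the bin count
are skipped with a warning. The region test is Welch's t on per-gene
mean occupancy over the downstream flank block (the 400 nt after the
stop codon) by default — the natural "around the stop codon" region for
peaks planted at the stop — with the classic pooled t and arbitrary bin
regions available.

## Pipeline and determinism

Stages communicate only via on-disk artifacts in plain-text formats
(FASTA / TSV / BED / JSON). A run is a pure function of its YAML config:
every random draw derives from the single seed via per-stage child
streams, so rerunning a config reproduces `report.json` byte for byte.
Wall-clock timings and file hashes are logged to `run.log` only and
deliberately kept out of the report so the determinism guarantee is
checkable by byte comparison. The default demo (6000 genes — large
enough for three disjoint 1000-transcript sets and stable calibration,
small enough to run in seconds) is the problem size used throughout the
examples and checks.

## Known limitations

* The moderated-t framework assumes a common residual df across genes
  (balanced replication); unbalanced designs would need Welch-style
  handling the package does not implement.
* The hypergeometric hit indicator discards multiplicity; a
  count-based test (e.g. binomial on total matches) would use more
  information but needs a background model for per-position rates.
* Binary prevalence weights every covered base equally; the score mode
  is a simple per-base mean, not a signal-extraction model.
* The generator's classes are relative-retention constructs; absolute
  per-class retentions in real oocytes are not identifiable from
  dosage data alone and the chosen values are calibration choices
  constrained only by the ~20% global loss.
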