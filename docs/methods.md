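# Methods

This note documents the models, parameter choices and numerical
conventions of `micmac`, and what the synthetic data does and does not
emulate.

## Synthetic genome

The generator partitions every contig into kb-aligned intervals of three
compartments — MAC-destined, MIC-PGM and MIC-only — at configurable
proportions (default 0.80 / 0.17 / 0.03). Blocks of MIC-PGM (4–16 kb)
and MIC-only (2–6 kb) are dropped at random positions into an initially
MAC-destined background; contig ends stay MAC-destined. kb alignment
makes 1-kb-window recovery unambiguous; a `ragged` mode jitters internal
boundaries by up to 400 nt to exercise partial-window behaviour.

Base composition is i.i.d. at GC = 0.28 (the AT-rich regime typical of
the organisms this models). Three feature classes are planted, mutually
non-overlapping and never crossing a compartment boundary:

* **IESs** — density 0.6 per MAC-destined kb (~480 in 1 Mb), lengths
  lognormal with median 51 nt and log-sd 0.456, truncated to
  [10, 2000] nt. The log-sd puts ~93% of draws under 100 nt, so the
  ≥ 90% rule holds with margin under sampling noise. Both ends are
  forced to the boundary dinucleotide (default `TA`). 98% of IESs are
  placed in MAC-destined intervals, the rest in MIC-PGM. IES interiors
  share the genomic base composition — how much real IES content differs
  from flanking DNA is not modelled, and nothing downstream depends on
  it.
* **Transposon copies** — drawn from a small synthetic consensus library
  (default 3 families × 1.5 kb), full-length or truncated (≥ 200 nt),
  mutated at up to 8% divergence, both strands. Target bp fractions per
  compartment default to 0.012 / 0.21 / 0.07: MIC-only is 3-fold
  TE-depleted relative to MIC-PGM.
* **Tandem repeats** — arrays of 120–800 nt with motif period 2–10 and
  1% motif divergence; target fractions 0.008 / 0.05 / 0.20, i.e. a
  4-fold satellite enrichment of MIC-only over MIC-PGM. Because planting
  is by whole features, small compartments overshoot their budget by up
  to one feature length.

**Excision convention.** IES coordinates include both boundary TAs; the
excised segment is `[start + 2, end)`, retaining one TA in the somatic
product, the convention of TA-bounded IES excision in *Paramecium*. The
chemistry is configurable; retention scoring only requires that
generator and scorer agree. Three genome views are derived with exact
(bijective on retained positions) liftovers: **somatic** (IESs excised,
MIC-PGM and MIC-only deleted), and **PGM-silenced** (only MIC-only
deleted — IESs and MIC-PGM retained). The PGM view exists because the
three-way window classification is undefined without a sample class that
covers MIC-PGM but not MIC-only sequence; biologically it models cells
in which the excision endonuclease is depleted yet the MIC-only fraction
is still eliminated. Length bookkeeping is exact:
`germline = somatic + excised IES nt + MIC-limited nt`.

Coordinates are 0-based half-open everywhere internally; 1-based only in
GFF3 output. All randomness flows through one seeded generator, so a
(config, seed) pair reproduces every byte.

## Read simulation

Paired-end reads (100 nt) from fragments of N(300, 100²) nt, truncated
to [read length, contig length] (truncation raises the realized mean
fragment to ≈ 305 nt), positions uniform, orientation FR with random
strand. Errors are uniform substitutions (default 0.002/base) with one
flat base quality (35) — no indels, no quality profile, no GC bias, no
PCR duplicates. Expected pairs per component =
`coverage × component_length / (2 × read_length)`.

A sample with unexcised copy fraction *f* at total coverage *c* is the
pool of germline at `f·c` and somatic at `(1−f)·c`. Defined this way the
expected retention score equals *f* exactly (junction reads split as a
binomial conditional on the local total), while the germline *read*
share is `f·Lg / (f·Lg + (1−f)·Ls)` — copies are weighted by their
length, as in real ploidy mixtures. The five study classes use
f = 0 (control), 0.69 / 0.82 (unsorted / sorted PGM-silenced) and
0.04 / 0.38 (unsorted / sorted MIC-enriched). Contaminant reads are
provenance-tagged draws from a separate sequence set, so the
"exclude contaminants" normalization step is testable without real
bacterial genomes.

## Mapping

Exact 21-mer seeds at `max_mismatches + 1` evenly spaced offsets: by
pigeonhole every ungapped hit with ≤ max_mismatches (default 3)
substitutions is found when the read is at least `(max_mm+1)·k` long.
Candidates are verified by vectorised Hamming counting. Mapping quality
is 60 for a best hit unique by a ≥ 2-mismatch margin, 30 for a margin of
1, 0 for a tie; "uniquely mapped" downstream means mapq ≥ 30. Ties are
broken deterministically (contig order, then coordinate, then strand).
Seeds occurring more than 256 times are truncated; reads from long
satellite arrays may then lose hits, but such reads are mapq-0
multi-mappers that every downstream filter discards anyway.

Reads with no full-length hit are rescued by the best prefix or suffix
alignment with ≤ max_mismatches mismatches and ≥ 30 aligned nt,
emitted with soft clips. This reproduces the behaviour of local-mode
aligners on reads spanning an excision junction of the other genome
view: without it, pooled-depth estimates lose the junction-crossing half
of somatic coverage around each IES. Clipped alignments contribute to
depth but are excluded from junction-support counting.

## Retention scoring

Reads are mapped to both references. At each IES boundary, full-length
alignments with ≤ 1 mismatch (the default `max_mismatch`) covering the
junction with ≥ 5 nt on both sides count as IES+ (germline reference)
or IES− (somatic reference; the single excision junction serves both
boundaries). The 5-nt overhang is a package choice — enough informative
sequence on each side of a junction to exclude coincidental overlap; it
cancels between the two classes, so the score is insensitive to it.
Reads supporting both forms of one IES are discarded. Mates and
boundaries are counted independently (no fragment deduplication).
Undefined scores (no junction coverage) are excluded from summaries
rather than imputed; histograms use fixed 0.05-wide bins.

## Windows, depth, compartments

1-kb non-overlapping windows; a terminal remainder is kept iff > 400 nt
(401 counts, 400 drops). Depth counts aligned bases of mapq ≥ 30
alignments with base quality ≥ 30. Normalization multiplies by
`1e9 / nucleotides_sequenced` (excluding contaminant-tagged reads); the
constant is arbitrary and recorded in output metadata — only ratios
matter. Per-nucleotide classification calls depth < 20 MIC-limited on
*raw* depth (the threshold reads as raw fold-coverage; the choice is
recorded in config).

The NB Wald test uses median-of-ratios size factors (reported unscaled),
a per-window method-of-moments dispersion floored at 0.01, the
delta-method SE of the log ratio of class means, and a two-sided normal
reference; BH adjustment excludes untestable (all-zero) windows from the
multiplicity count. Fold-changes are raw, not shrunken, and pegged at
±10 log2 units when a class mean is zero. No dispersion-trend shrinkage,
outlier handling or independent filtering is done: validation is
parameter and compartment recovery on synthetic data, not bitwise
equality with a particular differential-coverage package (an externally
produced results table in the same TSV schema can be imported for
cross-checking). With Poisson-like synthetic counts at 2–3 replicates
the floor makes the test conservative by design; its type-I error is
calibrated (empirically 0.05–0.06 at α = 0.05) in the regime where the
moment estimator is consistent — true dispersion above the floor and
large replicate numbers.

Mode counting on the two-sample density grid smooths with a uniform
3×3 filter and counts local maxima reaching ≥ 15% of the dominant
mode's height — a relative rule, so the count is invariant to bin width
and window number.

## Composition

GC excludes ambiguous bases from the denominator. Low-complexity masking
flags 100-nt windows with AT > 87% or GC > 89% (strict inequalities) and
poly-purine/pyrimidine runs ≥ 30 nt. The tandem-repeat finder seeds
candidate periods (2–500) from recurring 10-mers and extends with
+2/−7 match/mismatch scoring, reporting arrays with score ≥ 50 and ≥ 2
copies; overlaps resolve by score, then smaller period, then leftmost.
It is a deliberate simplification of probabilistic tandem-repeat
models — no indels, no composition term — adequate for the near-perfect
arrays the generator plants. TE masking is k-mer-seeded, ungapped and
diagonal-banded with a +1/−4 density score, ≥ 80% identity over
≥ 80 nt; it will not find diverged or indel-riddled copies the way a
full local aligner would. Enrichment between compartments uses exact
two-sided binomial tests on base-pair counts; treating nucleotides as
independent trials is anti-conservative for clustered features, so these
p-values support ranking and directional claims, not literal error
rates.

## Problem sizes and what the tests show

Validation runs at: 1 Mb / 5 contigs / ~480 IESs / 50x per sample for
retention recovery (means recovered within ±0.02 of f for all five
classes) and for the pooled 40x + 60x depth check (≈ 97x over
MAC-destined windows — junction clipping and IES interiors account for
the few points below the nominal 100x); 300 kb for compartment recovery
(≥ 95% window accuracy; satellite enrichment and TE depletion of
MIC-only vs MIC-PGM at p < 1e-10) and for the two-cloud density
structure. Passing these shows the statistics are implemented correctly
and unbiased under the generator's assumptions; it does *not* show
robustness to indels, coverage bias, mappability artefacts, diverged
repeats, or assembly fragmentation, none of which the simulation
contains.
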