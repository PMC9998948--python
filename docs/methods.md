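# Methods

This note records the models, conventions, and numerical choices behind
`tescope`, in the spirit of a statistical-software methods appendix: what
each procedure assumes, which knobs matter, and what the synthetic
benchmarks do and do not demonstrate.

## Conventions

All coordinates are 0-based half-open internally; RepeatMasker tables
(1-based inclusive, "C" orientation) are converted on parse and restored on
export. Minus-strand alignments store coordinates on the forward strand of
the target with an orientation flag. Sequences use one internal DNA
alphabet: U is mapped to T on ingest and remembered per record so writers
can restore the RNA alphabet. Non-ACGT symbols (N, and the separator used
internally by the mapper) never match anything.

## Repeat landscape

**Clustering.** Library redundancy is removed by greedy incremental
clustering: entries are visited in decreasing length (ties toward the
lexicographically later id) and each joins the first cluster whose
representative matches it at or above the identity threshold, else founds a
cluster. Identity is `matches / length of the shorter sequence` under the
best ungapped offset alignment. This approximates CD-HIT-est's global
identity semantics without its heuristics; it is exact for the
contained-duplicate case (identity 1.0 reduces to exact-duplicate classes)
and deterministic throughout. Gapped identity is out of scope, so diverged
homologs containing indels cluster less readily than CD-HIT would merge
them.

**Masking.** The read masker is a desk-scale stand-in for a full
repeat-masking engine, matched to the simulator's substitution-only
mutation model. Exact 11-mer seeds nominate (consensus, diagonal) pairs per
strand; a diagonal qualifies when its best-scoring contiguous segment
(match +1, mismatch −2, maximum-subarray scan) reaches `min_hit_len`
(default 30 bp — the evidence gate that rejects chance 11-mer hits in
background sequence, whose best segments stay near seed length). The
reported hit then spans the **full** read/consensus overlap on that
diagonal, so `pct_div` is the Hamming mismatch fraction of the whole
aligned read region; hits above `max_divergence` (default 40%) are
discarded. Reporting the full overlap rather than the trimmed segment keeps
recovered divergences identical to the planted per-read mutation fractions
instead of biased low by end-trimming. Overlapping hits on a read are
resolved best-score-first with ties to the lower consensus id; surviving
intervals are merged before masked base pairs are summed.

**Diversity.** Superfamilies are the "species" and masked base pairs the
"individuals": `D = Σ nᵢ(nᵢ−1)/(N(N−1))` (finite-sample Simpson),
Gini–Simpson `1−D`, Shannon `H = −Σ pᵢ ln pᵢ` with `0·ln 0 = 0`; `N ≥ 2`
required. H is exactly scale-invariant; the finite-sample `D` converges to
`Σ pᵢ²` at the base-pair counts involved (tested to 1e-4 at N ≥ 1e6). The
default community for diversity is the set of named superfamilies —
derivative categories (TRIM/LARD/MITE) and order-level-only or unknown
rows are excluded, which is the configuration under which the bundled
survey's abundance vector reproduces its published Shannon index (1.92).
The survey's published Gini–Simpson value is not reproducible from its
printed per-superfamily percentages under the stated formula (the best
reconstruction gives ≈0.81), because the underlying masked-base-pair counts
are not printed at full precision; the Simpson implementation is therefore
validated against closed forms instead.

**Divergence landscapes.** Each read contributes once per superfamily via
its least-divergent hit, binned at 1%. A superfamily is "ongoing" when the
[0,1%) bin is occupied. Shape labels come from a 3-bin moving average
(edge-truncated): a global maximum in bin 0 is "recent-peak-decreasing",
otherwise the local-maxima count separates unimodal from multimodal past
peaks. Shape classification of real landscapes is inherently visual; the
smoothing rule is a reproducible proxy, and on read-level histograms the
discreteness of per-read mismatch counts (a 150-bp read can only show
divergences at multiples of ⅔%) can produce sawtooth artifacts that the
3-bin smoother does not fully remove — shape calls are robust for the
hand-scale histograms they are tested on, less so for fine-binned
read-level data.

## Small-RNA processing and mapping

Filtering applies, in order: length bounds (18–40 nt inclusive), N
content, an optional mean-quality threshold, and contaminant removal
(full-length exact match to rRNA/mito references on either strand —
conservative and deterministic). Putative piRNAs are the 25–30 nt subset;
both total and unique counts are reported since published analyses use
both denominators. miRNA annotation flags 21–24 nt reads matching a
reference exactly on either strand.

The mapper finds **all** full-length ungapped placements of a query with at
most k substitutions (k ≤ 5). Queries are split into k+1 disjoint equal
blocks; any placement within budget must contain one exact block
(pigeonhole), so exact block matches — located through a sorted index of
base-7-packed windows — nominate candidates that are then Hamming-verified.
When the query is no longer than k, every placement is within budget and
all offsets are verified directly. The result is provably identical to a
brute-force sliding-window scan, and the test suite asserts this
equivalence property on randomized instances. Multi-mapping reads keep all
placements; per-target read counting is once-per-read-per-target.

## Ping-pong signature

Sense mapping allows 0 mismatches (a piRNA processed from a transcript
should match it exactly); antisense allows ≤3 (cleavage tolerates imperfect
pairing). Transcripts lacking hits in either orientation are excluded — the
signature is defined only where both strands are represented. With the
sense 5′ end at offset `s` and the antisense 5′ end at
`a = offset + length − 1`, each (sense, antisense) placement pair on a
transcript contributes overlap `ℓ = a − s + 1`, accumulated for
`1 ≤ ℓ ≤ 25` via position-count cross-correlation (linear in transcript
length, not quadratic in reads). Pairs are read-level — duplicated
sequences count per read — and multi-transcript placements count
independently, a transcript-centric convention. The Z-score standardizes
the focal fraction against the sample standard deviation of the other 24
overlap fractions; it is undefined (None) for degenerate distributions and
an error with fewer than 3 background lengths. Calibration on simulated
pools: with no planted pairs |Z₁₀| < 3 in ≥95% of seeds, and with pair
fraction 0.3 in 20,000 piRNAs the modal overlap is 10 with Z₁₀ > 3 in ≥95%
of seeds (both asserted in the suite at exactly these sizes).

## Expression and pathway ratios

TPM uses the transcript length as the effective length (no fragment-length
correction — a quantifier-internal detail that would break the closed-form
synthetic oracle); every non-degenerate column sums to 1e6. Superfamily
expression means TPM across same-sex replicates per transcript, then sums
within superfamily. Sex-bias testing is Welch's t on log10(TPM+1) (the
pseudocount handles zeros), skipping superfamilies under 10 transcripts;
genome-wide differential-expression calling (negative-binomial modeling) is
out of scope, but an external differentially-expressed transcript list can
be applied as a pre-filter. Abundance–expression and RPM–TPM relationships
are ordinary least squares on log10-transformed positive values, reporting
Pearson R, slope, p, and a t-based slope CI.

Pathway activity per individual is the ratio of a silencing set's summed
TPM to the miRNA-processing set's summed TPM, which cancels library scale
and spares cross-species normalization. The bundled sets (21 piRNA
processing, 14 repressive-chromatin, TRIM28, 14 miRNA processing) ship as a
YAML resource. In full-set mode missing genes contribute zero (emulating
incomplete annotations); conservative mode first restricts all sets to
genes present in every species of the panel — the published conservative
subsets are not enumerated gene-by-gene, so intersection semantics are the
stated interpretation. The genome-size regression is OLS of the ratio on
log10(genome size, Gb), requiring ≥4 species.

## Synthetic data: what it emulates and what it does not

The generators plant the study conditions: genome reads as mutated
consensus fragments (per-copy divergence drawn from point-mass,
exponential, or normal-mixture models; exactly `round(d·L/100)` positions
substituted, so realized divergence is exact and recorded); transcriptome
counts multinomial in expression × length with a per-transcript male
multiplier; small-RNA pools with a truncated-discretized-normal piRNA
length law (mode 29 nt over 25–30), first-nucleotide U forced with
probability u on antisense primaries, a sense partner emitted with
probability ρ at exactly a 10-nt 5′–5′ overlap, plus optional 22-nt
transcript-derived reads, synthetic miRNA copies, and contaminant
fragments; and species panels with log-normal gene noise of unit mean, so
expected pathway ratios equal the configured ones. Defaults follow the
study conditions where stated (length bounds, piRNA window, mismatch
budgets, 29-nt mode, 15-species 1–130 Gb size range); free parameters
(1.5-kb transcripts, 150-bp reads, 20% log-normal noise, equal
sense/antisense piRNA split) are fixed at values typical for this kind of
data.

Known simplifications: no indels and no sequencing-error model beyond
substitutions, one consensus per superfamily (real superfamilies are
consensus ensembles), uniform read qualities, no genome architecture
(piRNA clusters, strand asymmetries along real transcripts), and
exact-match miRNA annotation against a synthetic reference rather than a
curated database. Consequently, passing recovery tests demonstrate
correctness of the statistics under the stated generative model — they do
not certify performance on real libraries where indel divergence,
quality artifacts, and reference incompleteness matter.

The benchmark problem sizes — 20,000 reads for landscape recovery, 20,000
piRNAs × 200 seeds for ping-pong calibration, 100 panel seeds for the
genome-size null — were chosen so the full suite completes in minutes on a
single core while keeping Monte-Carlo error well inside the asserted
margins.

## A note on the bundled survey data

`tescope.datasets` ships the printed summary numbers of a published
low-coverage repeat survey of the ~21 Gb *Ranodon sibiricus* genome.
Derived quantities (method shares, expression fractions, coverage,
diversity, abundance–expression correlations) are recomputed from the raw
printed counts at call time, never stored. One caveat is inherent to
printed tables: the survey's own abundance–expression correlations were
computed on a 19-superfamily set that includes superfamilies whose genomic
abundance falls below the table's printing precision; from the printed
columns alone (16 superfamilies with both values), the ovary correlation
reproduces in sign and magnitude (R ≈ 0.77) while the testis correlation
lands lower (R ≈ 0.66) than the published value, driven by one
low-abundance, high-expression superfamily (Maverick) whose sub-precision
genomic abundance is not recoverable.
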