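"""Repeat-library clustering, genome proportions, diversity, and divergence
landscapes.

The desk-scale masker here stands in for a full repeat-masking engine: it
finds, for each read, ungapped alignments to library consensuses by exact
k-mer seeding followed by best-segment scoring on the seeded diagonal.
Because the simulators plant substitution-only divergence, an ungapped
diagonal alignment recovers the true placement and the per-read divergence
exactly, which keeps every downstream landscape statistic testable against
planted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import AlignmentHit, AnnotationLabel, SequenceRecord, get_logger, revcomp

__all__ = [
    "RepeatLibrary",
    "ClusterSet",
    "AbundanceVector",
    "DiversityResult",
    "DivergenceHistogram",
    "ActivityCall",
    "cluster_contigs",
    "pairwise_identity",
    "mask_reads",
    "genome_proportions",
    "diversity_indices",
    "divergence_histogram",
    "classify_activity",
]

MIN_CONTIG_LEN = 100  # repeat contigs shorter than this are rejected


@dataclass
class RepeatLibrary:
    """Consensus sequences with TE labels; entries < 100 bp are rejected."""

    entries: list[tuple[SequenceRecord, AnnotationLabel]]
    provenance: dict[str, str] = field(default_factory=dict)
    rejected: list[str] = field(default_factory=list)

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        labels: Sequence[AnnotationLabel],
        provenance: Mapping[str, str] | None = None,
        min_length: int = MIN_CONTIG_LEN,
    ):
        if len(records) != len(labels):
            raise ValueError("records/labels length mismatch")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate entry ids in repeat library")
        self.entries = []
        self.rejected = []
        for rec, lab in zip(records, labels):
            if len(rec.seq) >= min_length:
                self.entries.append((rec, lab))
            else:
                self.rejected.append(rec.id)
        if self.rejected:
            get_logger().warning(
                "RepeatLibrary: rejected %d contigs < %d bp", len(self.rejected), min_length
            )
        self.provenance = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def records(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.entries]

    @property
    def annotation(self) -> dict[str, AnnotationLabel]:
        return {rec.id: lab for rec, lab in self.entries}


# ---------------------------------------------------------------------------
# redundancy clustering

def pairwise_identity(a: str, b: str) -> float:
    """Identity of the best ungapped offset alignment, over the shorter sequence.

    The shorter sequence is slid along the longer one; at each offset the
    number of matching positions in the overlap is counted, and the best
    match count is divided by the length of the shorter sequence.
    """
    if len(a) > len(b):
        a, b = b, a
    sa = np.frombuffer(a.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.encode(), dtype=np.uint8)
    n, m = len(sa), len(sb)
    best = 0
    # offsets with full containment of the shorter sequence
    for off in range(m - n + 1):
        best = max(best, int((sa == sb[off : off + n]).sum()))
        if best == n:
            break
    return best / n


@dataclass
class ClusterSet:
    clusters: list[list[str]]          # member ids per cluster
    representatives: list[str]         # longest member per cluster
    identity: float

    def as_mapping(self) -> dict[str, str]:
        """member id -> representative id"""
        return {
            member: rep
            for rep, cluster in zip(self.representatives, self.clusters)
            for member in cluster
        }


def cluster_contigs(library: RepeatLibrary, identity: float) -> ClusterSet:
    """Greedy incremental clustering at an identity threshold.

    Entries are visited in decreasing length (ties toward the
    lexicographically later id); each joins the first existing cluster whose
    representative matches it at >= ``identity`` over the shorter sequence,
    else founds a new cluster.  Representatives are therefore always the
    longest member of their cluster.
    """
    if not (0.0 < identity <= 1.0):
        raise ValueError("identity must be in (0, 1]")
    ordered = sorted(library.records, key=lambda r: (len(r.seq), r.id), reverse=True)
    reps: list[SequenceRecord] = []
    clusters: list[list[str]] = []
    for rec in ordered:
        for ci, rep in enumerate(reps):
            if pairwise_identity(rec.seq, rep.seq) >= identity:
                clusters[ci].append(rec.id)
                break
        else:
            reps.append(rec)
            clusters.append([rec.id])
    return ClusterSet(clusters, [r.id for r in reps], identity)


# ---------------------------------------------------------------------------
# read masking

_SEED_K = 11


def _seed_index(records: Sequence[SequenceRecord], k: int) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for ci, rec in enumerate(records):
        s = rec.seq
        for p in range(len(s) - k + 1):
            index.setdefault(s[p : p + k], []).append((ci, p))
    return index


def _best_segment(mismatch: np.ndarray) -> tuple[int, int, int]:
    """Best-scoring contiguous segment (match +1, mismatch -2).

    Returns (start, end, score) with end exclusive; the classic maximum-
    subarray scan, used as the evidence gate for a seeded diagonal.
    """
    scores = np.where(mismatch, -2, 1)
    best = cur = 0
    best_s = best_e = cur_s = 0
    for i, sc in enumerate(scores):
        if cur <= 0:
            cur = 0
            cur_s = i
        cur += sc
        if cur > best:
            best = cur
            best_s, best_e = cur_s, i + 1
    return best_s, best_e, int(best)


def mask_reads(
    reads: Sequence[SequenceRecord],
    library: RepeatLibrary,
    min_hit_len: int = 30,
    max_divergence: float = 40.0,
    seed_k: int = _SEED_K,
) -> list[AlignmentHit]:
    """Ungapped k-mer-seeded masking of reads against library consensuses.

    For each read and strand, exact ``seed_k``-mer matches nominate
    (consensus, diagonal) pairs; a diagonal qualifies when its best-scoring
    segment reaches ``min_hit_len``.  The reported hit spans the full
    read/consensus overlap on that diagonal (so ``pct_div`` is the Hamming
    mismatch fraction of the whole aligned read region) and is discarded if
    that divergence exceeds ``max_divergence``.  Each read position is
    attributed to at most one hit: highest score wins, ties to the lower
    consensus id.
    """
    if not len(library):
        raise ValueError("empty repeat library")
    records = library.records
    index = _seed_index(records, seed_k)
    enc = [np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in records]
    hits: list[AlignmentHit] = []
    for read in reads:
        candidates: list[AlignmentHit] = []
        for strand in "+-":
            seq = read.seq if strand == "+" else revcomp(read.seq)
            rlen = len(seq)
            renc = np.frombuffer(seq.encode(), dtype=np.uint8)
            seen: set[tuple[int, int]] = set()
            for p in range(rlen - seed_k + 1):
                for ci, cp in index.get(seq[p : p + seed_k], ()):
                    diag = cp - p
                    if (ci, diag) in seen:
                        continue
                    seen.add((ci, diag))
                    cons = enc[ci]
                    r0 = max(0, -diag)
                    r1 = min(rlen, len(cons) - diag)
                    if r1 - r0 < min_hit_len:
                        continue
                    mism = renc[r0:r1] != cons[r0 + diag : r1 + diag]
                    s, e, score = _best_segment(mism)
                    if e - s < min_hit_len:
                        continue
                    n_mism = int(mism.sum())
                    aligned = r1 - r0
                    pct = n_mism / aligned * 100.0
                    if pct > max_divergence:
                        continue
                    if strand == "+":
                        rs, re = r0, r1
                    else:  # flip to forward-read coordinates
                        rs, re = rlen - r1, rlen - r0
                    candidates.append(
                        AlignmentHit(
                            read_id=read.id,
                            consensus_id=records[ci].id,
                            read_start=rs,
                            read_end=re,
                            cons_start=r0 + diag,
                            cons_end=r1 + diag,
                            strand=strand,
                            pct_div=pct,
                            score=float(aligned - 3 * n_mism),
                        )
                    )
        # one hit per read position: best score first, ties to lower id
        candidates.sort(key=lambda h: (-h.score, h.consensus_id))
        taken: list[tuple[int, int]] = []
        for h in candidates:
            if all(h.read_end <= s or h.read_start >= e for s, e in taken):
                taken.append((h.read_start, h.read_end))
                hits.append(h)
    return hits


# ---------------------------------------------------------------------------
# genome proportions and diversity

@dataclass
class AbundanceVector:
    """Masked base pairs per superfamily; the community abundance vector."""

    counts: dict[str, float]
    total_bp: float | None = None  # denominator for percent-of-genome

    @property
    def N(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def proportions(self) -> dict[str, float]:
        N = self.N
        return {k: v / N for k, v in self.counts.items()} if N > 0 else {}

    @property
    def percent_of_genome(self) -> dict[str, float]:
        if not self.total_bp:
            raise ValueError("total_bp not set")
        return {k: v / self.total_bp * 100.0 for k, v in self.counts.items()}


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def genome_proportions(
    hits: Sequence[AlignmentHit],
    annotation: Mapping[str, AnnotationLabel],
    total_bp: float,
    read_lengths: Mapping[str, int] | None = None,
) -> AbundanceVector:
    """Masked bp per superfamily after merging overlapping hit intervals."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    per_read: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        if read_lengths is not None and h.read_end > read_lengths.get(h.read_id, h.read_end):
            raise ValueError(f"hit beyond read bounds: {h.read_id}")
        label = annotation.get(h.consensus_id, AnnotationLabel()).superfamily
        per_read.setdefault((h.read_id, label), []).append((h.read_start, h.read_end))
    counts: dict[str, float] = {}
    for (_, label), intervals in per_read.items():
        bp = sum(e - s for s, e in _merge_intervals(intervals))
        counts[label] = counts.get(label, 0.0) + bp
    return AbundanceVector(counts, total_bp=total_bp)


@dataclass
class DiversityResult:
    D: float            # Simpson's index, finite-sample form
    gini_simpson: float  # 1 - D
    H: float            # Shannon index, natural log
    labels: list[str]


def diversity_indices(abundance: AbundanceVector) -> DiversityResult:
    """Simpson's and Shannon diversity of the TE community.

    Superfamilies are the "species" and masked base pairs the "individuals":
    D = sum n_i(n_i - 1) / (N(N - 1)) and H = -sum p_i ln p_i with
    0 ln 0 = 0.  Unknown or class-only categories are expected to have been
    excluded upstream.
    """
    counts = {k: v for k, v in abundance.counts.items() if v > 0}
    if not counts:
        raise ValueError("no labels with positive abundance")
    n = np.array(list(counts.values()), dtype=float)
    N = n.sum()
    if N < 2:
        raise ValueError("Simpson's D undefined for N < 2")
    D = float((n * (n - 1)).sum() / (N * (N - 1)))
    p = n / N
    H = float(-(p * np.log(p)).sum())
    return DiversityResult(D, 1.0 - D, H, list(counts))


# ---------------------------------------------------------------------------
# divergence landscape

@dataclass
class DivergenceHistogram:
    superfamily: str
    counts: np.ndarray   # bin b covers [b, b+1) percent
    bin_width: float = 1.0

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.counts) + 1) * self.bin_width


def divergence_histogram(
    hits: Sequence[AlignmentHit],
    annotation: Mapping[str, AnnotationLabel],
    bin_width: float = 1.0,
) -> dict[str, DivergenceHistogram]:
    """Per-superfamily histogram of per-read divergence, 1% bins by default.

    Each read contributes once per superfamily, via its least-divergent hit
    to a consensus of that superfamily.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.pct_div < 0:
            raise ValueError("negative divergence")
        label = annotation.get(h.consensus_id, AnnotationLabel()).superfamily
        key = (h.read_id, label)
        if key not in best or h.pct_div < best[key]:
            best[key] = h.pct_div
    by_label: dict[str, list[float]] = {}
    for (_, label), div in best.items():
        by_label.setdefault(label, []).append(div)
    out = {}
    for label, divs in by_label.items():
        n_bins = int(max(divs) // bin_width) + 1
        counts = np.zeros(n_bins, dtype=int)
        for d in divs:
            counts[int(d // bin_width)] += 1
        out[label] = DivergenceHistogram(label, counts, bin_width)
    return out


@dataclass
class ActivityCall:
    ongoing: bool
    shape: str   # recent-peak-decreasing | past-peak-unimodal | past-peak-multimodal | flat/other
    argmax_bin: int


def _smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average with edge truncation (ends average fewer bins)."""
    if len(counts) < window:  # convolve('same') would outgrow the signal
        return counts.astype(float)
    kernel = np.ones(window)
    num = np.convolve(counts.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(counts, dtype=float), kernel, mode="same")
    return num / den


def classify_activity(hist: DivergenceHistogram) -> ActivityCall:
    """Ongoing-activity call and coarse amplification-history shape.

    A superfamily is called "ongoing" when reads < 1% diverged from a
    consensus exist.  The shape label comes from the 3-bin moving-average of
    the histogram: a global maximum in the first bin is the signature of a
    superfamily still accumulating at its highest-ever rate; otherwise the
    number of local maxima separates unimodal from multimodal past peaks.
    """
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    ongoing = counts[0] > 0
    sm = _smooth(counts)
    argmax = int(np.argmax(sm))
    if len(sm) > 1 and np.allclose(sm, sm[0]):
        return ActivityCall(bool(ongoing), "flat/other", argmax)
    if argmax == 0:
        return ActivityCall(bool(ongoing), "recent-peak-decreasing", 0)
    # interior and edge local maxima on the smoothed profile
    n_peaks = 0
    for i in range(len(sm)):
        left = sm[i - 1] if i > 0 else -np.inf
        right = sm[i + 1] if i < len(sm) - 1 else -np.inf
        if sm[i] > left and sm[i] >= right:
            n_peaks += 1
    shape = "past-peak-unimodal" if n_peaks <= 1 else "past-peak-multimodal"
    return ActivityCall(bool(ongoing), shape, argmax)
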