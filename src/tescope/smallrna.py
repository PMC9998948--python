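"""Small-RNA preprocessing, composition statistics, and the shared mapper.

The mapper implements full-length, ungapped placement of short queries on a
set of target sequences with a bounded number of substitutions.  Candidate
placements are found by pigeonhole seeding — a query with at most ``k``
mismatches must contain at least one of ``k+1`` disjoint exact blocks — and
verified by Hamming count, so the result is exactly the set a brute-force
sliding-window search would return.  Non-ACGT symbols never match anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import SequenceRecord, revcomp

__all__ = [
    "FilterConfig",
    "FilterStats",
    "LengthSpectrum",
    "FirstNtComposition",
    "MappingHit",
    "PiRNASet",
    "TargetIndex",
    "filter_small_rna",
    "length_spectrum",
    "first_nt_composition",
    "select_putative_pirnas",
    "annotate_mirnas",
    "map_with_mismatches",
]

# ---------------------------------------------------------------------------
# filtering

@dataclass
class FilterConfig:
    """Small-RNA filtering thresholds; input is assumed adapter-trimmed."""

    min_len: int = 18
    max_len: int = 40
    disallow_n: bool = True
    contaminants: Sequence[SequenceRecord] = ()
    min_mean_quality: float | None = None

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")


@dataclass
class FilterStats:
    n_input: int = 0
    removed_length: int = 0
    removed_n: int = 0
    removed_quality: int = 0
    removed_contaminant: int = 0
    n_kept: int = 0


def _mean_quality(qual: str) -> float:
    return float(np.mean([ord(c) - 33 for c in qual])) if qual else 0.0


def filter_small_rna(
    reads: Sequence[SequenceRecord], config: FilterConfig
) -> tuple[list[SequenceRecord], FilterStats]:
    """Apply length -> N-content -> quality -> contaminant removal, in order.

    Contaminant removal drops reads that match a contaminant reference
    full-length with zero mismatches on either strand.
    """
    stats = FilterStats(n_input=len(reads))
    # exact-substring membership on either strand, via one concatenated text
    contaminant_text = "X".join(
        s for r in config.contaminants for s in (r.seq, revcomp(r.seq))
    )
    kept = []
    for r in reads:
        if not (config.min_len <= len(r.seq) <= config.max_len):
            stats.removed_length += 1
            continue
        if config.disallow_n and "N" in r.seq:
            stats.removed_n += 1
            continue
        if (
            config.min_mean_quality is not None
            and r.qual is not None
            and _mean_quality(r.qual) < config.min_mean_quality
        ):
            stats.removed_quality += 1
            continue
        if contaminant_text and r.seq in contaminant_text:
            stats.removed_contaminant += 1
            continue
        kept.append(r)
    stats.n_kept = len(kept)
    return kept, stats


# ---------------------------------------------------------------------------
# composition statistics

@dataclass
class LengthSpectrum:
    counts: dict[int, int]
    mode: int | None


def length_spectrum(reads: Sequence[SequenceRecord]) -> LengthSpectrum:
    """Integer length counts with the modal length (ties to the smaller)."""
    counts: dict[int, int] = {}
    for r in reads:
        counts[len(r.seq)] = counts.get(len(r.seq), 0) + 1
    if not counts:
        return LengthSpectrum({}, None)
    mode = min(counts, key=lambda length: (-counts[length], length))
    return LengthSpectrum(dict(sorted(counts.items())), mode)


@dataclass
class FirstNtComposition:
    """Fractions of A/C/G/U at the first position, per read length.

    ``per_length[L]`` maps each RNA base to its fraction among length-L
    reads; ``overall_u`` is the 5'-U fraction over all reads.
    """

    per_length: dict[int, dict[str, float]]
    overall_u: float


_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


def first_nt_composition(
    reads: Sequence[SequenceRecord], group_by_length: bool = True
) -> FirstNtComposition:
    per_len: dict[int, dict[str, int]] = {}
    n_u = 0
    for r in reads:
        base = _DNA_TO_RNA.get(r.seq[0], "N")
        if base == "U":
            n_u += 1
        key = len(r.seq) if group_by_length else 0
        per_len.setdefault(key, {b: 0 for b in "ACGU"})
        if base in "ACGU":
            per_len[key][base] += 1
    fractions = {}
    for length, counts in sorted(per_len.items()):
        total = sum(counts.values())
        if total:
            fractions[length] = {b: c / total for b, c in counts.items()}
    overall = n_u / len(reads) if reads else 0.0
    return FirstNtComposition(fractions, overall)


@dataclass
class PiRNASet:
    """Length-selected putative piRNAs (25-30 nt by default)."""

    reads: list[SequenceRecord]
    n_total: int
    n_unique: int


def select_putative_pirnas(
    reads: Sequence[SequenceRecord], min_len: int = 25, max_len: int = 30
) -> PiRNASet:
    sel = [r for r in reads if min_len <= len(r.seq) <= max_len]
    return PiRNASet(sel, len(sel), len({r.seq for r in sel}))


def annotate_mirnas(
    reads: Sequence[SequenceRecord],
    mirna_reference: Sequence[SequenceRecord],
    min_len: int = 21,
    max_len: int = 24,
) -> tuple[list[bool], float]:
    """Flag reads matching a miRNA reference exactly on either strand.

    Returns a per-read flag list (aligned with ``reads``) and the flagged
    fraction among reads in the ``min_len``-``max_len`` window.
    """
    if not mirna_reference:
        raise ValueError("empty miRNA reference")
    ref_text = "X".join(
        s for r in mirna_reference for s in (r.seq, revcomp(r.seq))
    )
    flags = []
    n_window = n_flagged = 0
    for r in reads:
        in_window = min_len <= len(r.seq) <= max_len
        flag = in_window and r.seq in ref_text
        flags.append(flag)
        n_window += in_window
        n_flagged += flag
    fraction = n_flagged / n_window if n_window else 0.0
    return flags, fraction


# ---------------------------------------------------------------------------
# mismatch-bounded ungapped mapping

@dataclass(frozen=True)
class MappingHit:
    """One full-length ungapped placement of a read on a target.

    ``offset`` is 0-based on the forward strand of the target; for antisense
    hits the placed sequence is the reverse complement of the read.
    """

    read_id: str
    target_id: str
    offset: int
    orientation: str  # {"sense", "antisense"}
    mismatches: int
    length: int


# target symbols: A=0 C=1 G=2 T=3 N=5 separator=6; query N encodes to 4 so
# that N never matches N and nothing matches a separator
_ENC_TARGET = np.full(256, 6, dtype=np.uint8)
_ENC_QUERY = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC_TARGET[ord(_c)] = _i
    _ENC_QUERY[ord(_c)] = _i
_ENC_TARGET[ord("N")] = 5
_BASE = 7          # packing base covering symbols 0..6
_MAX_BLOCK = 22    # 7**22 < 2**64


def _encode(seq: str, table: np.ndarray) -> np.ndarray:
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class TargetIndex:
    """Seed index over a fixed target set, reusable across many queries."""

    _PAD = 6  # separator run longer than any allowed mismatch budget

    def __init__(self, targets: Sequence[SequenceRecord]):
        self.ids = [t.id for t in targets]
        self.lengths = np.array([len(t.seq) for t in targets], dtype=np.int64)
        sep = "X" * self._PAD
        concat = sep.join(t.seq for t in targets) if targets else ""
        self._enc = _encode(concat, _ENC_TARGET) if concat else np.empty(0, np.uint8)
        starts = np.zeros(len(targets), dtype=np.int64)
        if len(targets) > 1:
            starts[1:] = np.cumsum(self.lengths[:-1] + self._PAD)
        self.starts = starts
        self.ends = starts + self.lengths
        self._block_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def _block_index(self, b: int) -> tuple[np.ndarray, np.ndarray]:
        """Sorted base-7 codes of all length-``b`` windows, with positions."""
        if b not in self._block_cache:
            n = len(self._enc) - b + 1
            if n <= 0:
                codes = np.empty(0, dtype=np.uint64)
                order = np.empty(0, dtype=np.int64)
            else:
                powers = (_BASE ** np.arange(b - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
                windows = np.lib.stride_tricks.sliding_window_view(self._enc, b)
                codes_all = (windows.astype(np.uint64) * powers).sum(axis=1)
                order = np.argsort(codes_all, kind="stable").astype(np.int64)
                codes = codes_all[order]
            self._block_cache[b] = (codes, order)
        return self._block_cache[b]

    def map_batch(
        self, reads: Sequence[SequenceRecord], k: int, orientation: str = "sense"
    ) -> list[MappingHit]:
        """All placements with <= ``k`` substitutions, for every read."""
        if orientation not in {"sense", "antisense"}:
            raise ValueError(f"bad orientation {orientation!r}")
        if not (0 <= k <= 5):
            raise ValueError("k must be in 0..5")
        if not self.ids or not reads:
            return []
        hits: list[MappingHit] = []
        by_len: dict[int, list[int]] = {}
        for i, r in enumerate(reads):
            by_len.setdefault(len(r.seq), []).append(i)
        for L, idxs in by_len.items():
            seqs = [
                reads[i].seq if orientation == "sense" else revcomp(reads[i].seq)
                for i in idxs
            ]
            q = np.stack([_encode(s, _ENC_QUERY) for s in seqs])
            qi, off, mism = self._map_group(q, L, k)
            tidx = np.searchsorted(self.starts, off, side="right") - 1
            for j in range(len(qi)):
                t = tidx[j]
                hits.append(
                    MappingHit(
                        read_id=reads[idxs[qi[j]]].id,
                        target_id=self.ids[t],
                        offset=int(off[j] - self.starts[t]),
                        orientation=orientation,
                        mismatches=int(mism[j]),
                        length=L,
                    )
                )
        hits.sort(key=lambda h: (h.read_id, h.target_id, h.offset, h.orientation))
        return hits

    def _map_group(self, q: np.ndarray, L: int, k: int):
        """Vectorized pigeonhole search for a matrix of length-L queries."""
        nq = q.shape[0]
        if L <= k:
            # every placement is within budget: verify all offsets directly
            n_off = len(self._enc) - L + 1
            if n_off <= 0:
                e = np.empty(0, np.int64)
                return e, e, e
            off = np.tile(np.arange(n_off, dtype=np.int64), nq)
            qidx = np.repeat(np.arange(nq, dtype=np.int64), n_off)
            return self._verify(q, qidx, off, L, k)
        b = max(1, min(L // (k + 1), _MAX_BLOCK))
        powers = (_BASE ** np.arange(b - 1, -1, -1, dtype=np.uint64)).astype(np.uint64)
        codes_sorted, order = self._block_index(b)
        cand_q: list[np.ndarray] = []
        cand_off: list[np.ndarray] = []
        for blk in range(k + 1):
            o = blk * b
            if o + b > L:
                break
            qcodes = (q[:, o : o + b].astype(np.uint64) * powers).sum(axis=1)
            left = np.searchsorted(codes_sorted, qcodes, side="left")
            right = np.searchsorted(codes_sorted, qcodes, side="right")
            counts = right - left
            total = int(counts.sum())
            if total == 0:
                continue
            qidx = np.repeat(np.arange(nq), counts)
            within = np.arange(total) - np.repeat(
                np.concatenate(([0], np.cumsum(counts)[:-1])), counts
            )
            pos = order[np.repeat(left, counts) + within]
            cand_q.append(qidx)
            cand_off.append(pos - o)
        if not cand_q:
            return np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64)
        qidx = np.concatenate(cand_q)
        off = np.concatenate(cand_off)
        # dedupe (query, offset) pairs seeded by multiple blocks
        ok = (off >= 0) & (off + L <= len(self._enc))
        qidx, off = qidx[ok], off[ok]
        if len(qidx) == 0:
            return qidx, off, np.empty(0, np.int64)
        key = qidx * np.int64(len(self._enc) + 1) + off
        _, uniq = np.unique(key, return_index=True)
        return self._verify(q, qidx[uniq], off[uniq], L, k)

    def _verify(self, q, qidx, off, L, k):
        """Hamming-verify candidate placements, keeping those inside one target."""
        if len(qidx) == 0:
            return qidx, off, np.empty(0, np.int64)
        t = np.searchsorted(self.starts, off, side="right") - 1
        ok = (off >= self.starts[t]) & (off + L <= self.ends[t])
        qidx, off = qidx[ok], off[ok]
        if len(qidx) == 0:
            return qidx, off, np.empty(0, np.int64)
        windows = self._enc[off[:, None] + np.arange(L)]
        mism = (windows != q[qidx]).sum(axis=1)
        keep = mism <= k
        return qidx[keep], off[keep], mism[keep].astype(np.int64)


def map_with_mismatches(
    query: str | SequenceRecord,
    targets: Sequence[SequenceRecord],
    k: int,
    orientation: str = "sense",
) -> list[MappingHit]:
    """Full-length ungapped placements of one query on each target.

    Equivalent to a brute-force sliding-window Hamming search; antisense
    queries are reverse-complemented before placement and reported on the
    forward coordinates of the target.
    """
    if isinstance(query, str):
        query = SequenceRecord("query", query)
    return TargetIndex(targets).map_batch([query], k, orientation)
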