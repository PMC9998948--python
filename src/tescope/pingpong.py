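"""Ping-pong signature statistics for putative piRNAs.

Secondary piRNA biogenesis cleaves a target transcript 10 nt from the 5'
end of the guide, so ping-pong amplification leaves a characteristic excess
of sense/antisense piRNA pairs whose 5' ends overlap by exactly 10 nt.
This module maps putative piRNAs to TE transcripts (0 mismatches sense,
up to 3 antisense), builds the distribution of 5'-5' overlap lengths, and
standardizes the 10-nt fraction against the other overlap lengths as a
Z-score.

Overlap definition: a sense hit's 5' end sits at transcript offset ``s``
(its placement offset); an antisense hit's 5' end sits at
``a = offset + length - 1``.  The pair's overlap is ``l = a - s + 1``,
counted when ``1 <= l <= L``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import AnnotationLabel, SequenceRecord
from .smallrna import MappingHit, PiRNASet, TargetIndex

__all__ = [
    "OverlapDistribution",
    "PingPongResult",
    "map_pirnas_to_tes",
    "overlap_distribution",
    "zscore",
    "zscore_from_fractions",
    "pingpong_pairs_by_superfamily",
    "rpm_by_superfamily",
    "summarize_pirna_by_superfamily",
    "pingpong_signature",
]


def map_pirnas_to_tes(
    pirnas: PiRNASet | Sequence[SequenceRecord],
    te_transcripts: Sequence[SequenceRecord],
    sense_k: int = 0,
    antisense_k: int = 3,
    index: TargetIndex | None = None,
) -> tuple[list[MappingHit], list[MappingHit]]:
    """Sense and antisense placements of putative piRNAs on TE transcripts.

    Sense mapping allows no mismatches (a piRNA processed directly from a
    transcript should match it exactly); antisense mapping allows up to
    ``antisense_k`` because target cleavage tolerates imperfect pairing.
    Transcripts hit in only one orientation are excluded from both returned
    hit lists — the signature is defined only where both strands are
    represented.
    """
    reads = pirnas.reads if isinstance(pirnas, PiRNASet) else list(pirnas)
    if not reads:
        return [], []
    if index is None:
        index = TargetIndex(te_transcripts)
    sense = index.map_batch(reads, sense_k, "sense")
    antisense = index.map_batch(reads, antisense_k, "antisense")
    both = {h.target_id for h in sense} & {h.target_id for h in antisense}
    return (
        [h for h in sense if h.target_id in both],
        [h for h in antisense if h.target_id in both],
    )


@dataclass
class OverlapDistribution:
    """Counts and fractions of 5'-5' overlap lengths 1..L."""

    counts: np.ndarray      # counts[l-1] = pairs with overlap l
    max_overlap: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray | None:
        t = self.total
        return self.counts / t if t > 0 else None

    @property
    def modal_overlap(self) -> int | None:
        return int(np.argmax(self.counts)) + 1 if self.total > 0 else None


def overlap_distribution(
    sense_hits: Sequence[MappingHit],
    antisense_hits: Sequence[MappingHit],
    max_overlap: int = 25,
) -> OverlapDistribution:
    """Distribution of 5'-5' overlap lengths over all sense/antisense pairs.

    Every (sense placement, antisense placement) pair on the same transcript
    contributes once; duplicated read sequences therefore count per read.
    Computed per transcript from 5'-position counts, so the cost is linear
    in transcript length rather than quadratic in hit count.
    """
    counts = np.zeros(max_overlap, dtype=np.int64)
    by_target_s: dict[str, list[int]] = {}
    by_target_a: dict[str, list[int]] = {}
    for h in sense_hits:
        by_target_s.setdefault(h.target_id, []).append(h.offset)
    for h in antisense_hits:
        by_target_a.setdefault(h.target_id, []).append(h.offset + h.length - 1)
    for target, s_pos in by_target_s.items():
        a_pos = by_target_a.get(target)
        if not a_pos:
            continue
        hi = max(max(s_pos), max(a_pos)) + 1
        cs = np.bincount(s_pos, minlength=hi)
        ca = np.bincount(a_pos, minlength=hi)
        for l in range(1, max_overlap + 1):
            d = l - 1
            # pairs with a - s = d
            counts[l - 1] += int(np.dot(ca[d:], cs[: hi - d]))
    return OverlapDistribution(counts, max_overlap)


def zscore_from_fractions(fractions: np.ndarray, focal: int) -> float | None:
    """Z = (f_focal - mean(f_bg)) / sd(f_bg), sample sd over the background.

    The background is every overlap length other than the focal one.
    Returns None when the background sd is zero (degenerate distribution).
    """
    f = np.asarray(fractions, dtype=float)
    if not (1 <= focal <= len(f)):
        raise ValueError("focal length outside distribution range")
    bg = np.delete(f, focal - 1)
    if len(bg) < 3:
        raise ValueError("fewer than 3 background overlap lengths")
    sd = float(bg.std(ddof=1))
    if sd == 0.0:
        return None
    return float((f[focal - 1] - bg.mean()) / sd)


def zscore(dist: OverlapDistribution, focal: int = 10) -> float | None:
    """Standardized excess of the focal overlap fraction (see
    :func:`zscore_from_fractions`)."""
    if dist.total == 0:
        raise ValueError("no overlapping pairs")
    return zscore_from_fractions(dist.fractions, focal)


@dataclass
class PingPongResult:
    distribution: OverlapDistribution
    z10: float | None
    n_sense: int
    n_antisense: int


def pingpong_signature(
    pirnas: PiRNASet | Sequence[SequenceRecord],
    te_transcripts: Sequence[SequenceRecord],
    sense_k: int = 0,
    antisense_k: int = 3,
    max_overlap: int = 25,
    focal: int = 10,
    index: TargetIndex | None = None,
) -> PingPongResult:
    """End-to-end signature: map, build the overlap distribution, score."""
    sense, antisense = map_pirnas_to_tes(
        pirnas, te_transcripts, sense_k, antisense_k, index=index
    )
    dist = overlap_distribution(sense, antisense, max_overlap)
    z = zscore(dist, focal) if dist.total > 0 else None
    return PingPongResult(dist, z, len(sense), len(antisense))


def pingpong_pairs_by_superfamily(
    sense_hits: Sequence[MappingHit],
    antisense_hits: Sequence[MappingHit],
    annotation: Mapping[str, AnnotationLabel],
    focal: int = 10,
) -> dict[str, int]:
    """Ping-pong pair counts (overlap exactly ``focal``) per TE superfamily."""
    by_target_s: dict[str, list[int]] = {}
    by_target_a: dict[str, list[int]] = {}
    for h in sense_hits:
        by_target_s.setdefault(h.target_id, []).append(h.offset)
    for h in antisense_hits:
        by_target_a.setdefault(h.target_id, []).append(h.offset + h.length - 1)
    out: dict[str, int] = {}
    d = focal - 1
    for target, s_pos in by_target_s.items():
        a_pos = by_target_a.get(target)
        if not a_pos:
            continue
        hi = max(max(s_pos), max(a_pos)) + 1
        cs = np.bincount(s_pos, minlength=hi)
        ca = np.bincount(a_pos, minlength=hi)
        n = int(np.dot(ca[d:], cs[: hi - d]))
        if n:
            label = annotation.get(target, AnnotationLabel()).superfamily
            out[label] = out.get(label, 0) + n
    return out


def rpm_by_superfamily(
    hits: Sequence[MappingHit],
    annotation: Mapping[str, AnnotationLabel],
    library_size: int,
) -> dict[str, float]:
    """piRNA reads-per-million per TE superfamily, for one individual.

    ``library_size`` is the individual's total filtered small-RNA read
    count.  A read contributes once per target it maps to (count once per
    read per target), then per-contig RPMs are summed within superfamily.
    """
    if library_size <= 0:
        raise ValueError("library size must be positive")
    per_target: dict[str, set[str]] = {}
    for h in hits:
        per_target.setdefault(h.target_id, set()).add(h.read_id)
    out: dict[str, float] = {}
    for target, read_ids in per_target.items():
        label = annotation.get(target, AnnotationLabel()).superfamily
        out[label] = out.get(label, 0.0) + len(read_ids) / library_size * 1e6
    return out


def summarize_pirna_by_superfamily(
    per_individual: Mapping[str, Mapping[str, float]],
    sex_of: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Average per-superfamily RPM across same-sex individuals.

    ``per_individual`` maps individual id -> {superfamily: RPM}; returns
    {sex: {superfamily: mean RPM}}.
    """
    by_sex: dict[str, list[Mapping[str, float]]] = {}
    for ind, rpms in per_individual.items():
        if ind not in sex_of:
            raise ValueError(f"individual {ind!r} has no recorded sex")
        by_sex.setdefault(sex_of[ind], []).append(rpms)
    out: dict[str, dict[str, float]] = {}
    for sex, tables in by_sex.items():
        labels = {label for t in tables for label in t}
        out[sex] = {
            label: float(np.mean([t.get(label, 0.0) for t in tables]))
            for label in labels
        }
    return out
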