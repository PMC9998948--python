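"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the study conditions of a low-coverage shotgun
survey of a TE-rich gonad: a genome of reads drawn from TE superfamilies
with configured proportions and per-copy divergence distributions; gonadal
transcript pools with sex-biased TE expression; small-RNA pools with a
piRNA length mode near 29 nt, a tunable 5'-U bias, a tunable fraction of
sense/antisense pairs with an exact 10-nt 5'-5' overlap, plus miRNA and
rRNA/mitochondrial contaminant reads; and per-species silencing-pathway
expression tables.  Mutation is substitution-only, so downstream divergence
(a Hamming mismatch fraction) has an exact planted oracle.  Identical seeds
give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationLabel, ExpressionTable, SequenceRecord, revcomp
from .landscape import RepeatLibrary

__all__ = [
    "PointMass",
    "Exponential",
    "NormalMixture",
    "SuperfamilySpec",
    "GenomeSimConfig",
    "SimulatedGenome",
    "TranscriptSpec",
    "TranscriptomeSimConfig",
    "SimulatedTranscriptome",
    "SmallRNASimConfig",
    "SimulatedSmallRNA",
    "SpeciesSpec",
    "PanelConfig",
    "SimulatedPanel",
    "simulate_repeat_genome",
    "simulate_transcriptome",
    "simulate_small_rna",
    "simulate_species_panel",
    "random_sequence",
    "synthetic_mirna_reference",
    "synthetic_contaminants",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# divergence models

@dataclass(frozen=True)
class PointMass:
    """Every copy diverged by exactly ``value`` percent."""

    value: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.full(n, self.value)

    def cdf(self, x):
        return (np.asarray(x, dtype=float) >= self.value).astype(float)


@dataclass(frozen=True)
class Exponential:
    """Exponential per-copy divergence (percent) — a steadily active family."""

    mean: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.exponential(self.mean, size=n)

    def cdf(self, x):
        return 1.0 - np.exp(-np.asarray(x, dtype=float) / self.mean)


@dataclass(frozen=True)
class NormalMixture:
    """Mixture of normals (percent) — past amplification bursts."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        vals = rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])
        return np.clip(vals, 0.0, None)


# ---------------------------------------------------------------------------
# repeat genome

@dataclass
class SuperfamilySpec:
    label: AnnotationLabel
    consensus_length: int
    proportion: float
    divergence: PointMass | Exponential | NormalMixture


@dataclass
class GenomeSimConfig:
    superfamilies: list[SuperfamilySpec]
    read_length: int = 150
    total_bp: int = 3_000_000
    unknown_proportion: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(s.proportion for s in self.superfamilies) + self.unknown_proportion
        if total > 1.0 + 1e-9:
            raise ValueError(f"proportions sum to {total:.3f} > 1")
        if self.read_length <= 0 or self.total_bp <= 0:
            raise ValueError("lengths must be positive")
        for s in self.superfamilies:
            if s.consensus_length < self.read_length:
                raise ValueError(
                    f"{s.label.superfamily}: consensus shorter than read length"
                )


@dataclass
class GenomeTruth:
    proportions: dict[str, float]          # configured per-superfamily proportion
    read_source: dict[str, str | None]     # read id -> superfamily (None = background)
    divergence_drawn: dict[str, float]     # per-copy divergence as drawn (percent)
    divergence_realized: dict[str, float]  # mutated fraction actually planted (percent)


@dataclass
class SimulatedGenome:
    reads: list[SequenceRecord]
    library: RepeatLibrary
    truth: GenomeTruth


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    if n_mut == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(len(arr), size=n_mut, replace=False)
    # substitute with one of the three other bases
    shift = rng.integers(1, 4, size=n_mut)
    idx = np.searchsorted(_BASES, arr[pos])
    arr[pos] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode()


def simulate_repeat_genome(config: GenomeSimConfig) -> SimulatedGenome:
    """Shotgun reads as mutated fragments of superfamily consensuses.

    Each TE-derived read is a uniform fragment of its superfamily consensus
    with exactly ``round(d/100 * L)`` substitutions, where d is the per-copy
    divergence drawn from the configured distribution; the remainder of the
    genome is random background sequence.
    """
    rng = np.random.default_rng(config.seed)
    specs = list(config.superfamilies)
    if config.unknown_proportion > 0:
        specs.append(
            SuperfamilySpec(AnnotationLabel(), 2000, config.unknown_proportion, Exponential(5.0))
        )
    consensuses = [
        SequenceRecord(f"{s.label.superfamily}_cons_{i}", random_sequence(rng, s.consensus_length))
        for i, s in enumerate(specs)
    ]
    library = RepeatLibrary(consensuses, [s.label for s in specs])
    L = config.read_length
    n_reads = config.total_bp // L
    probs = [s.proportion for s in specs]
    probs.append(max(0.0, 1.0 - sum(probs)))
    counts = rng.multinomial(n_reads, probs)
    reads: list[SequenceRecord] = []
    src: dict[str, str | None] = {}
    drawn: dict[str, float] = {}
    realized: dict[str, float] = {}
    rid = 0
    for spec, cons, n in zip(specs, consensuses, counts[:-1]):
        divs = spec.divergence.sample(rng, int(n))
        starts = rng.integers(0, len(cons.seq) - L + 1, size=int(n))
        for d, start in zip(divs, starts):
            n_mut = min(int(round(d / 100.0 * L)), L)
            seq = _mutate(rng, cons.seq[start : start + L], n_mut)
            name = f"r{rid:07d}"
            reads.append(SequenceRecord(name, seq))
            src[name] = spec.label.superfamily
            drawn[name] = float(d)
            realized[name] = n_mut / L * 100.0
            rid += 1
    for _ in range(int(counts[-1])):
        name = f"r{rid:07d}"
        reads.append(SequenceRecord(name, random_sequence(rng, L)))
        src[name] = None
        rid += 1
    truth = GenomeTruth(
        {s.label.superfamily: s.proportion for s in specs}, src, drawn, realized
    )
    return SimulatedGenome(reads, library, truth)


# ---------------------------------------------------------------------------
# transcriptome

@dataclass
class TranscriptSpec:
    id: str
    length: int
    superfamily: str | None = None   # None marks an endogenous gene
    expression: float = 1.0          # relative molar expression
    male_multiplier: float = 1.0

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"transcript {self.id}: nonpositive length")
        if self.expression < 0:
            raise ValueError(f"transcript {self.id}: negative expression")


@dataclass
class TranscriptomeSimConfig:
    transcripts: list[TranscriptSpec]
    replicates_per_sex: int = 3
    reads_per_replicate: int = 1_000_000
    seed: int = 0


@dataclass
class SimulatedTranscriptome:
    transcripts: list[SequenceRecord]
    annotation: dict[str, str]          # transcript id -> superfamily (TEs only)
    lengths: dict[str, int]
    counts: ExpressionTable
    sex_of: dict[str, str]
    expected_tpm: pd.DataFrame          # transcript x {"female", "male"}


def simulate_transcriptome(config: TranscriptomeSimConfig) -> SimulatedTranscriptome:
    """Replicate count tables drawn multinomially from planted expression.

    Read counts are proportional to expression x transcript length (reads,
    not molecules), so length-normalized TPM recovers the planted molar
    expression shares; ``expected_tpm`` holds the exact expectation per sex.
    """
    rng = np.random.default_rng(config.seed)
    specs = config.transcripts
    ids = [t.id for t in specs]
    lengths = np.array([t.length for t in specs], dtype=float)
    records = [SequenceRecord(t.id, random_sequence(rng, t.length)) for t in specs]
    expr = np.array([t.expression for t in specs], dtype=float)
    mult = np.array([t.male_multiplier for t in specs], dtype=float)
    cols = {}
    sex_of = {}
    expected = {}
    for sex, m in (("female", np.ones_like(mult)), ("male", mult)):
        e = expr * m
        if e.sum() == 0:
            raise ValueError("all expression zero")
        weights = e * lengths
        p = weights / weights.sum()
        expected[sex] = e / e.sum() * 1e6
        for rep in range(config.replicates_per_sex):
            sample = f"{sex}_{rep + 1}"
            cols[sample] = rng.multinomial(config.reads_per_replicate, p)
            sex_of[sample] = sex
    counts = ExpressionTable(pd.DataFrame(cols, index=ids), unit="count")
    annotation = {t.id: t.superfamily for t in specs if t.superfamily is not None}
    return SimulatedTranscriptome(
        records,
        annotation,
        {t.id: t.length for t in specs},
        counts,
        sex_of,
        pd.DataFrame(expected, index=ids),
    )


# ---------------------------------------------------------------------------
# small RNA pool

@dataclass
class SmallRNASimConfig:
    """Small-RNA pool with a planted ping-pong signal.

    Antisense "primary" piRNAs are drawn from TE transcripts with first-
    nucleotide U probability ``u_prob``; with probability ``rho`` each gets a
    sense partner whose 5' end makes an exact 10-nt 5'-5' overlap.  The
    remaining sense piRNAs, miRNA copies, and contaminant fragments fill the
    pool per the configured weights.
    """

    transcripts: Sequence[SequenceRecord]
    n_reads: int = 20_000
    transcript_weights: Sequence[float] | None = None
    length_mode: int = 29
    length_sd: float = 1.0
    min_pirna_len: int = 25
    max_pirna_len: int = 30
    u_prob: float = 0.9
    rho: float = 0.0
    antisense_fraction: float = 0.5
    peak22_weight: float = 0.0
    mirna_reference: Sequence[SequenceRecord] = ()
    mirna_weight: float = 0.0
    contaminant_reference: Sequence[SequenceRecord] = ()
    contaminant_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError("empty transcript set")
        w = self.peak22_weight + self.mirna_weight + self.contaminant_weight
        if w > 1.0 + 1e-9:
            raise ValueError("category weights exceed 1")
        for p in (self.u_prob, self.rho, self.antisense_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.mirna_weight > 0 and not self.mirna_reference:
            raise ValueError("mirna_weight > 0 requires a reference")
        if self.contaminant_weight > 0 and not self.contaminant_reference:
            raise ValueError("contaminant_weight > 0 requires a reference")


@dataclass
class SmallRNATruth:
    category: dict[str, str]        # read id -> pirna_sense | pirna_antisense |
                                    #   pingpong_partner | mirna | contaminant
    partner_of: dict[str, str]      # partner read id -> its antisense primary
    u_prob: float
    rho: float
    source_transcript: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedSmallRNA:
    reads: list[SequenceRecord]
    truth: SmallRNATruth


def _length_probs(cfg: SmallRNASimConfig) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.arange(cfg.min_pirna_len, cfg.max_pirna_len + 1)
    p = np.exp(-0.5 * ((lengths - cfg.length_mode) / max(cfg.length_sd, 1e-9)) ** 2)
    return lengths, p / p.sum()


def simulate_small_rna(config: SmallRNASimConfig) -> SimulatedSmallRNA:
    rng = np.random.default_rng(config.seed)
    transcripts = list(config.transcripts)
    if config.transcript_weights is not None:
        tw = np.asarray(config.transcript_weights, dtype=float)
        if len(tw) != len(transcripts) or (tw < 0).any() or tw.sum() == 0:
            raise ValueError("bad transcript weights")
    else:
        tw = np.ones(len(transcripts))
    tw = tw / tw.sum()
    lengths, lp = _length_probs(config)
    max_len = int(lengths.max())
    for t in transcripts:
        if len(t.seq) < max_len + 21:
            raise ValueError(f"transcript {t.id} too short for partner placement")

    w_pirna = 1.0 - config.peak22_weight - config.mirna_weight - config.contaminant_weight
    n_cat = rng.multinomial(
        config.n_reads,
        [w_pirna, config.peak22_weight, config.mirna_weight, config.contaminant_weight],
    )
    n_pirna, n_peak22, n_mirna, n_contam = (int(x) for x in n_cat)
    n_anti = int(rng.binomial(n_pirna, config.antisense_fraction))
    n_sense_budget = n_pirna - n_anti

    reads: list[SequenceRecord] = []
    category: dict[str, str] = {}
    partner_of: dict[str, str] = {}
    source: dict[str, str] = {}
    rid = 0

    def emit(seq: str, cat: str, tid: str | None = None) -> str:
        nonlocal rid
        name = f"s{rid:07d}"
        reads.append(SequenceRecord(name, seq, qual="I" * len(seq)))
        category[name] = cat
        if tid is not None:
            source[name] = tid
        rid += 1
        return name

    n_partners = 0
    for _ in range(n_anti):
        ti = int(rng.choice(len(transcripts), p=tw))
        t = transcripts[ti]
        L = int(rng.choice(lengths, p=lp))
        # keep the 5' end where a partner with a 10-nt overlap always fits
        a = int(rng.integers(max(L - 1, 9), len(t.seq) - max_len + 9))
        seq = revcomp(t.seq[a - L + 1 : a + 1])
        if rng.random() < config.u_prob:
            seq = "T" + seq[1:]
        anti_name = emit(seq, "pirna_antisense", t.id)
        if n_partners < n_sense_budget and rng.random() < config.rho:
            L2 = int(rng.choice(lengths, p=lp))
            s = a - 9  # overlap = a - s + 1 = 10
            pname = emit(t.seq[s : s + L2], "pingpong_partner", t.id)
            partner_of[pname] = anti_name
            n_partners += 1
    for _ in range(n_sense_budget - n_partners):
        ti = int(rng.choice(len(transcripts), p=tw))
        t = transcripts[ti]
        L = int(rng.choice(lengths, p=lp))
        s = int(rng.integers(0, len(t.seq) - L + 1))
        emit(t.seq[s : s + L], "pirna_sense", t.id)
    for _ in range(n_peak22):
        ti = int(rng.choice(len(transcripts), p=tw))
        t = transcripts[ti]
        s = int(rng.integers(0, len(t.seq) - 22 + 1))
        emit(t.seq[s : s + 22], "pirna_sense", t.id)
    for _ in range(n_mirna):
        m = config.mirna_reference[int(rng.integers(len(config.mirna_reference)))]
        emit(m.seq, "mirna")
    for _ in range(n_contam):
        c = config.contaminant_reference[int(rng.integers(len(config.contaminant_reference)))]
        L = int(rng.integers(18, min(33, len(c.seq) + 1)))
        s = int(rng.integers(0, len(c.seq) - L + 1))
        emit(c.seq[s : s + L], "contaminant")
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = SmallRNATruth(category, partner_of, config.u_prob, config.rho, source)
    return SimulatedSmallRNA(reads, truth)


def synthetic_mirna_reference(
    n: int = 50, length: int = 22, seed: int = 7_122_022
) -> list[SequenceRecord]:
    """A bundled synthetic miRNA reference: random distinct 22-mers."""
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out = []
    while len(out) < n:
        s = random_sequence(rng, length)
        if s not in seen:
            seen.add(s)
            out.append(SequenceRecord(f"mir-{len(out) + 1}", s))
    return out


def synthetic_contaminants(seed: int = 24_021_960) -> list[SequenceRecord]:
    """Synthetic stand-ins for the mitochondrial genome and rRNA set."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord("mito", random_sequence(rng, 4000)),
        SequenceRecord("rRNA_18S", random_sequence(rng, 1800)),
        SequenceRecord("rRNA_28S", random_sequence(rng, 3500)),
    ]


# ---------------------------------------------------------------------------
# cross-species pathway panel

@dataclass
class SpeciesSpec:
    name: str
    genome_size_gb: float
    ratio_pirna: float = 1.0
    ratio_repressive: float = 0.5
    ratio_trim28: float = 0.1
    missing_genes: Sequence[str] = ()


@dataclass
class PanelConfig:
    species: list[SpeciesSpec]
    gene_sets: "object"               # PathwayGeneSets
    noise_sd: float = 0.2             # sd of log-normal per-gene noise
    replicates_per_sex: int = 2
    mirna_gene_mean: float = 100.0
    seed: int = 0


@dataclass
class SimulatedPanel:
    tables: dict[str, ExpressionTable]
    genome_sizes: dict[str, float]
    sex_of: dict[str, str]
    expected_ratios: pd.DataFrame     # species x {ratio_pirna, ratio_repressive, ratio_trim28}


def simulate_species_panel(config: PanelConfig) -> SimulatedPanel:
    """Per-species gene x individual TPM tables with planted pathway ratios.

    Every gene's TPM is log-normal around its configured mean with unit
    expectation, so each set's expected summed TPM — and hence each expected
    ratio — equals the configured value; ``noise_sd = 0`` recovers the
    configured ratios exactly.  Genes listed in ``missing_genes`` are absent
    from that species' table, emulating incomplete annotations.
    """
    rng = np.random.default_rng(config.seed)
    gs = config.gene_sets
    mirna_total = len(gs.mirna) * config.mirna_gene_mean
    tables: dict[str, ExpressionTable] = {}
    sex_of: dict[str, str] = {}
    expected = {}
    for sp in config.species:
        means = {}
        for g in gs.mirna:
            means[g] = config.mirna_gene_mean
        for g in gs.pirna:
            means[g] = sp.ratio_pirna * mirna_total / len(gs.pirna)
        for g in gs.repressive:
            means[g] = sp.ratio_repressive * mirna_total / len(gs.repressive)
        for g in gs.bridge:
            means[g] = sp.ratio_trim28 * mirna_total / len(gs.bridge)
        for g in sp.missing_genes:
            means.pop(g, None)
        genes = sorted(means)
        mu = np.array([means[g] for g in genes])
        cols = {}
        for sex in ("female", "male"):
            for rep in range(config.replicates_per_sex):
                ind = f"{sp.name}_{sex[0]}{rep + 1}"
                if config.noise_sd > 0:
                    noise = rng.lognormal(
                        -config.noise_sd**2 / 2, config.noise_sd, size=len(genes)
                    )
                else:
                    noise = np.ones(len(genes))
                cols[ind] = mu * noise
                sex_of[ind] = sex
        tables[sp.name] = ExpressionTable(pd.DataFrame(cols, index=genes), unit="TPM")
        expected[sp.name] = {
            "ratio_pirna": sp.ratio_pirna,
            "ratio_repressive": sp.ratio_repressive,
            "ratio_trim28": sp.ratio_trim28,
        }
    return SimulatedPanel(
        tables,
        {sp.name: sp.genome_size_gb for sp in config.species},
        sex_of,
        pd.DataFrame(expected).T,
    )
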