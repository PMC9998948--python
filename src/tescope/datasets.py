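"""Published repeat-survey summary for the Siberian salamander.

*Ranodon sibiricus* carries a ~21 Gb genome.  The published low-coverage
shotgun survey of that genome reports, per TE superfamily, the percent of
the genome masked (under repeat libraries that include or exclude
unclassified repeats) and summed gonadal expression (TPM) per sex, along
with per-mining-method repeat-contig counts and a transcriptome annotation
summary.  Those printed values are bundled here so the landscape,
diversity, and regression operations can be exercised on real survey data
without any download.

All functions recompute derived quantities (shares, coverages, diversity
inputs) from the raw printed counts at call time.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "superfamily_survey",
    "mining_method_counts",
    "mining_method_shares",
    "known_te_share",
    "transcriptome_summary",
    "expression_fractions",
    "sequencing_coverage_percent",
    "named_superfamily_percents",
    "GENOME_SIZE_GB",
    "SURVEY_TOTAL_BP",
]

#: Haploid genome size used by the survey (average of independent estimates).
GENOME_SIZE_GB = 21.3

#: Total base pairs of filtered, trimmed shotgun reads in the survey.
SURVEY_TOTAL_BP = 2_314_096_923

# Per-superfamily summary: percent of genome masked with the repeat library
# including / excluding unclassified repeats, and summed TPM per sex.  None
# marks quantities the survey could not estimate (superfamily absent from
# the corresponding dataset).  Derivative categories (TRIM/LARD/MITE) and
# order-level "unknown" rows are flagged so diversity analyses can exclude
# them.
_ROWS = [
    # order, superfamily, pct_incl, pct_excl, tpm_ovary, tpm_testis, named
    ("LTR", "Gypsy", 3.85, 6.50, 827, 3024, True),
    ("LTR", "ERV", 0.41, 0.43, 392, 694, True),
    ("LTR", "Copia", 0.10, 0.25, 31, 26, True),
    ("LTR", "Bel-Pao", 0.05, 0.05, None, None, True),
    ("LTR", "Retrovirus", None, None, 1, 10, True),
    ("LTR", "THE1", None, None, None, None, True),
    ("LTR", "unknown-LTR", None, None, None, None, False),
    ("DIRS", "DIRS", 4.44, 5.95, 5427, 11962, True),
    ("PLE", "Penelope", 0.09, 0.12, 123, 352, True),
    ("LINE", "Jockey", 9.69, 12.12, 6206, 15535, True),
    ("LINE", "L1", 5.04, 6.62, 2954, 7610, True),
    ("LINE", "RTE", 0.12, 0.24, 130, 360, True),
    ("LINE", "I", 0.09, 0.17, 42, 125, True),
    ("LINE", "R2", None, None, None, 1, True),
    ("LINE", "unknown-LINE", 0.39, 1.89, None, None, False),
    ("SINE", "5S", 0.23, 0.18, 5, 1, True),
    ("SINE", "7SL", None, None, 1, None, True),
    ("SINE", "tRNA", None, None, None, None, True),
    ("SINE", "unknown-SINE", 0.45, 3.42, 2901, 2471, False),
    ("TRIM", "TRIM", 3.80, 9.76, 1651, 5847, False),
    ("LARD", "LARD", 0.15, 0.73, 515, 2643, False),
    ("TIR", "PIF-Harbinger", 2.98, 4.22, 575, 1359, True),
    ("TIR", "hAT", 1.15, 1.12, 83, 26, True),
    ("TIR", "Tc1-Mariner", 0.18, 0.63, 58, 87, True),
    ("TIR", "PiggyBac", 0.05, 0.08, 21, 15, True),
    ("TIR", "MuDR", None, None, 4, 10, True),
    ("TIR", "CACTA", None, None, 2, 1, True),
    ("TIR", "ISL2EU", None, None, 18, 16, True),
    ("TIR", "Ginger", None, None, 10, 6, True),
    ("TIR", "Academ", None, None, 5, 8, True),
    ("TIR", "P", None, None, 1, 1, True),
    ("TIR", "unknown-TIR", 0.33, 1.46, None, None, False),
    ("MITE", "MITE", 0.56, 4.07, 465, 1188, False),
    ("Maverick", "Maverick", 0.05, 0.05, 44, 762, True),
    ("Helitron", "Helitron", 0.18, 0.48, 2, 10, True),
]


def superfamily_survey() -> pd.DataFrame:
    """Per-superfamily genomic abundance and gonadal expression.

    Columns: ``order``, ``pct_incl_unknown``, ``pct_excl_unknown`` (percent
    of genome masked with the library including/excluding unclassified
    repeats), ``tpm_ovary``, ``tpm_testis`` (summed TPM per sex), and
    ``named`` (True for named superfamilies, False for derivative or
    order-level-only categories).  Index: superfamily label.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "order", "superfamily", "pct_incl_unknown", "pct_excl_unknown",
            "tpm_ovary", "tpm_testis", "named",
        ],
    ).set_index("superfamily")
    for col in ("pct_incl_unknown", "pct_excl_unknown", "tpm_ovary", "tpm_testis"):
        df[col] = df[col].astype("float64")
    return df


def named_superfamily_percents(exclude_unknown_library: bool = True) -> pd.Series:
    """Percent-of-genome for the named superfamilies with numeric estimates.

    This is the abundance vector that feeds the genomic TE community
    diversity indices: derivative categories and order-level-only rows are
    excluded, as are superfamilies the masking could not quantify.
    """
    df = superfamily_survey()
    col = "pct_excl_unknown" if exclude_unknown_library else "pct_incl_unknown"
    s = df.loc[df["named"], col].dropna()
    return s


def mining_method_counts() -> pd.Series:
    """Repeat contigs (>=100 bp, deduplicated) found per mining program."""
    return pd.Series(
        {
            "RepeatMasker": 75_381,
            "TE-HMMER": 3_108,
            "HelSearch": 1,
            "LTRharvest": 84,
            "MGEScan-non-LTR": 0,
            "MITE-Hunter": 7,
            "SINE-finder": 48,
            "TEdenovo": 306,
            "RepeatScout": 3_671,
            "dnaPipeTE": 24_090,
            "RepeatModeler": 3_213,
        }
    )


def mining_method_shares() -> pd.Series:
    """Percent of all mined repeat contigs contributed by each program."""
    counts = mining_method_counts()
    return counts / counts.sum() * 100.0


#: Repeat contigs classified as known TEs, out of all mined repeat contigs.
_KNOWN_TE_CONTIGS = 54_221
_TOTAL_REPEAT_CONTIGS = 109_909


def known_te_share() -> float:
    """Percent of mined repeat contigs classified as known TEs."""
    return _KNOWN_TE_CONTIGS / _TOTAL_REPEAT_CONTIGS * 100.0


def transcriptome_summary() -> pd.DataFrame:
    """Gonad transcriptome annotation-category summary (contigs, summed TPM)."""
    rows = [
        ("endogenous_gene", 51_647, 678_366, 58_041, 513_783),
        ("autonomous_te", 26_358, 17_890, 41_421, 43_694),
        ("non_autonomous_te", 1_700, 5_538, 2_348, 12_151),
        ("gene_autonomous_te", 722, 2_618, 1_001, 5_748),
        ("gene_non_autonomous_te", 168, 2_779, 189, 1_073),
        ("unannotated", 215_508, 292_828, 334_533, 423_550),
    ]
    return pd.DataFrame(
        rows,
        columns=["category", "contigs_ovary", "tpm_ovary", "contigs_testis", "tpm_testis"],
    ).set_index("category")


def expression_fractions() -> pd.DataFrame:
    """Percent of total gonadal expression per annotation category and sex."""
    df = transcriptome_summary()
    return pd.DataFrame(
        {
            "ovary": df["tpm_ovary"] / df["tpm_ovary"].sum() * 100.0,
            "testis": df["tpm_testis"] / df["tpm_testis"].sum() * 100.0,
        }
    )


def sequencing_coverage_percent(
    total_bp: int = SURVEY_TOTAL_BP, genome_size_gb: float = GENOME_SIZE_GB
) -> float:
    """Shotgun sequencing coverage as percent of the haploid genome."""
    return total_bp / (genome_size_gb * 1e9) * 100.0
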