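"""TPM aggregation, sex-bias statistics, and silencing-pathway ratios.

TPM here uses the transcript length itself as the effective length: per
sample, rate_i = count_i / length_i and TPM_i = rate_i / sum(rates) * 1e6,
so every non-degenerate column sums to one million.  Pathway activity per
individual is summarized as the ratio of summed TPM of a silencing gene set
(piRNA processing, repressive chromatin machinery, or the TRIM28 bridge) to
summed TPM of the miRNA-processing set, a normalization that cancels
per-library scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import ExpressionTable, get_logger

__all__ = [
    "PathwayGeneSets",
    "PathwayRatioResult",
    "RegressionResult",
    "tpm",
    "superfamily_expression",
    "abundance_expression_regression",
    "sex_bias_ttest",
    "load_pathway_gene_sets",
    "pathway_ratios",
    "ratio_vs_genome_size",
]


def tpm(counts: ExpressionTable, lengths: Mapping[str, float] | pd.Series) -> ExpressionTable:
    """Transcripts-per-million from raw counts and transcript lengths."""
    if counts.unit != "count":
        raise ValueError("tpm() expects a count table")
    lengths = pd.Series(lengths).reindex(counts.values.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise ValueError(f"missing lengths for rows {missing}")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rates = counts.values.div(lengths, axis=0)
    colsum = rates.sum(axis=0)
    zero_cols = colsum[colsum == 0].index
    if len(zero_cols):
        get_logger().warning("tpm: all-zero columns %s", list(zero_cols))
        colsum = colsum.replace(0, np.nan)
    out = rates.div(colsum, axis=1).fillna(0.0) * 1e6
    return ExpressionTable(out, unit="TPM")


def superfamily_expression(
    table: ExpressionTable,
    annotation: Mapping[str, str],
    sex_of: Mapping[str, str],
) -> pd.DataFrame:
    """Summed mean TPM per (superfamily, sex).

    Per transcript, TPM is averaged across same-sex replicates; the averages
    are then summed over all transcripts annotated to each superfamily.
    Transcripts absent from ``annotation`` are excluded.
    """
    if table.unit != "TPM":
        raise ValueError("expects a TPM table")
    for sample in table.values.columns:
        if sample not in sex_of:
            raise ValueError(f"sample {sample!r} has no recorded sex")
    df = table.values
    rows = {}
    for sex in sorted(set(sex_of.values())):
        samples = [s for s in df.columns if sex_of[s] == sex]
        mean_tpm = df[samples].mean(axis=1)
        sums: dict[str, float] = {}
        for transcript, value in mean_tpm.items():
            label = annotation.get(transcript)
            if label is None:
                continue
            sums[label] = sums.get(label, 0.0) + float(value)
        rows[sex] = sums
    return pd.DataFrame(rows).fillna(0.0).sort_index()


@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    p: float
    n: int
    stderr: float = float("nan")

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Confidence interval for the slope (t distribution, n-2 df)."""
        if self.n < 3 or not np.isfinite(self.stderr):
            raise ValueError("CI requires n >= 3 and a finite stderr")
        tcrit = stats.t.ppf(0.5 + level / 2, self.n - 2)
        return (self.slope - tcrit * self.stderr, self.slope + tcrit * self.stderr)


def abundance_expression_regression(
    genomic_percent: Mapping[str, float],
    expression_tpm: Mapping[str, float],
    log_transform: bool = True,
) -> RegressionResult:
    """OLS of expression on genomic abundance, log10 both axes by default.

    Superfamilies with a nonpositive value on either axis are excluded with
    a warning; at least 3 must remain.
    """
    shared = sorted(set(genomic_percent) & set(expression_tpm))
    pairs = [(genomic_percent[k], expression_tpm[k]) for k in shared]
    kept = [(x, y) for x, y in pairs if x > 0 and y > 0]
    if len(kept) < len(pairs):
        get_logger().warning(
            "abundance_expression_regression: excluded %d nonpositive pairs",
            len(pairs) - len(kept),
        )
    if len(kept) < 3:
        raise ValueError("need >= 3 superfamilies with positive values")
    x = np.array([p[0] for p in kept])
    y = np.array([p[1] for p in kept])
    if log_transform:
        x, y = np.log10(x), np.log10(y)
    res = stats.linregress(x, y)
    return RegressionResult(
        r=float(res.rvalue), slope=float(res.slope), intercept=float(res.intercept),
        p=float(res.pvalue), n=len(kept), stderr=float(res.stderr),
    )


def sex_bias_ttest(
    mean_tpm_by_sex: pd.DataFrame,
    annotation: Mapping[str, str],
    min_transcripts: int = 10,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Welch's t-test of male vs female per-transcript expression, by superfamily.

    ``mean_tpm_by_sex`` has one row per transcript and columns "female" and
    "male" holding the mean TPM across same-sex replicates.  Values are
    log10(TPM + 1)-transformed by default.  Superfamilies represented by
    fewer than ``min_transcripts`` transcripts are skipped.
    """
    for col in ("female", "male"):
        if col not in mean_tpm_by_sex.columns:
            raise ValueError(f"missing column {col!r}")
    groups: dict[str, list[str]] = {}
    for transcript in mean_tpm_by_sex.index:
        label = annotation.get(transcript)
        if label is not None:
            groups.setdefault(label, []).append(transcript)
    rows = []
    for label, members in sorted(groups.items()):
        if len(members) < min_transcripts:
            continue
        f = mean_tpm_by_sex.loc[members, "female"].to_numpy(dtype=float)
        m = mean_tpm_by_sex.loc[members, "male"].to_numpy(dtype=float)
        if log_transform:
            f, m = np.log10(f + 1), np.log10(m + 1)
        if np.var(f) == 0 and np.var(m) == 0:
            t, p = (0.0, 1.0) if np.mean(f) == np.mean(m) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(m, f, equal_var=False)
        rows.append({"superfamily": label, "n_transcripts": len(members),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("superfamily") if rows else pd.DataFrame(
        columns=["n_transcripts", "t", "p"]
    )


# ---------------------------------------------------------------------------
# silencing-pathway expression ratios

@dataclass
class PathwayGeneSets:
    """Disjoint uppercase gene sets for the three silencing proxies."""

    pirna: list[str]
    repressive: list[str]
    bridge: list[str]
    mirna: list[str]

    def __post_init__(self):
        sets = [set(self.pirna), set(self.repressive), set(self.bridge), set(self.mirna)]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError(f"gene sets overlap: {sorted(a & b)}")

    def restricted_to(self, genes: set[str]) -> "PathwayGeneSets":
        return PathwayGeneSets(
            [g for g in self.pirna if g in genes],
            [g for g in self.repressive if g in genes],
            [g for g in self.bridge if g in genes],
            [g for g in self.mirna if g in genes],
        )


def load_pathway_gene_sets() -> PathwayGeneSets:
    """The bundled piRNA / repressive-chromatin / TRIM28 / miRNA gene sets."""
    text = resources.files("tescope").joinpath("data/pathway_genes.yaml").read_text()
    raw = yaml.safe_load(text)
    return PathwayGeneSets(raw["pirna"], raw["repressive"], raw["bridge"], raw["mirna"])


@dataclass
class PathwayRatioResult:
    individual: str
    species: str
    sex: str | None
    ratio_pirna: float | None
    ratio_repressive: float | None
    ratio_trim28: float | None
    genome_size_gb: float | None


def _set_sum(col: pd.Series, genes: Sequence[str]) -> float:
    present = [g for g in genes if g in col.index]
    return float(col.loc[present].sum())


def pathway_ratios(
    tables: Mapping[str, ExpressionTable],
    gene_sets: PathwayGeneSets,
    genome_sizes: Mapping[str, float] | None = None,
    sex_of: Mapping[str, str] | None = None,
    conservative: bool = False,
) -> list[PathwayRatioResult]:
    """Per-individual silencing-to-miRNA pathway expression ratios.

    ``tables`` maps species -> gene x individual TPM table.  In the default
    (full-set) mode, genes missing from a species' table contribute zero to
    the sums, emulating incomplete annotations.  In conservative mode all
    sets are first restricted to genes present in every species of the
    panel, so no individual's ratio is distorted by a missing gene.
    Individuals whose miRNA-set sum is zero get None ratios.
    """
    sets = gene_sets
    if conservative:
        shared: set[str] | None = None
        for table in tables.values():
            genes = set(table.values.index)
            shared = genes if shared is None else shared & genes
        sets = gene_sets.restricted_to(shared or set())
    if not sets.mirna:
        raise ValueError("miRNA gene set is empty after restriction")
    results = []
    for species, table in tables.items():
        gsize = (genome_sizes or {}).get(species)
        for ind in table.values.columns:
            col = table.values[ind]
            denom = _set_sum(col, sets.mirna)
            if denom == 0:
                get_logger().warning("pathway_ratios: zero miRNA sum for %s", ind)
                r = (None, None, None)
            else:
                r = (
                    _set_sum(col, sets.pirna) / denom,
                    _set_sum(col, sets.repressive) / denom,
                    _set_sum(col, sets.bridge) / denom,
                )
            results.append(
                PathwayRatioResult(
                    individual=str(ind),
                    species=species,
                    sex=(sex_of or {}).get(str(ind)),
                    ratio_pirna=r[0],
                    ratio_repressive=r[1],
                    ratio_trim28=r[2],
                    genome_size_gb=gsize,
                )
            )
    return results


def ratio_vs_genome_size(
    results: Sequence[PathwayRatioResult],
    which: str = "ratio_pirna",
) -> RegressionResult:
    """OLS of a pathway ratio on log10 genome size across the species panel."""
    pts = [
        (r.genome_size_gb, getattr(r, which))
        for r in results
        if r.genome_size_gb is not None and getattr(r, which) is not None
    ]
    species = {r.species for r in results if r.genome_size_gb is not None}
    if len(species) < 4:
        raise ValueError("need at least 4 species")
    x = np.log10([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(y, y[0]):
        return RegressionResult(r=0.0, slope=0.0, intercept=float(y[0]),
                                p=1.0, n=len(pts), stderr=0.0)
    res = stats.linregress(x, y)
    return RegressionResult(
        r=float(res.rvalue), slope=float(res.slope), intercept=float(res.intercept),
        p=float(res.pvalue), n=len(pts), stderr=float(res.stderr),
    )
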