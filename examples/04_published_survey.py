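"""Recompute headline numbers from the bundled salamander repeat survey.

The published low-coverage survey of the ~21 Gb Ranodon sibiricus genome is
shipped as a small dataset; every derived number below is recomputed from
the raw printed counts.
"""

from tescope import datasets
from tescope.expression import abundance_expression_regression
from tescope.landscape import AbundanceVector, diversity_indices

shares = datasets.mining_method_shares()
print("Repeat-mining method shares (% of all mined contigs):")
for method, pct in shares.sort_values(ascending=False).head(4).items():
    print(f"  {method:14s} {pct:5.1f} %")
print(f"Known-TE share of mined contigs: {datasets.known_te_share():.2f} %")
print(f"Shotgun sequencing coverage:     {datasets.sequencing_coverage_percent():.1f} %")

percents = datasets.named_superfamily_percents(exclude_unknown_library=True)
div = diversity_indices(AbundanceVector({k: v * 1e6 for k, v in percents.items()}))
print(f"\nTE community diversity over the {len(percents)} named superfamilies")
print(f"(unknown repeats excluded from the masking library):")
print(f"  Shannon H = {div.H:.2f}")

df = datasets.superfamily_survey()
rows = df[df["named"]].dropna(subset=["pct_excl_unknown", "tpm_ovary", "tpm_testis"])
print(f"\nGenomic abundance vs gonadal expression, log10-log10, "
      f"{len(rows)} superfamilies:")
for sex in ("ovary", "testis"):
    reg = abundance_expression_regression(
        rows["pct_excl_unknown"].to_dict(), rows[f"tpm_{sex}"].to_dict()
    )
    print(f"  {sex:6s} R = {reg.r:.3f}  slope = {reg.slope:.2f}  p = {reg.p:.4f}")
print("\nMore abundant TE superfamilies are expressed more in both sexes: the")
print("genomic TE load and the transcribed TE pool rise together.")
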