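"""Repeat landscape of a simulated genome: masking, proportions, diversity.

Simulates low-coverage shotgun reads from a genome that is 40% Gypsy, 25%
L1, 10% hAT and 25% non-repetitive, masks the reads against the consensus
library, and summarizes the TE community.
"""

from tescope.io import AnnotationLabel
from tescope.landscape import (
    AbundanceVector,
    classify_activity,
    divergence_histogram,
    diversity_indices,
    genome_proportions,
    mask_reads,
)
from tescope.simulate import (
    Exponential,
    GenomeSimConfig,
    NormalMixture,
    SuperfamilySpec,
    simulate_repeat_genome,
)

config = GenomeSimConfig(
    superfamilies=[
        SuperfamilySpec(AnnotationLabel("I", "LTR", "Gypsy"), 3000, 0.40, Exponential(4.0)),
        SuperfamilySpec(AnnotationLabel("I", "LINE", "L1"), 3000, 0.25,
                        NormalMixture((8.0,), (2.0,), (1.0,))),
        SuperfamilySpec(AnnotationLabel("II", "TIR", "hAT"), 2000, 0.10, Exponential(2.0)),
    ],
    read_length=150,
    total_bp=8_000 * 150,
    seed=42,
)
sim = simulate_repeat_genome(config)
hits = mask_reads(sim.reads, sim.library)

abundance = genome_proportions(hits, sim.library.annotation, total_bp=config.total_bp)
print("Masked percent of genome (planted: Gypsy 40, L1 25, hAT 10):")
for label, pct in sorted(abundance.percent_of_genome.items()):
    print(f"  {label:8s} {pct:5.1f} %")

div = diversity_indices(AbundanceVector(abundance.counts))
print(f"\nTE community diversity over {len(div.labels)} superfamilies:")
print(f"  Shannon H      = {div.H:.3f}  (max ln K = {__import__('math').log(len(div.labels)):.3f})")
print(f"  Gini-Simpson   = {div.gini_simpson:.3f}  (probability two masked bp differ in superfamily)")

print("\nAmplification history (1% divergence bins):")
for label, hist in sorted(divergence_histogram(hits, sim.library.annotation).items()):
    call = classify_activity(hist)
    print(
        f"  {label:8s} peak bin {call.argmax_bin:2d}  "
        f"{'ongoing' if call.ongoing else 'quiescent':9s} {call.shape}"
    )
print("\nAn exponential divergence profile peaks near 0% (recent copies), while the")
print("L1 burst planted at ~8% shows up as a past, unimodal amplification peak.")
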