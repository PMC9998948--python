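import numpy as np
import pytest
from scipy import stats

from tescope.expression import load_pathway_gene_sets
from tescope.io import AnnotationLabel, SequenceRecord
from tescope.simulate import (
    Exponential,
    GenomeSimConfig,
    NormalMixture,
    PanelConfig,
    PointMass,
    SmallRNASimConfig,
    SpeciesSpec,
    SuperfamilySpec,
    TranscriptSpec,
    TranscriptomeSimConfig,
    simulate_repeat_genome,
    simulate_small_rna,
    simulate_species_panel,
    simulate_transcriptome,
)

GYPSY = AnnotationLabel("I", "LTR", "Gypsy")
L1 = AnnotationLabel("I", "LINE", "L1")


def _genome_cfg(**kw):
    defaults = dict(
        superfamilies=[
            SuperfamilySpec(GYPSY, 2000, 0.5, Exponential(4.0)),
            SuperfamilySpec(L1, 2000, 0.3, PointMass(0.0)),
        ],
        read_length=150,
        total_bp=500 * 150,
        seed=1,
    )
    defaults.update(kw)
    return GenomeSimConfig(**defaults)


class TestGenomeSimulator:
    def test_zero_divergence_reads_are_exact_substrings(self):
        cfg = _genome_cfg(
            superfamilies=[SuperfamilySpec(GYPSY, 2000, 1.0, PointMass(0.0))]
        )
        sim = simulate_repeat_genome(cfg)
        cons = sim.library.records[0].seq
        assert all(r.seq in cons for r in sim.reads)

    def test_seed_determinism(self):
        a = simulate_repeat_genome(_genome_cfg(seed=7))
        b = simulate_repeat_genome(_genome_cfg(seed=7))
        assert [(r.id, r.seq) for r in a.reads] == [(r.id, r.seq) for r in b.reads]
        c = simulate_repeat_genome(_genome_cfg(seed=8))
        assert [(r.id, r.seq) for r in a.reads] != [(r.id, r.seq) for r in c.reads]

    def test_proportions_over_one_rejected(self):
        with pytest.raises(ValueError):
            _genome_cfg(
                superfamilies=[
                    SuperfamilySpec(GYPSY, 2000, 0.7, PointMass(0.0)),
                    SuperfamilySpec(L1, 2000, 0.5, PointMass(0.0)),
                ]
            )

    def test_truth_partitions_reads(self):
        sim = simulate_repeat_genome(_genome_cfg())
        assert set(sim.truth.read_source) == {r.id for r in sim.reads}
        n_te = sum(1 for v in sim.truth.read_source.values() if v is not None)
        assert n_te == len(sim.truth.divergence_realized)

    def test_realized_divergence_matches_planted_mutations(self):
        sim = simulate_repeat_genome(_genome_cfg(seed=5))
        cons = {rec.id.split("_cons")[0]: rec.seq for rec in sim.library.records}
        by_read = {r.id: r.seq for r in sim.reads}
        checked = 0
        for rid, sf in sim.truth.read_source.items():
            if sf is None or sf != "Gypsy":
                continue
            # realized divergence equals the Hamming distance to the best
            # consensus window
            seq = by_read[rid]
            c = cons[sf]
            best = min(
                sum(a != b for a, b in zip(seq, c[o : o + len(seq)]))
                for o in range(len(c) - len(seq) + 1)
            )
            assert best / len(seq) * 100.0 == pytest.approx(
                sim.truth.divergence_realized[rid]
            )
            checked += 1
            if checked >= 25:
                break
        assert checked > 0

    def test_drawn_divergence_matches_configured_distribution(self):
        cfg = _genome_cfg(
            superfamilies=[SuperfamilySpec(GYPSY, 2000, 1.0, Exponential(4.0))],
            total_bp=10_000 * 150,
        )
        sim = simulate_repeat_genome(cfg)
        drawn = np.array(list(sim.truth.divergence_drawn.values()))
        res = stats.kstest(drawn, Exponential(4.0).cdf)
        assert res.pvalue > 0.01

    def test_consensus_shorter_than_read_rejected(self):
        with pytest.raises(ValueError):
            _genome_cfg(
                superfamilies=[SuperfamilySpec(GYPSY, 100, 0.5, PointMass(0.0))]
            )

    def test_normal_mixture_weights_validated(self):
        with pytest.raises(ValueError):
            NormalMixture((5.0, 15.0), (1.0, 1.0), (0.5, 0.6))


class TestTranscriptomeSimulator:
    def test_degenerate_multinomial(self):
        sim = simulate_transcriptome(
            TranscriptomeSimConfig(
                [TranscriptSpec("t1", 500)], replicates_per_sex=1, reads_per_replicate=1000
            )
        )
        assert (sim.counts.values.to_numpy() == 1000).all()

    def test_equal_expression_counts_within_binomial_sd(self):
        n = 1_000_000
        sim = simulate_transcriptome(
            TranscriptomeSimConfig(
                [TranscriptSpec(f"t{i}", 800) for i in range(4)],
                replicates_per_sex=1,
                reads_per_replicate=n,
                seed=2,
            )
        )
        sd = np.sqrt(n * 0.25 * 0.75)
        assert (np.abs(sim.counts.values.to_numpy() - n / 4) < 3 * sd).all()

    def test_zero_length_transcript_rejected(self):
        with pytest.raises(ValueError):
            TranscriptSpec("bad", 0)

    def test_male_multiplier_shifts_expected_tpm(self):
        sim = simulate_transcriptome(
            TranscriptomeSimConfig(
                [
                    TranscriptSpec("gene", 1000, None, 9.0),
                    TranscriptSpec("te", 1000, "Gypsy", 1.0, male_multiplier=3.0),
                ],
                replicates_per_sex=1,
            )
        )
        exp = sim.expected_tpm
        assert exp.loc["te", "female"] == pytest.approx(1e5)
        assert exp.loc["te", "male"] == pytest.approx(3 / 12 * 1e6)


class TestSmallRNASimulator:
    def test_u_bias_one_forces_all_primaries_to_u(self, te_transcripts):
        sim = simulate_small_rna(
            SmallRNASimConfig(
                transcripts=te_transcripts, n_reads=500, u_prob=1.0, rho=0.0, seed=4
            )
        )
        by_id = {r.id: r for r in sim.reads}
        primaries = [
            by_id[rid]
            for rid, cat in sim.truth.category.items()
            if cat == "pirna_antisense"
        ]
        assert primaries and all(r.seq[0] == "T" for r in primaries)

    def test_rho_one_pairs_every_antisense_with_budget(self, te_transcripts):
        sim = simulate_small_rna(
            SmallRNASimConfig(
                transcripts=te_transcripts,
                n_reads=400,
                rho=1.0,
                antisense_fraction=0.4,
                seed=5,
            )
        )
        cats = list(sim.truth.category.values())
        n_anti = cats.count("pirna_antisense")
        n_partner = cats.count("pingpong_partner")
        assert n_partner == min(n_anti, cats.count("pirna_sense") + n_partner)
        assert len(sim.truth.partner_of) == n_partner

    def test_truth_categories_partition_reads(self, te_transcripts):
        mirna = [SequenceRecord("m1", "ACGT" * 5 + "AC")]
        contam = [SequenceRecord("c1", "GATTACA" * 40)]
        sim = simulate_small_rna(
            SmallRNASimConfig(
                transcripts=te_transcripts,
                n_reads=1000,
                mirna_reference=mirna,
                mirna_weight=0.2,
                contaminant_reference=contam,
                contaminant_weight=0.1,
                seed=6,
            )
        )
        assert set(sim.truth.category) == {r.id for r in sim.reads}
        assert len(sim.reads) == 1000

    def test_category_weights_recovered(self, te_transcripts):
        mirna = [SequenceRecord("m1", "ACGT" * 5 + "AC")]
        sim = simulate_small_rna(
            SmallRNASimConfig(
                transcripts=te_transcripts,
                n_reads=20_000,
                mirna_reference=mirna,
                mirna_weight=0.25,
                seed=8,
            )
        )
        frac = list(sim.truth.category.values()).count("mirna") / 20_000
        assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 20_000)

    def test_empty_transcript_set_rejected(self):
        with pytest.raises(ValueError):
            SmallRNASimConfig(transcripts=[], n_reads=10)

    def test_determinism(self, te_transcripts):
        a = simulate_small_rna(SmallRNASimConfig(transcripts=te_transcripts, n_reads=300, seed=9))
        b = simulate_small_rna(SmallRNASimConfig(transcripts=te_transcripts, n_reads=300, seed=9))
        assert [(r.id, r.seq) for r in a.reads] == [(r.id, r.seq) for r in b.reads]


class TestSpeciesPanel:
    def _species(self):
        return [
            SpeciesSpec(f"sp{i}", g, ratio_pirna=1.5, ratio_repressive=0.6, ratio_trim28=0.1)
            for i, g in enumerate([1.0, 2.5, 5.5, 21.0, 44.0, 130.0])
        ]

    def test_zero_noise_recovers_ratios_exactly(self):
        gs = load_pathway_gene_sets()
        panel = simulate_species_panel(
            PanelConfig(self._species(), gs, noise_sd=0.0, seed=1)
        )
        from tescope.expression import pathway_ratios

        res = pathway_ratios(panel.tables, gs, panel.genome_sizes, panel.sex_of)
        for r in res:
            assert r.ratio_pirna == pytest.approx(1.5)
            assert r.ratio_repressive == pytest.approx(0.6)
            assert r.ratio_trim28 == pytest.approx(0.1)

    def test_missing_genes_absent_from_table(self):
        gs = load_pathway_gene_sets()
        sp = self._species()
        sp[0] = SpeciesSpec("sp0", 1.0, missing_genes=("PIWIL1", "MAEL"))
        panel = simulate_species_panel(PanelConfig(sp, gs, seed=2))
        assert "PIWIL1" not in panel.tables["sp0"].values.index
        assert "PIWIL1" in panel.tables["sp1"].values.index

    def test_determinism(self):
        gs = load_pathway_gene_sets()
        a = simulate_species_panel(PanelConfig(self._species(), gs, seed=3))
        b = simulate_species_panel(PanelConfig(self._species(), gs, seed=3))
        for name in a.tables:
            assert a.tables[name].values.equals(b.tables[name].values)
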