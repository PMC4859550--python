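"""Synthetic-data generator: determinism, event ledgers, planted motifs,
codon bias, and whole genome-set invariants."""

import numpy as np
import pytest

from yeastevol.cai import cai, relative_adaptiveness
from yeastevol.codonmodel import build_rate_matrix
from yeastevol.genetic_code import (
    CODON_TO_AA,
    STOP_CODONS,
    reverse_complement,
    synonymous_families,
    translate,
)
from yeastevol.promoters import extract_promoters
from yeastevol.simulate import (
    MOTIF,
    MOTIF_RC,
    SimulationConfig,
    _scan_motif_starts,
    build_genome_set,
    simulate_biased_genes,
    simulate_codon_alignment,
    simulate_promoters,
    write_genome_set,
)
from yeastevol.trees import BranchClassTree, guide_tree


class TestCodonSimulation:
    def test_deterministic_under_seed(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=40, seed=42)
        a1, l1 = simulate_codon_alignment(seven_taxon_tree, cfg)
        a2, l2 = simulate_codon_alignment(seven_taxon_tree, cfg)
        assert a1.seqs == a2.seqs
        assert len(l1) == len(l2)
        assert all(
            (e1.site, e1.from_codon, e1.to_codon) == (e2.site, e2.from_codon, e2.to_codon)
            for e1, e2 in zip(l1, l2)
        )

    def test_zero_branch_lengths_give_identical_leaves(self):
        tree = guide_tree(0.0)
        cfg = SimulationConfig(codon_length=30, seed=1)
        aln, ledger = simulate_codon_alignment(tree, cfg)
        assert ledger == []
        assert len(set(aln.seqs)) == 1

    def test_omega_zero_forbids_nonsynonymous_events(self, seven_taxon_tree):
        cfg = SimulationConfig(
            codon_length=60, omega_by_class={0: 0.0, 1: 0.0}, seed=3
        )
        _, ledger = simulate_codon_alignment(seven_taxon_tree, cfg)
        assert ledger, "expected synonymous events on a tree with length"
        assert all(e.synonymous for e in ledger)

    def test_ledger_flags_match_genetic_code(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=50, omega_by_class={0: 0.5, 1: 2.0}, seed=7)
        _, ledger = simulate_codon_alignment(seven_taxon_tree, cfg)
        n_syn = sum(e.synonymous for e in ledger)
        n_nonsyn = sum(not e.synonymous for e in ledger)
        assert n_syn + n_nonsyn == len(ledger)
        for e in ledger:
            assert e.synonymous == (CODON_TO_AA[e.from_codon] == CODON_TO_AA[e.to_codon])
            assert e.to_codon not in STOP_CODONS

    def test_mean_substitutions_per_codon_equals_branch_length(self):
        """With Q normalised to unit expected rate, the expected number of
        substitutions per codon on a branch equals its length."""
        tree = BranchClassTree.from_newick("(A:0.1,B:0.0);")
        t, n_sites, n_seeds = 0.1, 2000, 25
        counts = []
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                codon_length=n_sites, kappa=2.0, omega_by_class={0: 0.5}, seed=seed
            )
            _, ledger = simulate_codon_alignment(tree, cfg)
            counts.append(len(ledger) / n_sites)
        mean = float(np.mean(counts))
        mc_se = float(np.std(counts, ddof=1)) / np.sqrt(n_seeds)
        assert abs(mean - t) <= 3 * mc_se + 1e-12

    def test_unknown_branch_class_rejected(self, seven_taxon_tree):
        cfg = SimulationConfig(codon_length=10, omega_by_class={0: 0.2}, seed=0)
        with pytest.raises(ValueError, match="branch class"):
            simulate_codon_alignment(seven_taxon_tree, cfg)


class TestPromoterSimulation:
    def test_no_planting_with_exclude_policy_gives_motif_free_sequences(self):
        cfg = SimulationConfig(seed=5, background_motif_policy="exclude")
        proms, ledger = simulate_promoters([(f"g{i}", "MRP") for i in range(40)], cfg)
        assert ledger == []
        for seq in proms.values():
            assert MOTIF not in seq and MOTIF_RC not in seq

    def test_planted_frequency_recovered(self):
        """plant_prob 0.15 in every MRP window: the fraction of genes with a
        planted motif per window stays inside the 99%% binomial interval."""
        from scipy.stats import binom

        n_genes, p = 2000, 0.15
        cfg = SimulationConfig(
            seed=11,
            plant_prob={("MRP", w): p for w in range(1, 13)},
        )
        _, ledger = simulate_promoters(
            [(f"g{i}", "MRP") for i in range(n_genes)], cfg
        )
        lo, hi = binom.ppf([0.005, 0.995], n_genes, p)
        per_window = np.zeros(13, dtype=int)
        for pm in ledger:
            per_window[pm.window] += 1
        for w in range(1, 13):
            assert lo <= per_window[w] <= hi, f"window {w}: {per_window[w]}"

    def test_planted_coordinates_scan_back_to_their_window(self):
        cfg = SimulationConfig(
            seed=2, plant_prob={("CRP", w): 0.5 for w in range(1, 13)}
        )
        proms, ledger = simulate_promoters(
            [(f"g{i}", "CRP") for i in range(50)], cfg
        )
        from yeastevol.promoters import motif_hit_windows

        by_gene = {}
        for pm in ledger:
            by_gene.setdefault(pm.gene, set()).add(pm.window)
        for gene, seq in proms.items():
            wins, _ = motif_hit_windows(seq, MOTIF, 50, 12)
            assert wins == by_gene.get(gene, set())

    def test_unknown_gene_set_rejected(self):
        cfg = SimulationConfig(seed=0)
        cfg.plant_prob = {("XXX", 1): 0.5}
        with pytest.raises(ValueError, match="unknown gene set"):
            simulate_promoters([("g1", "CRP")], cfg)


class TestBiasedGenes:
    def test_full_bias_gives_cai_one(self):
        ref = simulate_biased_genes(
            {c: 1.0 for fam in synonymous_families().values() for c in fam},
            1.0, 5, 60, seed=0,
        )
        table = relative_adaptiveness(ref)
        genes = simulate_biased_genes(table.weights, 1.0, 10, 80, seed=1)
        for g in genes:
            assert cai(g, table) == pytest.approx(1.0)

    def test_zero_bias_matches_analytic_geometric_mean(self):
        """Uniform within-family sampling: E[log w] is the family-averaged
        log weight; the long-gene CAI converges to its exponential."""
        weights = {}
        for fam in synonymous_families().values():
            for i, c in enumerate(sorted(fam)):
                weights[c] = 1.0 if i == 0 else 0.5
        fams = synonymous_families()
        import math

        logs = []
        for aa, fam in fams.items():
            if len(fam) == 1:  # Met/Trp excluded from CAI
                continue
            logs.append(np.mean([math.log(weights[c]) for c in fam]))
        expected = math.exp(np.mean(logs))
        table_genes = simulate_biased_genes(weights, 0.0, 30, 500, seed=4)
        from yeastevol.cai import AdaptivenessTable

        table = AdaptivenessTable(weights=dict(weights))
        values = [cai(g, table) for g in table_genes]
        assert float(np.mean(values)) == pytest.approx(expected, abs=0.02)

    def test_empty_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_biased_genes({}, 0.5, 1, 10, seed=0)
        assert simulate_biased_genes({"TTT": 1.0}, 0.5, 0, 10, seed=0) == []

    def test_deterministic(self):
        w = {c: 1.0 for fam in synonymous_families().values() for c in fam}
        assert simulate_biased_genes(w, 0.3, 4, 30, seed=9) == (
            simulate_biased_genes(w, 0.3, 4, 30, seed=9)
        )


@pytest.fixture(scope="module")
def genome_set():
    cfg = SimulationConfig(n_genes=12, codon_length=40, seed=21,
                           plant_prob={("MRP", 2): 0.8, ("CRP", 1): 0.5})
    return build_genome_set(cfg)


class TestGenomeSet:

    def test_gene_records_within_contigs_and_in_frame(self, genome_set):
        for sp in genome_set.species:
            contig = genome_set.contigs[sp]
            for rec in genome_set.genes[sp]:
                seq = contig[rec.contig]
                assert 1 <= rec.start <= rec.end <= len(seq)
                cds = seq[rec.start - 1 : rec.end]
                if rec.strand == "-":
                    cds = reverse_complement(cds)
                assert len(cds) % 3 == 0
                translate(cds)  # raises on internal stops

    def test_cds_matches_alignment_row(self, genome_set):
        for sp in genome_set.species:
            for rec in genome_set.genes[sp]:
                aln = genome_set.alignments[rec.gene]
                expect = aln.seqs[aln.taxa.index(sp)]
                contig = genome_set.contigs[sp][rec.contig]
                cds = contig[rec.start - 1 : rec.end]
                if rec.strand == "-":
                    cds = reverse_complement(cds)
                assert cds == expect

    def test_extracted_promoters_match_simulated(self, genome_set):
        """Promoters recovered from the assembled genome equal the simulated
        ones on both strands (the planted-motif ledger therefore transfers)."""
        cfg = genome_set.config
        for sp in genome_set.species:
            pset = extract_promoters(
                genome_set.contigs[sp], genome_set.genes[sp],
                genome_set.set_labels, length=cfg.promoter_length, species=sp,
            )
            by_gene = {r.gene: r for r in pset.records}
            for gid, prom in genome_set.promoters[sp].items():
                assert by_gene[gid].seq == prom

    def test_planted_motifs_inside_promoter_span(self, genome_set):
        L = genome_set.config.promoter_length
        for sp in genome_set.species:
            for pm in genome_set.planted[sp]:
                assert 6 <= pm.distance <= L
                seq = genome_set.promoters[sp][pm.gene]
                pos = L - pm.distance
                assert seq[pos : pos + 6] == pm.strand_form

    def test_write_round_trip(self, genome_set, tmp_path):
        write_genome_set(genome_set, tmp_path)
        from Bio import SeqIO

        sp = genome_set.species[0]
        recs = list(SeqIO.parse(tmp_path / f"{sp}.genome.fasta", "fasta"))
        assert len(recs) == 1
        assert str(recs[0].seq) == genome_set.contigs[sp][recs[0].id]
        gff = (tmp_path / f"{sp}.genes.gff3").read_text().splitlines()
        assert gff[0] == "##gff-version 3"
        assert len(gff) == 1 + len(genome_set.genes[sp])
        truth = (tmp_path / "ground_truth.json").read_text()
        assert '"true_omega"' in truth


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(codon_freqs=np.full(61, 1.0))
        with pytest.raises(ValueError, match="omega"):
            SimulationConfig(omega_by_class={0: -1.0})
        with pytest.raises(ValueError, match="plant_prob"):
            SimulationConfig(plant_prob={("MRP", 1): 1.5})

    def test_from_file(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "n_genes = 9\ncodon_length = 33\nkappa = 3.5\n"
            "omega_class_0 = 0.1\nomega_class_1 = 2.5\n"
            "plant_prob_MRP_3 = 0.4\nplant_prob_CRP = 0.2\nseed = 7\n"
        )
        cfg = SimulationConfig.from_file(path)
        assert cfg.n_genes == 9 and cfg.codon_length == 33
        assert cfg.kappa == 3.5
        assert cfg.omega_by_class == {0: 0.1, 1: 2.5}
        assert cfg.plant_prob[("MRP", 3)] == 0.4
        assert cfg.plant_prob[("CRP", 1)] == 0.2
        assert cfg.plant_prob[("CRP", 12)] == 0.2
        assert cfg.seed == 7

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("frobnicate = 1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            SimulationConfig.from_file(path)
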