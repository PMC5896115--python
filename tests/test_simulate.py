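"""Synthetic genomes, planted SVs, coordinate maps, and derived alignments."""

import numpy as np
import pytest

from rnasv.segmentation import HEAD, TAIL
from rnasv.simulate import (
    GenomeMap,
    emit_alignments,
    make_genome,
    plant_svs,
    revcomp,
    simulate_dataset,
    true_tsvs,
)

ALL_TYPES = ("deletion", "inversion", "insertion", "duplication", "translocation")


class TestMakeGenome:
    def test_deterministic_under_seed(self):
        g1, a1 = make_genome(seed=3)
        g2, a2 = make_genome(seed=3)
        assert g1 == g2 and a1 == a2

    def test_different_seed_differs(self):
        assert make_genome(seed=3)[0] != make_genome(seed=4)[0]

    def test_no_genes_empty_annotation(self):
        _, ann = make_genome(n_genes=0, seed=0)
        assert ann == []

    def test_exon_geometry_respected(self):
        _, ann = make_genome(
            n_genes=4, seed=0,
            exon_geometry={"n_exons": 3, "exon_len": 120, "intron_len": 200},
        )
        for g in ann:
            assert len(g.exons) == 3
            assert g.transcript_length == 3 * 120

    def test_genes_disjoint_with_gaps(self):
        _, ann = make_genome(n_genes=10, seed=1)
        by_chrom = {}
        for g in ann:
            by_chrom.setdefault(g.chrom, []).append(g)
        for genes in by_chrom.values():
            genes.sort(key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end >= 500


class TestPlantSvs:
    def _setup(self, counts, seed=5):
        genome, ann = make_genome(seed=seed)
        return genome, ann, plant_svs(genome, ann, counts, seed=seed)

    def test_inversion_is_reverse_complement(self):
        genome, ann, (re, svs, gmap) = self._setup({"inversion": 1})
        (sv,) = svs
        img = gmap.forward(sv.chrom, sv.start)
        rc, q, strand = img
        assert strand == "-"
        assert re[rc][q] == revcomp(genome[sv.chrom][sv.start])

    def test_deletion_shortens_chromosome(self):
        genome, ann, (re, svs, gmap) = self._setup({"deletion": 1})
        (sv,) = svs
        assert len(re[sv.chrom]) == len(genome[sv.chrom]) - (sv.end - sv.start)
        assert gmap.forward(sv.chrom, sv.start) is None

    def test_insertion_lengthens_chromosome(self):
        genome, ann, (re, svs, gmap) = self._setup({"insertion": 1})
        (sv,) = svs
        assert len(re[sv.chrom]) == len(genome[sv.chrom]) + sv.novel_length

    def test_duplication_is_tandem(self):
        genome, ann, (re, svs, gmap) = self._setup({"duplication": 1})
        (sv,) = svs
        block = genome[sv.chrom][sv.start:sv.end]
        rc, q, _ = gmap.forward(sv.chrom, sv.start)
        assert re[rc][q : q + 2 * len(block)] == block + block

    def test_translocation_moves_sequence_across_chromosomes(self):
        genome, ann, (re, svs, gmap) = self._setup({"translocation": 1})
        (sv,) = svs
        rc, q, strand = gmap.forward(sv.chrom, sv.start)
        assert rc == sv.dest_chrom and strand == "+"
        L = sv.end - sv.start
        assert re[rc][q : q + L] == genome[sv.chrom][sv.start : sv.end]
        assert len(re[sv.chrom]) == len(genome[sv.chrom]) - L

    def test_round_trip_forward_backward_identity(self):
        genome, ann, (re, svs, gmap) = self._setup({t: 1 for t in ALL_TYPES}, seed=9)
        rng = np.random.default_rng(0)
        checked = 0
        for chrom, seq in genome.items():
            for pos in rng.integers(0, len(seq), size=300):
                img = gmap.forward(chrom, int(pos))
                if img is None:
                    continue  # deleted base
                rc, q, _ = img
                assert gmap.backward(rc, q) == (chrom, int(pos))
                checked += 1
        assert checked > 200

    def test_materialized_sequence_matches_map(self):
        genome, ann, (re, svs, gmap) = self._setup({t: 1 for t in ALL_TYPES}, seed=9)
        rng = np.random.default_rng(1)
        for chrom, seq in genome.items():
            for pos in rng.integers(0, len(seq), size=200):
                img = gmap.forward(chrom, int(pos))
                if img is None:
                    continue
                rc, q, strand = img
                base = seq[int(pos)]
                assert re[rc][q] == (base if strand == "+" else revcomp(base))

    def test_unknown_type_rejected(self):
        genome, ann = make_genome(seed=0)
        with pytest.raises(ValueError, match="unknown SV types"):
            plant_svs(genome, ann, {"inverzion": 1}, seed=0)


class TestTrueTsvs:
    def test_inversion_inside_gene_yields_oriented_junctions(self):
        genome, ann = make_genome(seed=5)
        re, svs, gmap = plant_svs(genome, ann, {"inversion": 1}, seed=5)
        truth = true_tsvs(ann, gmap)
        assert truth  # the SV is planted gene-hitting
        for t in truth:
            sides = (t.bp1.side, t.bp2.side)
            assert sides in {(TAIL, TAIL), (HEAD, HEAD)}

    def test_no_svs_no_truth(self):
        genome, ann = make_genome(seed=5)
        gmap = GenomeMap({c: [] for c in genome})  # placeholder, not used
        re, svs, gmap = plant_svs(genome, ann, {}, seed=5)
        assert true_tsvs(ann, gmap) == []

    def test_junction_silent_types_yield_no_truth(self):
        # deletions clip reads, duplications and novel insertions leave
        # intron-like forward gaps: none are observable as discordant pairs
        genome, ann = make_genome(seed=5)
        for t in ("deletion", "duplication", "insertion"):
            re, svs, gmap = plant_svs(genome, ann, {t: 1}, seed=5)
            assert true_tsvs(ann, gmap) == []


class TestEmitAlignments:
    def test_null_genome_all_pairs_concordant(self, null_dataset):
        assert null_dataset.pairs
        assert all(p.concordant for p in null_dataset.pairs)

    def test_junction_straddling_fragments_discordant(self, small_dataset):
        # pairs from genes hit by an inversion or translocation must include
        # discordant ones; cross-check with the classifier
        assert any(not p.concordant for p in small_dataset.pairs)

    def test_expected_pair_count_within_3_sigma(self):
        genome, ann = make_genome(seed=2)
        re, svs, gmap = plant_svs(genome, ann, {}, seed=2)
        pairs = emit_alignments(ann, gmap, coverage=30.0, read_len=100, frag_len=300, seed=2)
        lam = sum(
            30.0 * g.transcript_length / 200.0
            for g in ann if g.transcript_length >= 300
        )
        assert abs(len(pairs) - lam) <= 3 * np.sqrt(lam)

    def test_deterministic_under_seed(self):
        genome, ann = make_genome(seed=2)
        re, svs, gmap = plant_svs(genome, ann, {"inversion": 2}, seed=2)
        p1 = emit_alignments(ann, gmap, seed=5)
        p2 = emit_alignments(ann, gmap, seed=5)
        assert [(p.read_name, p.first, p.second) for p in p1] == [
            (p.read_name, p.first, p.second) for p in p2
        ]

    def test_noise_rate_adds_noise_pairs(self):
        genome, ann = make_genome(seed=2)
        re, svs, gmap = plant_svs(genome, ann, {}, seed=2)
        pairs = emit_alignments(ann, gmap, noise_rate=0.05, seed=3)
        assert any(p.read_name.startswith("noise_") for p in pairs)

    def test_read_len_must_be_below_frag_len(self):
        genome, ann = make_genome(seed=2)
        re, svs, gmap = plant_svs(genome, ann, {}, seed=2)
        with pytest.raises(ValueError):
            emit_alignments(ann, gmap, read_len=300, frag_len=300)


class TestSimulateDataset:
    def test_truth_coordinates_are_within_reference(self, small_dataset):
        ds = small_dataset
        for t in ds.truth:
            for bp in (t.bp1, t.bp2):
                assert 0 <= bp.pos <= ds.chrom_lengths[bp.chrom]

    def test_parts_lie_within_reference(self, small_dataset):
        ds = small_dataset
        for p in ds.pairs[:500]:
            for end in (p.first, p.second):
                for part in end.parts:
                    assert 0 <= part.start < part.end <= ds.chrom_lengths[part.chrom]
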