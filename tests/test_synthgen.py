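"""Synthetic populations, shotgun reads, and ground-truth instances."""

import numpy as np
import pytest

from tangleasm import (EvolutionConfig, ReadConfig, generate_population,
                       make_instance, shred_reads, validate_walk)
from tangleasm._dna import revcomp
from tangleasm.graphio import Walk, WalkPair


def zero_rate_config(**kw):
    defaults = dict(initial_length=2000, population_size=5, generations=2,
                    str_rate=0, cnv_rate=0, short_repeat_rate=0,
                    long_repeat_rate=0, translocation_rate=0,
                    inversion_rate=0, point_rate=0, seed=1)
    defaults.update(kw)
    return EvolutionConfig(**defaults)


class TestPopulation:
    def test_zero_rates_give_identical_genomes(self):
        genomes = generate_population(zero_rate_config())
        assert len(genomes) == 5
        assert len({g for g, _p in genomes}) == 1

    def test_default_population_and_lineage(self):
        cfg = EvolutionConfig(initial_length=3000, population_size=20,
                              generations=4, seed=2)
        genomes = generate_population(cfg)
        assert len(genomes) == 20
        assert genomes[0][1] is None
        for i, (_g, parent) in enumerate(genomes[1:], start=1):
            assert parent is not None and parent < i

    def test_point_rate_hamming_expectation(self):
        """Mean child-parent Hamming distance ~ Binomial(L, r*f)."""
        L, r, f = 3000, 0.01, 0.5
        dists = []
        for seed in range(50):
            cfg = zero_rate_config(initial_length=L, population_size=2,
                                   generations=1, point_rate=r,
                                   descendant_rate_factor=f, seed=seed)
            parent, child = [g for g, _p in generate_population(cfg)]
            dists.append(sum(a != b for a, b in zip(parent, child)))
        mean = np.mean(dists)
        expect = L * r * f
        sigma = np.sqrt(L * r * f * (1 - r * f) / 50)
        assert abs(mean - expect) <= 3 * sigma

    def test_inversion_only_preserves_length(self):
        cfg = zero_rate_config(initial_length=5000, population_size=6,
                               inversion_rate=2e-3, seed=3)
        genomes = generate_population(cfg)
        assert {len(g) for g, _p in genomes} == {5000}

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            generate_population(zero_rate_config(initial_length=100,
                                                 cnv_rate=1e-4))

    def test_reproducible(self):
        cfg = EvolutionConfig(initial_length=2000, population_size=5,
                              generations=2, seed=9)
        assert generate_population(cfg) == generate_population(cfg)


class TestReads:
    def test_read_count_formula(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), size=10_000))
        reads = shred_reads(genome, ReadConfig(coverage=30, read_length=100,
                                               sub_error_rate=0.0, seed=0))
        assert len(reads) == 3000

    def test_error_free_reads_are_substrings(self):
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        reads = shred_reads(genome, ReadConfig(coverage=2, read_length=80,
                                               sub_error_rate=0.0, seed=1))
        for rec in reads:
            s = str(rec.seq)
            assert s in genome or revcomp(s) in genome

    def test_error_rate_binomial_expectation(self):
        rng = np.random.default_rng(2)
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        cfg = ReadConfig(coverage=20, read_length=100, sub_error_rate=0.01,
                         seed=2)
        reads = shred_reads(genome, cfg)[:1000]
        mismatches = []
        for rec in reads:
            s = str(rec.seq)
            pos = int(rec.description.split("pos=")[1].split()[0])
            ref = genome[pos:pos + 100]
            if "strand=-" in rec.description:
                s = revcomp(s)
            mismatches.append(sum(a != b for a, b in zip(s, ref)))
        mean = np.mean(mismatches)
        sigma = np.sqrt(100 * 0.01 * 0.99 / len(mismatches))
        assert abs(mean - 1.0) <= 3 * sigma

    def test_total_bases_near_coverage(self):
        rng = np.random.default_rng(3)
        genome = "".join(rng.choice(list("ACGT"), size=4000))
        cfg = ReadConfig(coverage=10, read_length=130, sub_error_rate=0, seed=3)
        reads = shred_reads(genome, cfg)
        total = sum(len(r.seq) for r in reads)
        assert abs(total - 10 * 4000) <= 130

    def test_read_longer_than_genome_rejected(self):
        with pytest.raises(ValueError, match="read_length"):
            shred_reads("ACGT" * 10, ReadConfig(read_length=100))

    def test_reproducible(self):
        genome = "ACGT" * 200
        cfg = ReadConfig(coverage=3, read_length=50, seed=11)
        a = shred_reads(genome, cfg)
        b = shred_reads(genome, cfg)
        assert [str(r.seq) for r in a] == [str(r.seq) for r in b]


class TestInstances:
    def test_truth_walk_valid_and_weights_are_visit_counts(self):
        for seed in range(10):
            for shape in ("line", "cycle", "tangle", "random"):
                inst = make_instance(shape=shape, n_nodes=5, node_length=30,
                                     walk_length=6, orientation="oriented",
                                     seed=seed)
                assert validate_walk(inst.graph, inst.truth_walk) == []
                visits = {}
                for nid, _o in inst.truth_walk:
                    visits[nid] = visits.get(nid, 0) + 1
                for nid, node in inst.graph.nodes.items():
                    assert node.weight == float(visits.get(nid, 0))

    def test_line_prefix_walk_leaves_tail_at_zero(self):
        inst = make_instance(shape="line", n_nodes=5, node_length=20,
                             walk_length=3, orientation="plain", seed=0)
        weights = [inst.graph.nodes[f"n{i:03d}"].weight for i in range(5)]
        assert weights == [1, 1, 1, 0, 0]

    def test_noise_is_truncated_and_rounded(self):
        inst = make_instance(shape="line", n_nodes=6, node_length=20,
                             walk_length=6, weight_noise_sd=0.8, seed=4)
        for node in inst.graph.nodes.values():
            assert node.weight >= 0
            assert node.weight == round(node.weight, 1)

    def test_diploid_truth_is_pair(self):
        inst = make_instance(shape="cycle", n_nodes=4, node_length=20,
                             walk_length=6, orientation="diploid", seed=5)
        assert isinstance(inst.truth_walk, WalkPair)
        assert isinstance(inst.truth_sequence, tuple)

    def test_truth_sequence_matches_walk(self):
        inst = make_instance(shape="line", n_nodes=3, node_length=25,
                             walk_length=3, orientation="plain", seed=6)
        expect = "".join(inst.graph.nodes[nid].sequence
                         for nid, _o in inst.truth_walk)
        assert inst.truth_sequence == expect

    def test_reproducible(self):
        a = make_instance(shape="tangle", n_nodes=6, node_length=30,
                          walk_length=7, seed=8)
        b = make_instance(shape="tangle", n_nodes=6, node_length=30,
                          walk_length=7, seed=8)
        assert a.truth_walk.steps == b.truth_walk.steps
        assert a.truth_sequence == b.truth_sequence
        assert a.graph.edges == b.graph.edges

    def test_zero_walk_length(self):
        inst = make_instance(shape="line", n_nodes=3, node_length=20,
                             walk_length=0, seed=9)
        assert isinstance(inst.truth_walk, Walk) and len(inst.truth_walk) == 0
        assert all(n.weight == 0 for n in inst.graph.nodes.values())
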