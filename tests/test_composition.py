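import numpy as np
import pytest

from minitax.composition import (
    CompositionModel,
    CompositionVector,
    composition_posterior,
    effective_start_positions,
    em_update,
    filter_composition_by_identity,
    median_identities,
    project_composition,
    read_likelihood,
    run_em,
)
from minitax.mapping import CandidateMapping, ReadMappingSet


def make_read(read_id, length, cands):
    """cands: list of (genome, mapping_quality)."""
    rms = ReadMappingSet(read_id=read_id, read_length=length)
    for i, (g, q) in enumerate(cands):
        c = CandidateMapping(read_id, g, f"{g}_c1", i * 10, i * 10 + length, 1)
        c.mapping_quality = q
        rms.candidates.append(c)
    return rms


class TestEffectiveStartPositions:
    def test_single_contig(self):
        assert effective_start_positions(1000, [10_000]) == 9000

    def test_summed_over_contigs(self):
        assert effective_start_positions(1000, [5000, 3000]) == 6000

    def test_clamped_when_read_longer_than_contig(self):
        assert effective_start_positions(1000, [800]) == 1

    def test_no_contigs_rejected(self):
        with pytest.raises(ValueError):
            effective_start_positions(1000, [])


GCL = {"g1": [10_000], "g2": [10_000]}


class TestReadLikelihood:
    def test_single_candidate_full_mass(self):
        rms = make_read("r", 1000, [("g1", 1.0)])
        assert read_likelihood(rms, {"g1": 1.0, "g2": 0.0}, GCL) == pytest.approx(
            1.0 / 9000
        )

    def test_symmetric_candidates_equal_terms(self):
        rms = make_read("r", 1000, [("g1", 0.5), ("g2", 0.5)])
        ll = read_likelihood(rms, {"g1": 0.5, "g2": 0.5}, GCL)
        assert ll == pytest.approx(2 * 0.5 * 0.5 / 9000)

    def test_manual_spreadsheet_sum(self):
        # 3 reads x 2 genomes with asymmetric qualities and contig lengths
        gcl = {"g1": [6000], "g2": [4000, 3000]}
        F = {"g1": 0.7, "g2": 0.3}
        rms = make_read("r1", 1000, [("g1", 0.8), ("g2", 0.2)])
        expected = 0.8 * (1 / 5000) * 0.7 + 0.2 * (1 / (3000 + 2000)) * 0.3
        assert read_likelihood(rms, F, gcl) == pytest.approx(expected)


class TestCompositionPosterior:
    def test_single_candidate_posterior_one(self):
        rms = make_read("r", 1000, [("g1", 1.0)])
        assert composition_posterior(rms, {"g1": 1.0, "g2": 0.0}, GCL) == [1.0]

    def test_equal_factors_reduce_to_F(self):
        rms = make_read("r", 1000, [("g1", 0.5), ("g2", 0.5)])
        post = composition_posterior(rms, {"g1": 0.8, "g2": 0.2}, GCL)
        assert post == pytest.approx([0.8, 0.2])

    def test_asymmetric_brute_force(self):
        gcl = {"g1": [6000], "g2": [11_000]}
        F = {"g1": 0.4, "g2": 0.6}
        rms = make_read("r", 1000, [("g1", 0.3), ("g2", 0.7)])
        t1 = 0.3 * (1 / 5000) * 0.4
        t2 = 0.7 * (1 / 10_000) * 0.6
        post = composition_posterior(rms, F, gcl)
        assert post == pytest.approx([t1 / (t1 + t2), t2 / (t1 + t2)])

    def test_degenerate_denominator_warns_uniform(self):
        rms = make_read("r", 1000, [("g1", 0.5), ("g2", 0.5)])
        with pytest.warns(UserWarning):
            post = composition_posterior(rms, {"g1": 0.0, "g2": 0.0}, GCL)
        assert post == [0.5, 0.5]


class TestEMUpdate:
    def test_unique_reads_are_a_fixed_point(self):
        reads = [make_read(f"r{i}", 1000, [("g1", 1.0)]) for i in range(5)]
        F = em_update(reads, {"g1": 1.0, "g2": 0.0}, GCL)
        assert F["g1"] == pytest.approx(1.0)
        assert F["g2"] == pytest.approx(0.0)

    def test_symmetric_split_stays_uniform(self):
        reads = [
            make_read(f"r{i}", 1000, [("g1", 0.5), ("g2", 0.5)]) for i in range(4)
        ]
        F = em_update(reads, {"g1": 0.5, "g2": 0.5}, GCL)
        assert F["g1"] == pytest.approx(0.5)
        assert sum(F.values()) == pytest.approx(1.0)


def random_instance(rng, n_reads=30, n_genomes=4):
    gcl = {f"g{j}": [int(rng.integers(5000, 20_000))] for j in range(n_genomes)}
    reads = []
    for i in range(n_reads):
        k = int(rng.integers(1, n_genomes + 1))
        genomes = rng.choice(sorted(gcl), size=k, replace=False)
        quals = rng.dirichlet(np.ones(k))
        reads.append(
            make_read(f"r{i}", int(rng.integers(1000, 4000)), list(zip(genomes, quals)))
        )
    return reads, gcl


class TestRunEM:
    def test_single_genome_converges_immediately(self):
        gcl = {"g1": [10_000]}
        reads = [make_read(f"r{i}", 1000, [("g1", 1.0)]) for i in range(3)]
        res = run_em(reads, gcl)
        assert res.converged
        assert res.params["g1"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_loglik_monotone_and_posteriors_normalized(self, seed):
        rng = np.random.default_rng(seed)
        reads, gcl = random_instance(rng)
        model = CompositionModel(reads, gcl)
        res = model.fit()
        trace = np.array(res.loglike_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        # per-read posterior sums
        sums = np.bincount(
            model.data.read_idx, weights=res.candidate_posteriors
        )
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert res.params.sum() == pytest.approx(1.0, abs=1e-9)

    def test_twin_genomes_split_but_species_sum_is_right(self):
        # identical genomes are unidentifiable at strain level; EM keeps the
        # uniform split while their combined mass matches the truth
        gcl = {"twinA": [10_000], "twinB": [10_000], "other": [10_000]}
        reads = [
            make_read(f"t{i}", 1000, [("twinA", 0.5), ("twinB", 0.5)])
            for i in range(8)
        ] + [make_read(f"o{i}", 1000, [("other", 1.0)]) for i in range(2)]
        res = run_em(reads, gcl)
        assert res.params["twinA"] == pytest.approx(res.params["twinB"], abs=1e-6)
        assert res.params["twinA"] + res.params["twinB"] == pytest.approx(0.8)
        assert res.params["other"] == pytest.approx(0.2)

    def test_order_invariance(self):
        rng = np.random.default_rng(123)
        reads, gcl = random_instance(rng)
        res_fwd = run_em(reads, gcl)
        res_rev = run_em(list(reversed(reads)), gcl)
        assert np.allclose(res_fwd.params.values, res_rev.params.values, atol=1e-12)


class TestFinalize:
    def test_no_unmapped_reads_means_zero_unassigned(self):
        reads = [make_read(f"r{i}", 1000, [("g1", 1.0)]) for i in range(4)]
        res = CompositionModel(reads, {"g1": [10_000]}).fit()
        comp, assignments = res.finalize()
        assert comp.unassigned_fraction == 0.0
        assert comp.total() == pytest.approx(1.0)
        assert all(a.genome_id == "g1" for a in assignments)

    def test_unmapped_fraction_rescales_genomes(self):
        reads = [make_read(f"r{i}", 1000, [("g1", 1.0)]) for i in range(9)]
        reads.append(ReadMappingSet("u1", 2000))  # long but unmapped
        res = CompositionModel(reads, {"g1": [10_000]}).fit()
        comp, assignments = res.finalize()
        assert comp.unassigned_fraction == pytest.approx(0.10)
        assert comp.fractions["g1"] == pytest.approx(0.90)
        unassigned = [a for a in assignments if a.genome_id is None]
        assert [a.read_id for a in unassigned] == ["u1"]

    def test_sub_length_reads_counted_by_denominator_switch(self):
        reads = [make_read(f"r{i}", 1000, [("g1", 1.0)]) for i in range(8)]
        reads.append(ReadMappingSet("s1", 400, too_short=True))
        reads.append(ReadMappingSet("s2", 300, too_short=True))
        res = CompositionModel(reads, {"g1": [10_000]}).fit()
        comp_all, assign_all = res.finalize(denominator="all-reads")
        assert comp_all.unassigned_fraction == pytest.approx(0.2)
        assert len(assign_all) == 10
        comp_long, assign_long = res.finalize(denominator="long-reads")
        assert comp_long.unassigned_fraction == 0.0
        assert len(assign_long) == 8

    def test_tie_between_locations_is_deterministic(self):
        def build():
            rms = ReadMappingSet("r", 1000)
            for start in (2000, 500):  # same genome, two equal-quality spots
                c = CandidateMapping("r", "g1", "g1_c1", start, start + 1000, 1)
                c.mapping_quality = 0.5
                rms.candidates.append(c)
            return [rms]

        picks = set()
        for _ in range(3):
            res = CompositionModel(build(), {"g1": [10_000]}).fit()
            _, (a,) = res.finalize()
            best = [c for c in build()[0].candidates]
            picks.add(a.genome_id)
        assert picks == {"g1"}
        # the chosen start is the leftmost of the tied pair, every run
        res = CompositionModel(build(), {"g1": [10_000]}).fit()
        rms = res.model.mappings[0]
        best = min(
            rms.candidates,
            key=lambda c: (-c.posterior, -c.mapping_quality, c.genome_id, c.contig_id, c.start),
        )
        assert best.start == 500


class TestProjection:
    def test_strain_masses_sum_into_species(self, toy_taxonomy):
        comp = CompositionVector({"g3": 0.3, "g4": 0.2, "g2": 0.5})
        sp = project_composition(comp, toy_taxonomy, "species")
        assert sp[7] == pytest.approx(0.5)  # g3+g4 share species 7
        assert sp[6] == pytest.approx(0.5)

    def test_family_level_collapses_to_one_bucket(self, toy_taxonomy):
        comp = CompositionVector({"g1": 0.4, "g2": 0.3, "g3": 0.2}, 0.1)
        fam = project_composition(comp, toy_taxonomy, "family")
        assert fam[2] == pytest.approx(0.9)
        assert fam[0] == pytest.approx(0.1)
        assert sum(fam.values()) == pytest.approx(1.0)

    def test_matches_brute_force_groupby(self, toy_taxonomy):
        rng = np.random.default_rng(8)
        masses = rng.dirichlet(np.ones(4))
        genomes = ["g1", "g2", "g3", "g4"]
        comp = CompositionVector(dict(zip(genomes, masses)))
        for level in ("strain", "species", "genus", "family"):
            got = project_composition(comp, toy_taxonomy, level)
            expected = {}
            for g, m in zip(genomes, masses):
                t = toy_taxonomy.to_level(toy_taxonomy.strain_node_of(g), level)
                expected[t] = expected.get(t, 0.0) + m
            expected = {k: v for k, v in expected.items() if k != 0 or v > 0}
            assert got.keys() == expected.keys()
            for k in got:
                assert got[k] == pytest.approx(expected[k])


class TestIdentityFilter:
    def test_all_above_threshold_unchanged(self):
        comp = CompositionVector({"g1": 0.6, "g2": 0.4})
        out = filter_composition_by_identity(comp, {"g1": 0.9, "g2": 0.85}, 0.8)
        assert out.fractions == comp.fractions
        assert out.unassigned_fraction == 0.0

    def test_low_identity_mass_moves_to_unassigned(self, toy_taxonomy):
        comp = CompositionVector({"g1": 0.6, "g2": 0.4})
        out = filter_composition_by_identity(comp, {"g1": 0.9, "g2": 0.7}, 0.8)
        assert "g2" not in out.fractions
        assert out.unassigned_fraction == pytest.approx(0.4)
        assert out.total() == pytest.approx(1.0)
        # the removed strain's contribution disappears at higher levels too
        genus = project_composition(out, toy_taxonomy, "genus")
        assert genus[3] == pytest.approx(0.6)  # only g1's genus remains

    def test_threshold_zero_is_noop(self):
        comp = CompositionVector({"g1": 0.5, "g2": 0.5})
        out = filter_composition_by_identity(comp, {"g1": 0.1, "g2": 0.0}, 0.0)
        assert out.fractions == comp.fractions


class TestMixtureRecovery:
    def test_em_recovers_seeded_two_genome_mixture(self):
        """A (0.7, 0.3) mixture of divergent genomes is recovered within 0.02."""
        from minitax.index import IndexParams, build_index
        from minitax.mapping import map_reads
        from minitax.simulate import SimConfig, simulate_genomes, simulate_reads

        cfg = SimConfig(
            n_genomes=2, genome_length=40_000, divergence=0.1,
            total_bases=600_000, seed=31,
        )
        contigs, cmap, gtax, tax = simulate_genomes(cfg)
        truth = {"G001": 0.7, "G002": 0.3}
        reads = simulate_reads(contigs, cmap, truth, cfg, tax)
        idx = build_index(contigs, cmap, IndexParams())
        maps = map_reads([(r.read_id, r.sequence) for r in reads], idx)
        res = CompositionModel(maps, idx.genome_contig_lengths()).fit()
        realized = sum(r.genome_id == "G001" for r in reads) / len(reads)
        assert res.params["G001"] == pytest.approx(realized, abs=0.02)
        assert res.params["G001"] == pytest.approx(0.7, abs=0.05)


class TestMedianIdentities:
    def test_median_over_assigned_reads(self, sim_db, sim_mappings):
        res = CompositionModel(
            sim_mappings, sim_db["index"].genome_contig_lengths()
        ).fit()
        comp, assignments = res.finalize(taxonomy=sim_db["taxonomy"])
        med = median_identities(sim_mappings, assignments)
        for g, m in med.items():
            assert 0.8 <= m <= 1.0
        # identities should track the simulated accuracy
        overall = np.median(list(med.values()))
        assert abs(overall - sim_db["config"].accuracy) < 0.02
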