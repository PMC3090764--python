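"""Decision/minimization orchestration and haplotype reconstruction."""

import pytest

from pedphase2 import (Color, SimParams, count_recombinations, decide,
                       labels_to_haplotypes, minimize, mrhc_bruteforce,
                       simulate, transmission_cost)
from pedphase2.solver import PhasingError

from conftest import make_pedigree


class TestTransmissionCost:
    def test_parental_haplotype_costs_nothing(self):
        assert transmission_cost(((0, 1), (1, 0)), (0, 1)) == 0

    def test_recombinant_costs_one(self):
        assert transmission_cost(((0, 1), (1, 0)), (0, 0)) == 1
        assert transmission_cost(((0, 0), (1, 1)), (1, 0)) == 1

    def test_impossible_transmission(self):
        assert transmission_cost(((0, 0), (0, 0)), (1, 1)) is None


class TestLabelsToHaplotypes:
    def test_grey_member_phases(self):
        ped = make_pedigree([("a", None, None, (2, 2))])
        cfg = labels_to_haplotypes(ped, {"a": Color.GREEN})
        assert cfg.phased["a"] == ((0, 0), (1, 1))
        cfg = labels_to_haplotypes(ped, {"a": Color.RED})
        assert cfg.phased["a"] == ((0, 1), (1, 0))

    def test_unlabeled_member_unique_pair(self):
        ped = make_pedigree([("a", None, None, (0, 2))])
        cfg = labels_to_haplotypes(ped, {})
        assert cfg.phased["a"] == ((0, 0), (0, 1))

    def test_resolved_member_cannot_be_relabeled(self):
        ped = make_pedigree([("a", None, None, (0, 0))])
        with pytest.raises(PhasingError):
            labels_to_haplotypes(ped, {"a": Color.RED})

    def test_paternal_haplotype_first(self):
        ped = make_pedigree([
            ("f", None, None, (1, 1)),
            ("m", None, None, (0, 0)),
            ("c", "f", "m", (2, 2)),
        ])
        cfg = labels_to_haplotypes(ped, {"c": Color.GREEN})
        assert cfg.phased["c"] == ((1, 1), (0, 0))  # paternal 11 first
        assert cfg.origins["c"] == {"father": "h1", "mother": "h1"}
        assert cfg.events == []


class TestCountRecombinations:
    def test_crossover_between_sites_counts_once(self):
        # the parent's two haplotypes are 01/10; the child receives the
        # combined haplotype 00, a single crossover between the sites
        ped = make_pedigree([
            ("u", None, None, (2, 2)),
            ("w", None, None, (0, 0)),
            ("c", "u", "w", (0, 0)),
        ])
        cfg = labels_to_haplotypes(ped, {"u": Color.RED})
        count, events = count_recombinations(ped, cfg)
        assert count == 1 and events == [("c", "u")]
        assert cfg.origins["c"]["father"] == "recombinant"

    def test_witness_count_matches_k_star(self):
        for seed in range(40):
            ped, _ = simulate(SimParams(n_members=4 + seed % 9,
                                        recomb_rate=0.4, seed=seed))
            res = minimize(ped)
            count, _ = count_recombinations(ped, res.config)
            assert count == res.k_star

    def test_planted_truth_upper_bounds(self):
        for seed in range(20):
            ped, truth = simulate(SimParams(n_members=50, planted_events=4,
                                            seed=seed))
            assert minimize(ped).k_star <= len(truth.events)


class TestMinimize:
    def test_all_homozygous_is_zero(self):
        ped = make_pedigree([
            ("f", None, None, (0, 1)),
            ("m", None, None, (1, 0)),
            ("c", "f", "m", (2, 2)),
        ])
        res = minimize(ped)
        assert res.k_star == 0

    def test_negative_triangle_of_greys_costs_one(self):
        # three doubly heterozygous members, pairwise co-parents of
        # unlabeled children: the signed graph is a negative triangle
        ped = make_pedigree([
            ("a", None, None, (2, 2)),
            ("b", None, None, (2, 2)),
            ("c", None, None, (2, 2)),
            ("ab", "a", "b", (0, 2)),
            ("bc", "b", "c", (0, 2)),
            ("ca", "c", "a", (0, 2)),
        ])
        res = minimize(ped)
        assert res.k_star == 1
        assert len(res.config.events) == 1

    def test_matches_bruteforce(self):
        for seed in range(60):
            ped, _ = simulate(SimParams(
                n_members=3 + seed % 10, seed=seed,
                recomb_rate=(0.0, 0.35, 0.7)[seed % 3]))
            assert minimize(ped).k_star == mrhc_bruteforce(ped)

    def test_stats_reported(self):
        ped, _ = simulate(SimParams(n_members=100, seed=4))
        res = minimize(ped)
        assert res.stats["initial_vertices"] >= res.stats["reduced_vertices"]
        assert res.k_star == (res.stats["reduction_cost"]
                              + res.stats["reduced_line_index"])


class TestDecide:
    def test_zero_recombination_simulation_at_k0(self):
        ped, _ = simulate(SimParams(n_members=40, seed=11))
        yes, config = decide(ped, 0)
        assert yes and count_recombinations(ped, config)[0] == 0

    def test_agreement_with_minimize_and_monotone(self):
        for seed in range(25):
            ped, _ = simulate(SimParams(n_members=4 + seed % 8,
                                        recomb_rate=0.5, seed=seed))
            k_star = minimize(ped).k_star
            answers = [decide(ped, k)[0] for k in range(k_star + 2)]
            assert answers == [k >= k_star for k in range(k_star + 2)]

    def test_witness_within_budget(self):
        ped, _ = simulate(SimParams(n_members=30, planted_events=3, seed=2))
        k_star = minimize(ped).k_star
        yes, config = decide(ped, k_star)
        assert yes
        assert count_recombinations(ped, config)[0] <= k_star

    def test_negative_budget_rejected(self):
        ped, _ = simulate(SimParams(n_members=10, seed=0))
        with pytest.raises(ValueError):
            decide(ped, -1)
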