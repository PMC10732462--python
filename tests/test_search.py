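import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgtrace import (
    Alignment,
    CriteriaConfig,
    PhyloTree,
    SearchHit,
    SequenceRecord,
    TaxonRecord,
    align_to_profile,
    build_profile,
    calibrate_evalue,
    combine_balanced_seed,
    consensus_sequence,
    filter_ingroup,
    iterate_search,
    make_decoys,
    score_sequence,
    search_database,
    trim_gappy_columns,
)
from hgtrace.simulate import generate_domain_table, synthetic_family

from conftest import random_tree


def _random_seq(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


class TestTrimming:
    def test_all_gap_column_always_removed(self):
        aln = Alignment([("a", "A-C"), ("b", "A-C")])
        assert trim_gappy_columns(aln, 0.01).length == 2

    def test_boundary_arithmetic_at_one_fifth(self):
        # 10 rows, one residue: occupancy 0.1 < 0.2 -> removed;
        # two residues: 0.2 >= 0.2 -> kept
        rows = [(f"s{i}", ("A" if i < 1 else "-") + ("A" if i < 2 else "-") + "C")
                for i in range(10)]
        trimmed = trim_gappy_columns(Alignment(rows), 0.2)
        assert trimmed.length == 2

    def test_gapless_column_always_retained(self):
        aln = Alignment([("a", "A"), ("b", "C")])
        assert trim_gappy_columns(aln, 1.0).length == 1

    def test_zero_survivors_is_an_error(self):
        aln = Alignment([("a", "A-"), ("b", "-A"), ("c", "--"), ("d", "--")])
        with pytest.raises(ValueError, match="keep_fraction"):
            trim_gappy_columns(aln, 0.9)

    def test_column_set_monotone_in_threshold(self, toy_alignment):
        previous = None
        for x in (0.1, 0.3, 0.5, 0.8, 1.0):
            try:
                cols = trim_gappy_columns(toy_alignment, x).length
            except ValueError:
                cols = 0
            if previous is not None:
                assert cols <= previous
            previous = cols


class TestProfile:
    def test_laplace_rule_hand_value(self):
        # column with A:2, C:2 at alpha=1: P(A) = (2+1)/(4+20) = 0.125
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "C"), ("d", "C")])
        prof = build_profile(aln, pseudocount_alpha=1.0)
        assert prof.emissions[0, 0] == pytest.approx(0.125)
        assert prof.emissions[0, 1] == pytest.approx(0.125)

    def test_alpha_to_zero_limit_concentrates_on_consensus(self):
        aln = Alignment([("a", "A"), ("b", "A"), ("c", "A")])
        prof = build_profile(aln, pseudocount_alpha=1e-9)
        assert prof.emissions[0].argmax() == 0
        assert prof.emissions[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_emissions_normalised_per_column(self, toy_alignment):
        prof = build_profile(toy_alignment)
        assert np.allclose(prof.emissions.sum(axis=1), 1.0)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            Alignment([])


class TestScoring:
    def test_consensus_achieves_maximum_for_its_length(self):
        rng = random.Random(1)
        aln = Alignment([(f"s{i}", _random_seq(rng, 12)) for i in range(5)])
        prof = build_profile(aln)
        consensus = consensus_sequence(prof)
        max_score = prof.log_odds.max(axis=1).sum()
        assert score_sequence(prof, consensus) == pytest.approx(max_score)

    def test_toy_profile_hand_summed(self):
        aln = Alignment([("a", "ACD"), ("b", "ACD"), ("c", "AMD")])
        prof = build_profile(aln)
        expected = (prof.log_odds[0, 0] + prof.log_odds[1, 1]
                    + prof.log_odds[2, 2])  # A, C, D columns
        assert score_sequence(prof, "ACD") == pytest.approx(expected)

    def test_matches_exhaustive_window_enumeration(self):
        rng = random.Random(2)
        aln = Alignment([(f"s{i}", _random_seq(rng, 6)) for i in range(4)])
        prof = build_profile(aln)
        for _ in range(20):
            seq = _random_seq(rng, rng.randint(6, 15))
            brute = max(
                sum(prof.log_odds[j, "ACDEFGHIKLMNPQRSTVWY".index(seq[s + j])]
                    for j in range(6))
                for s in range(len(seq) - 5)
            )
            assert score_sequence(prof, seq) == pytest.approx(brute)

    def test_sequence_shorter_than_profile_rejected(self):
        aln = Alignment([("a", "ACDEF")])
        prof = build_profile(aln)
        with pytest.raises(ValueError, match="shorter"):
            score_sequence(prof, "AC")


class TestCalibration:
    @pytest.fixture
    def calibrated(self):
        rng = random.Random(3)
        aln = Alignment([(f"s{i}", _random_seq(rng, 10)) for i in range(5)])
        prof = build_profile(aln)
        decoys = [SequenceRecord(f"d{i}", f"t{i}", _random_seq(rng, 25))
                  for i in range(200)]
        return prof, calibrate_evalue(prof, decoys, db_size=500)

    def test_add_one_bound_above_all_decoys(self, calibrated):
        _, cal = calibrated
        n = len(cal.decoy_scores)
        assert cal.e_value(float(cal.decoy_scores[-1]) + 1e-9) <= 500 / (n + 1)

    def test_score_below_all_decoys_gives_db_size(self, calibrated):
        _, cal = calibrated
        assert cal.e_value(-1e9) == pytest.approx(500)

    def test_monotone_non_increasing_over_grid(self, calibrated):
        _, cal = calibrated
        values = [cal.e_value(s) for s in np.linspace(-30, 60, 300)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(v > 0 for v in values)

    def test_too_few_decoys_rejected(self, calibrated):
        prof, _ = calibrated
        few = [SequenceRecord("d", "t", "ACDEFGHIKLMN")] * 5
        with pytest.raises(ValueError, match="100"):
            calibrate_evalue(prof, few, db_size=10)


class TestSearchDatabase:
    def _setup(self, n_per_species, n_species=1, cap=10):
        # members of a sharp family, several sequences per species
        aln, db, _, labels = synthetic_family(7, n_members=n_per_species * n_species,
                                              n_decoys=0)
        members = [s for s in db if labels[s.seq_id] == "member"]
        seqs = [
            SequenceRecord(s.seq_id, f"sp{(i % n_species):02d}", s.residues)
            for i, s in enumerate(members)
        ]
        taxa = [TaxonRecord(f"sp{i:02d}", "x", "eukaryote", "Metazoa", "s")
                for i in range(n_species)]
        prof = build_profile(aln)
        cal = calibrate_evalue(prof, make_decoys(seqs, seed=1), db_size=len(seqs))
        cfg = CriteriaConfig(hit_cap_per_species=cap)
        return prof, seqs, taxa, cfg, cal

    def test_cap_truncates_to_best_evalues(self):
        prof, seqs, taxa, cfg, cal = self._setup(15)
        hits = search_database(prof, seqs, taxa, cfg, cal)
        assert len(hits) == 10
        all_hits = search_database(prof, seqs, taxa,
                                   CriteriaConfig(hit_cap_per_species=100), cal)
        best_ten = sorted(all_hits, key=lambda h: (h.e_value, h.seq_id))[:10]
        assert {h.seq_id for h in hits} == {h.seq_id for h in best_ten}

    def test_under_cap_all_retained(self):
        prof, seqs, taxa, cfg, cal = self._setup(3)
        assert len(search_database(prof, seqs, taxa, cfg, cal)) == 3

    def test_equal_evalue_tie_breaks_lexicographically(self):
        prof, seqs, taxa, cfg, cal = self._setup(4, cap=2)
        # force identical scores: all sequences identical
        clones = [SequenceRecord(f"z{i}", "sp00", seqs[0].residues)
                  for i in range(4)]
        hits = search_database(prof, clones, taxa, cfg, cal)
        assert [h.seq_id for h in hits] == ["z0", "z1"]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 4), st.floats(1e-9, 5e-4)),
                    min_size=1, max_size=40))
    def test_cap_never_exceeded_property(self, table):
        # random hit tables: no taxon ever contributes more than the cap
        cfg = CriteriaConfig(hit_cap_per_species=3)
        hits = [SearchHit(f"s{i}", f"t{taxon}", 0.0, e)
                for i, (taxon, e) in enumerate(table)]
        by_taxon = {}
        for h in hits:
            by_taxon.setdefault(h.taxon_id, []).append(h)
        capped = []
        for t in sorted(by_taxon):
            capped.extend(sorted(by_taxon[t],
                                 key=lambda h: (h.e_value, h.seq_id))[:3])
        counts = {}
        for h in capped:
            counts[h.taxon_id] = counts.get(h.taxon_id, 0) + 1
        assert all(c <= 3 for c in counts.values())


class TestBalancedSeed:
    def _side(self, rng, n, prefix):
        tree = random_tree(rng, n, labels=[f"{prefix}{i:03d}" for i in range(n)])
        seqs = [SequenceRecord(l, l, _random_seq(rng, 30))
                for l in sorted(tree.leaf_set)]
        return seqs, tree

    def test_both_sides_downsampled_to_k(self):
        rng = random.Random(4)
        cfg = CriteriaConfig(seed_k_each=5)
        bact = self._side(rng, 20, "b")
        euk = self._side(rng, 20, "e")
        combined = combine_balanced_seed(bact, euk, cfg)
        assert len(combined) == 10
        assert sum(1 for s in combined if s.seq_id.startswith("b")) == 5

    def test_small_side_taken_whole(self):
        rng = random.Random(5)
        cfg = CriteriaConfig(seed_k_each=10)
        bact = self._side(rng, 4, "b")
        euk = self._side(rng, 30, "e")
        combined = combine_balanced_seed(bact, euk, cfg)
        assert sum(1 for s in combined if s.seq_id.startswith("b")) == 4
        assert sum(1 for s in combined if s.seq_id.startswith("e")) == 10

    def test_output_is_subset_of_inputs(self):
        rng = random.Random(6)
        cfg = CriteriaConfig(seed_k_each=3)
        bact = self._side(rng, 8, "b")
        euk = self._side(rng, 8, "e")
        ids = {s.seq_id for s in combine_balanced_seed(bact, euk, cfg)}
        assert ids <= {s.seq_id for s in bact[0]} | {s.seq_id for s in euk[0]}

    def test_id_mismatch_rejected(self):
        rng = random.Random(7)
        seqs, tree = self._side(rng, 6, "b")
        with pytest.raises(ValueError, match="mismatch"):
            combine_balanced_seed((seqs[:-1], tree), self._side(rng, 6, "e"),
                                  CriteriaConfig())


class TestIterateSearch:
    def _mock_backend(self, script):
        """script: list of per-round seq_id lists."""
        def backend(round_index, aln):
            ids = script[min(round_index, len(script)) - 1]
            return [SearchHit(i, f"tax_{i}", 10.0, 1e-6) for i in ids]
        return backend

    def test_scripted_rounds_saturate(self, config):
        backend = self._mock_backend([["a", "b"], ["a", "b", "c"], ["a", "b", "c"]])
        rounds = iterate_search(
            Alignment([("seed", "ACD")]), [], [], set(), config,
            max_rounds=10, backend=backend,
        )
        assert len(rounds) == 3
        assert rounds[-1].stop_reason == "saturated"
        cumulative = set()
        for r in rounds:
            cumulative |= set(r.new_seq_ids)
        assert cumulative == {"a", "b", "c"}

    def test_first_round_only_seed_members_stops_immediately(self, config):
        backend = self._mock_backend([["seed"]])
        rounds = iterate_search(
            Alignment([("seed", "ACD")]), [], [], set(), config,
            max_rounds=5, backend=backend,
        )
        assert len(rounds) == 1 and rounds[0].stop_reason == "saturated"

    def test_outgroup_hit_stops_with_contamination(self, config):
        backend = self._mock_backend([["a"], ["a", "PAP_1"]])
        rounds = iterate_search(
            Alignment([("seed", "ACD")]), [], [], {"PAP_1"}, config,
            max_rounds=5, backend=backend,
        )
        assert rounds[-1].stop_reason == "contamination"
        assert rounds[-1].contamination_flag

    def test_max_rounds_stop(self, config):
        script = [[f"x{i}"] for i in range(10)]
        backend = self._mock_backend([list(itertools.chain(*script[:i + 1]))
                                      for i in range(10)])
        rounds = iterate_search(
            Alignment([("seed", "ACD")]), [], [], set(), config,
            max_rounds=4, backend=backend,
        )
        assert len(rounds) == 4 and rounds[-1].stop_reason == "max_rounds"

    def test_cumulative_hits_non_decreasing_real_backend(self, config):
        aln, db, taxa, _ = synthetic_family(0)
        rounds = iterate_search(aln, db, taxa, set(), config, max_rounds=6)
        sizes = []
        seen = set()
        for r in rounds:
            seen |= set(r.new_seq_ids)
            sizes.append(len(seen))
        assert sizes == sorted(sizes)
        assert rounds[-1].stop_reason in ("saturated", "max_rounds")

    def test_member_decoy_separation_at_default_conditions(self, config):
        # regression property of the generator + scorer pair: >= 90% of true
        # members and <= 5% of decoys pass the 1e-3 cutoff
        aln, db, taxa, labels = synthetic_family(0)
        prof = build_profile(aln)
        cal = calibrate_evalue(prof, make_decoys(db, seed=1), db_size=len(db))
        hit_ids = {h.seq_id for h in search_database(prof, db, taxa, config, cal)}
        members = {s for s, l in labels.items() if l == "member"}
        decoys = {s for s, l in labels.items() if l == "decoy"}
        assert len(hit_ids & members) / len(members) >= 0.9
        assert len(hit_ids & decoys) / len(decoys) <= 0.05


class TestAlignToProfile:
    def test_returns_best_window(self):
        aln = Alignment([("a", "ACDEF"), ("b", "ACDEF")])
        prof = build_profile(aln)
        seq = SequenceRecord("q", "t", "WWACDEFWW")
        assert align_to_profile(prof, seq) == "ACDEF"


class TestFilterIngroup:
    @pytest.fixture
    def setting(self):
        tree = PhyloTree.from_string(
            "((OUT1:1,OUT2:1):1,((ref1:1,ref2:1):1,(hitA:1,(hitB:1,ref3:1):1):1):1);"
        )
        seqs = [SequenceRecord("hitA", "t1", "ACDEF"),
                SequenceRecord("hitB", "t2", "ACDEF")]
        domains = generate_domain_table(seqs, {"hitA": ["PF10421"]}, seed=3)
        hits = [SearchHit("hitA", "t1", 10.0, 1e-5),
                SearchHit("hitB", "t2", 9.0, 1e-5)]
        return tree, domains, hits

    def test_no_family_domain_removed(self, setting):
        tree, domains, hits = setting
        kept, log = filter_ingroup(hits, tree, domains, {"PF10421"},
                                   {"OUT1", "OUT2"})
        assert [h.seq_id for h in kept] == ["hitA"]
        assert ("hitB", "no_family_domain") in log

    def test_hit_branching_with_outgroup_removed(self):
        tree = PhyloTree.from_string(
            "(((OUT1:1,hitA:1):1,OUT2:1):1,((ref1:1,ref2:1):1,(hitB:1,ref3:1):1):1);"
        )
        seqs = [SequenceRecord("hitA", "t1", "ACDEF"),
                SequenceRecord("hitB", "t2", "ACDEF")]
        domains = generate_domain_table(
            seqs, {"hitA": ["PF10421"], "hitB": ["PF10421"]}, seed=3
        )
        hits = [SearchHit("hitA", "t1", 10.0, 1e-5),
                SearchHit("hitB", "t2", 9.0, 1e-5)]
        kept, log = filter_ingroup(hits, tree, domains, {"PF10421"},
                                   {"OUT1", "OUT2"})
        assert [h.seq_id for h in kept] == ["hitB"]
        assert ("hitA", "outside_ingroup_clade") in log

    def test_family_domain_inside_clade_retained(self, setting):
        tree, domains, hits = setting
        kept, _ = filter_ingroup(hits[:1], tree, domains, {"PF10421"},
                                 {"OUT1", "OUT2"})
        assert [h.seq_id for h in kept] == ["hitA"]

    def test_outgroup_missing_from_tree_rejected(self, setting):
        tree, domains, hits = setting
        with pytest.raises(ValueError, match="outgroup"):
            filter_ingroup(hits, tree, domains, {"PF10421"}, {"NOT_THERE"})
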