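"""Lineage matrix, neighbor-joining trees, branch assignment and
contribution estimates."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetallineage.lineage import (
    ROOT_LABEL, BinaryMutationMatrix, branch_contribution, build_matrix,
    build_tree, clade_sets, compare_branches, early_mutations, first_branches,
    parse_newick, rooted_rf_distance, write_newick,
)
from fetallineage.synthetic import (
    CohortConfig, bulk_allele_counts, simulate_embryo, truth_matrix,
)

from conftest import SMALL_GENOME, make_call, make_record


def matrix_from_profiles(profiles: dict) -> BinaryMutationMatrix:
    """Profiles map clone -> set of mutation labels."""
    muts = sorted(set().union(*profiles.values()))
    frame = pd.DataFrame(0, index=sorted(profiles) + [ROOT_LABEL],
                         columns=muts, dtype=int)
    for clone, ms in profiles.items():
        frame.loc[clone, sorted(ms)] = 1
    meta = pd.DataFrame(
        [{"mutation": m, "contig": "chr1", "pos": i + 1, "ref": "A", "alt": "T"}
         for i, m in enumerate(muts)]).set_index("mutation")
    return BinaryMutationMatrix(matrix=frame, metadata=meta)


class TestBuildMatrix:
    def test_shared_and_private_counts(self):
        """2 clones sharing 3 variants with 5/4 private ones -> 3x12
        matrix including the root row."""
        shared_keys = [("chr1", p, "A", "T") for p in (1, 2, 3)]
        a_priv = [("chr1", p, "A", "T") for p in range(10, 15)]
        b_priv = [("chr1", p, "A", "T") for p in range(20, 24)]
        clonal = {
            "A": [make_record(pos=k[1]) for k in shared_keys + a_priv],
            "B": [make_record(pos=k[1]) for k in shared_keys + b_priv],
        }
        bm = build_matrix([], clonal)
        assert bm.matrix.shape == (3, 12)
        assert (bm.matrix.loc[ROOT_LABEL] == 0).all()

    def test_column_of_ones_allowed(self):
        clonal = {"A": [make_record(pos=5)], "B": [make_record(pos=5)]}
        bm = build_matrix([], clonal)
        assert bm.matrix.drop(index=ROOT_LABEL).to_numpy().sum() == 2

    def test_block_diagonal_private_sets(self):
        clonal = {"A": [make_record(pos=p) for p in (1, 2)],
                  "B": [make_record(pos=p) for p in (11, 12)]}
        bm = build_matrix([], clonal)
        sub = bm.matrix.drop(index=ROOT_LABEL)
        assert (sub.sum(axis=0) == 1).all()

    def test_single_clone_raises(self):
        with pytest.raises(ValueError):
            build_matrix([], {"A": [make_record()]})


class TestBuildTree:
    def test_two_cherries_with_internal_lengths(self):
        """{A,B} share 5, {C,D} share 7, 10 private each -> ((A,B),(C,D))
        with internal branches of 5 and 7 mutations."""
        prof = {
            "A": {f"ab{i}" for i in range(5)} | {f"a{i}" for i in range(10)},
            "B": {f"ab{i}" for i in range(5)} | {f"b{i}" for i in range(10)},
            "C": {f"cd{i}" for i in range(7)} | {f"c{i}" for i in range(10)},
            "D": {f"cd{i}" for i in range(7)} | {f"d{i}" for i in range(10)},
        }
        lt = build_tree(matrix_from_profiles(prof))
        clades = clade_sets(lt.tree)
        assert frozenset({"A", "B"}) in clades and frozenset({"C", "D"}) in clades
        lens = lt.branch_lengths()
        by_clade = {frozenset(l.name for l in n.tips()): n.name
                    for n in lt.tree.traverse(include_self=False)
                    if not n.is_tip()}
        assert lens[by_clade[frozenset({"A", "B"})]] == 5
        assert lens[by_clade[frozenset({"C", "D"})]] == 7
        assert not lt.conflicts

    def test_all_zero_matrix_star_tree(self):
        frame = pd.DataFrame(0, index=["A", "B", "C", ROOT_LABEL],
                             columns=["m1"], dtype=int)
        bm = BinaryMutationMatrix(matrix=frame, metadata=pd.DataFrame())
        lt = build_tree(bm)
        assert all(v == 0 for v in lt.branch_lengths().values())

    def test_trunk_mutations_assigned_above_first_split(self):
        prof = {
            "A": {"t1", "t2", "a1"},
            "B": {"t1", "t2", "b1"},
            "C": {"t1", "t2", "c1"},
        }
        lt = build_tree(matrix_from_profiles(prof))
        trunk = [n for n in lt.tree.traverse(include_self=False)
                 if set(l.name for l in n.tips()) == {"A", "B", "C"}]
        assert len(trunk) == 1
        assert sorted(lt.branch_mutations[trunk[0].name]) == ["t1", "t2"]
        assert not lt.conflicts

    def test_incompatible_carrier_set_is_conflict(self):
        prof = {
            "A": {"ab1", "ab2", "ab3", "ac"},
            "B": {"ab1", "ab2", "ab3"},
            "C": {"cd1", "cd2", "cd3", "ac"},
            "D": {"cd1", "cd2", "cd3"},
        }
        lt = build_tree(matrix_from_profiles(prof))
        assert lt.conflicts == ["ac"]
        total = sum(lt.branch_lengths().values()) + len(lt.conflicts)
        assert total == lt.matrix.matrix.shape[1]


def _all_rooted_topologies(leaves):
    """Every rooted binary topology on the given leaves, as clade sets."""
    if len(leaves) == 1:
        yield frozenset()
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(l for l in rest if l not in left_rest)
            if not right:
                continue
            for lc in _all_rooted_topologies(left):
                for rc in _all_rooted_topologies(right):
                    clades = set(lc) | set(rc)
                    if len(left) > 1:
                        clades.add(frozenset(left))
                    if len(right) > 1:
                        clades.add(frozenset(right))
                    yield frozenset(clades)


class TestPerfectPhylogenyOracle:
    """On conflict-free matrices the NJ tree must equal the unique
    fully-resolved perfect phylogeny found by exhaustive enumeration."""

    @pytest.mark.parametrize("seed", range(6))
    def test_nj_matches_enumeration(self, seed, small_reference):
        cfg = CohortConfig(n_donors_d21=1, n_donors_t21=0, clones_per_donor=5,
                           pre_gastrulation_divisions=4, mu_early=10.0,
                           n_germline=0, n_invitro=0, error_rate=0.0,
                           indels_per_clone=0.0, genome=SMALL_GENOME,
                           seed=1000 + seed)
        donor = simulate_embryo(cfg, reference=small_reference).donors[0]
        bm = truth_matrix(donor)
        sub = bm.matrix.drop(index=ROOT_LABEL)
        carrier_clades = {
            frozenset(sub.index[sub[m] == 1]) for m in sub.columns}
        nontrivial = {c for c in carrier_clades if 1 < len(c) < len(sub.index)}
        lt = build_tree(bm)
        assert not lt.conflicts
        # enumeration oracle: all topologies compatible with the carrier sets
        compatible = [clades for clades in
                      _all_rooted_topologies(tuple(sub.index))
                      if nontrivial <= clades]
        # NJ clades must be compatible, and where the data fully resolve
        # the topology, unique
        assert clade_sets(lt.tree) <= min(compatible, key=len) or \
            clade_sets(lt.tree) in compatible
        if len(nontrivial) == len(sub.index) - 2:   # fully resolved signal
            assert clade_sets(lt.tree) == nontrivial


class TestTreeRecovery:
    def test_rf_zero_against_truth(self, small_reference):
        cfg = CohortConfig(n_donors_d21=1, n_donors_t21=0, clones_per_donor=5,
                           mu_early=10.0, n_germline=0, n_invitro=0,
                           error_rate=0.0, indels_per_clone=0.0,
                           genome=SMALL_GENOME, seed=77)
        donor = simulate_embryo(cfg, reference=small_reference).donors[0]
        lt = build_tree(truth_matrix(donor))
        truth = parse_newick(donor.tree_newick)
        assert rooted_rf_distance(lt.tree, truth) == 0


class TestEarlyMutations:
    class SV:
        def __init__(self, key, present, bulk_vaf):
            self.record = make_record(pos=key)
            self.present = tuple(present)
            self.candidate_present = tuple(present)
            self.bulk_vafs = {"bulk1": bulk_vaf}

    def test_bulk_subclonal_variants_are_early(self):
        table = [self.SV(1, ("A", "B"), 0.45), self.SV(2, ("A",), 0.0),
                 self.SV(3, ("B",), 0.1)]
        early, per_clone = early_mutations(table, "bulk1")
        assert {k[1] for k in early} == {1, 3}
        assert per_clone == {"A": 1, "B": 2}

    def test_missing_bulk_raises(self):
        with pytest.raises(ValueError):
            early_mutations([self.SV(1, ("A",), 0.2)], "nope")


class TestBranchContribution:
    def _tree(self):
        prof = {"A": {"m1", "m2", "m3", "a1"}, "B": {"m1", "m2", "m3", "b1"},
                "C": {"c1"}}
        return build_tree(matrix_from_profiles(prof))

    def _branch_of(self, lt, muts):
        for name, ms in lt.branch_mutations.items():
            if set(ms) == muts:
                return name
        raise AssertionError

    def test_double_median_vaf_rule(self):
        lt = self._tree()
        counts = {"m1": (24, 8), "m2": (24, 8), "m3": (24, 8),
                  "a1": (30, 0), "b1": (30, 0), "c1": (30, 0)}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        assert out.loc[br, "contribution"] == pytest.approx(0.5)
        assert not out.loc[br, "subdivided"]

    def test_zero_vaf_mutations_not_used_for_median(self):
        lt = self._tree()
        counts = {"m1": (30, 0), "m2": (24, 6), "m3": (21, 9),
                  "a1": (30, 0), "b1": (30, 0), "c1": (30, 0)}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        assert out.loc[br, "n_contributing"] == 2
        assert out.loc[br, "contribution"] == pytest.approx(0.5)  # 2 x 0.25

    def test_heterogeneous_vafs_subdivide_branch(self):
        lt = self._tree()
        counts = {"m1": (5, 27), "m2": (24, 6), "m3": (29, 1),
                  "a1": (30, 0), "b1": (30, 0), "c1": (30, 0)}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        assert out.loc[br, "subdivided"]
        assert len(out.loc[br, "segments"]) == 3

    def test_homogeneous_counts_single_segment(self):
        """Counts 10/30 vs 11/29 vs 9/31 are chi-square homogeneous."""
        lt = self._tree()
        counts = {"m1": (30, 10), "m2": (29, 11), "m3": (31, 9),
                  "a1": (30, 0), "b1": (30, 0), "c1": (30, 0)}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        oracle = stats.chi2_contingency(np.array([[10, 11, 9], [30, 29, 31]]))[1]
        assert out.loc[br, "chi2_p"] == pytest.approx(oracle)
        assert oracle > 0.05 and not out.loc[br, "subdivided"]

    def test_no_contributing_mutation_is_undefined(self):
        lt = self._tree()
        counts = {m: (30, 0) for m in ("m1", "m2", "m3", "a1", "b1", "c1")}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        assert np.isnan(out.loc[br, "contribution"])

    def test_contribution_capped_at_one(self):
        lt = self._tree()
        counts = {"m1": (10, 25), "m2": (10, 25), "m3": (10, 25),
                  "a1": (30, 0), "b1": (30, 0), "c1": (30, 0)}
        out = branch_contribution(lt, counts)
        br = self._branch_of(lt, {"m1", "m2", "m3"})
        assert out.loc[br, "contribution"] == 1.0


class TestCompareBranches:
    def _tree(self):
        prof = {"A": {"m1", "a1"}, "B": {"m1", "b1"}, "C": {"c1", "c2"}}
        return build_tree(matrix_from_profiles(prof))

    def test_identical_counts_p_one(self):
        lt = self._tree()
        counts = {"m1": (30, 30), "c1": (15, 15), "c2": (15, 15),
                  "a1": (30, 0), "b1": (30, 0)}
        fb = first_branches(lt)
        p, _ = compare_branches(lt, counts, fb[0], fb[1])
        assert p == pytest.approx(1.0)

    def test_strong_asymmetry_detected_vs_hypergeometric_oracle(self):
        lt = self._tree()
        counts = {"m1": (30, 30), "c1": (30, 3), "c2": (25, 2),
                  "a1": (30, 0), "b1": (30, 0)}
        fb = first_branches(lt)
        p, table = compare_branches(lt, counts, fb[0], fb[1])
        assert p < 0.001
        # independent oracle: hypergeometric enumeration of the 2x2 table
        (a, b), (c, dd) = table
        M, n, N = a + b + c + dd, a + b, a + c
        rv = stats.hypergeom(M, n, N)
        p_obs = rv.pmf(a)
        oracle = sum(rv.pmf(k) for k in range(max(0, n + N - M), min(n, N) + 1)
                     if rv.pmf(k) <= p_obs * (1 + 1e-9))
        assert p == pytest.approx(oracle, rel=1e-6)

    def test_empty_branch_raises(self):
        lt = self._tree()
        counts = {"m1": (30, 30), "c1": (30, 0), "c2": (30, 0),
                  "a1": (30, 0), "b1": (30, 0)}
        fb = first_branches(lt)
        with pytest.raises(ValueError):
            compare_branches(lt, counts, fb[0], fb[1])


class TestNewickOutput:
    def test_round_trip_topology_and_lengths(self, tmp_path):
        prof = {"A": {"m1", "a1"}, "B": {"m1", "b1"}, "C": {"c1"}}
        lt = build_tree(matrix_from_profiles(prof))
        path = tmp_path / "t.nwk"
        write_newick(lt, path, sidecar=False)
        back = parse_newick(path.read_text())
        assert rooted_rf_distance(lt.tree, back) == 0
        assert sorted(l.name for l in back.tips()) == ["A", "B", "C"]
        lens = sorted(n.length for n in back.traverse(include_self=False)
                      if n.length is not None)
        assert lens == sorted(
            n.length for n in lt.tree.traverse(include_self=False)
            if n.length is not None)

    def test_polytomy_emitted_legally(self, tmp_path):
        frame = pd.DataFrame(0, index=["A", "B", "C", ROOT_LABEL],
                             columns=["m"], dtype=int)
        bm = BinaryMutationMatrix(matrix=frame, metadata=pd.DataFrame())
        lt = build_tree(bm)
        path = tmp_path / "star.nwk"
        write_newick(lt, path, sidecar=False)
        assert sorted(l.name for l in parse_newick(path.read_text()).tips()) \
            == ["A", "B", "C"]
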