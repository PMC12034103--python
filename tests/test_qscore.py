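"""Pairwise similarity backends, subcluster statistics, and Q-scores."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopclust.geometry import loop_centers
from loopclust.qscore import (
    D0_ANGSTROM,
    PairTable,
    SubclusterStats,
    pair_similarity,
    q_scores,
    subcluster_stats,
)
from loopclust.synthetic import NoiseSpec, builtin_templates, sample_loop

from conftest import make_loop


def _loops(template_idx=0, n=3, seed=0):
    t = builtin_templates()[template_idx]
    return [sample_loop(t, NoiseSpec(seed=seed), instance_seed=k) for k in range(n)]


class TestInteractionBackend:
    def test_self_similarity_hand_values(self, hand_loop):
        # 2 matched pairs, 1 matched stacking: 2*2 + 0.5*1 = 4.5
        score, rmsd, length = pair_similarity(hand_loop, hand_loop, "interaction_internal")
        assert score == pytest.approx(4.5)
        assert length == 2
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_reversed_annotations_still_match(self):
        a = make_loop(pairs=((1, 4, "tHS"),), stacks=())
        b = make_loop(pairs=((4, 1, "tSH"),), stacks=())  # same pair, flipped
        score, _, length = pair_similarity(a, b, "interaction_internal")
        assert score == pytest.approx(2.0)
        assert length == 1

    def test_no_common_classes(self):
        a = make_loop(pairs=((0, 5, "cWW"),), stacks=())
        b = make_loop(pairs=((0, 5, "tHH"),), stacks=())
        score, rmsd, length = pair_similarity(a, b, "interaction_internal")
        assert (score, rmsd, length) == (0.0, 0.0, 0)

    def test_stacks_alone_score_half(self):
        a = make_loop(pairs=(), stacks=((1, 2, "upward"),))
        b = make_loop(pairs=(), stacks=((2, 1, "downward"),))  # same physical stack
        score, _, length = pair_similarity(a, b, "interaction_internal")
        assert score == pytest.approx(0.5)
        assert length == 0

    def test_symmetry(self):
        a, b = _loops(0, 2, seed=5)
        assert pair_similarity(a, b, "interaction_internal") == pytest.approx(
            pair_similarity(b, a, "interaction_internal")
        )


class TestStructureBackend:
    def test_self_similarity(self, hand_loop):
        score, rmsd, length = pair_similarity(hand_loop, hand_loop, "structure_internal")
        assert score == pytest.approx(1.0)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert length == hand_loop.n_nucleotides

    def test_rigid_motion_invariance(self, hand_loop):
        moved = make_loop()
        R = Rotation.random(random_state=0).as_matrix()
        for nt in moved.nucleotides:
            nt.backbone_coords = {
                a: np.asarray(x) @ R.T + [10.0, 0.0, -4.0]
                for a, x in nt.backbone_coords.items()
            }
        score, rmsd, _ = pair_similarity(hand_loop, moved, "structure_internal")
        assert score == pytest.approx(1.0, abs=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-8)

    def test_matches_independent_superposition_oracle(self):
        a, b = _loops(1, 2, seed=2)
        score, rmsd, length = pair_similarity(a, b, "structure_internal")
        P, Q = loop_centers(a), loop_centers(b)
        k = min(len(P), len(Q))
        Pc = P[:k] - P[:k].mean(axis=0)
        Qc = Q[:k] - Q[:k].mean(axis=0)
        rot, _ = Rotation.align_vectors(Qc, Pc)
        dists = np.linalg.norm(rot.apply(Pc) - Qc, axis=1)
        assert length == k
        assert rmsd == pytest.approx(np.sqrt(np.mean(dists**2)), abs=1e-6)
        assert score == pytest.approx(
            np.mean(1.0 / (1.0 + (dists / D0_ANGSTROM) ** 2)), abs=1e-6
        )


class TestPairTable:
    def test_order_insensitive_lookup(self):
        t = PairTable([("a", "b", "structure", 0.9, 1.2, 6)])
        assert t.lookup("b", "a", "structure") == (0.9, 1.2, 6.0)

    def test_missing_pair_is_an_error(self):
        t = PairTable()
        with pytest.raises(KeyError, match="structure"):
            t.lookup("a", "b", "structure")

    def test_from_tsv(self, tmp_path):
        path = tmp_path / "pairs.tsv"
        path.write_text("# header\na\tb\tinteraction\t4.5\t0.3\t2\n")
        t = PairTable.from_tsv(path)
        assert t.lookup("a", "b", "interaction") == (4.5, 0.3, 2.0)

    def test_external_backend_uses_table(self, hand_loop):
        other = make_loop(location="2ZZZ_B:5-10")
        t = PairTable([(hand_loop.loop_id, other.loop_id, "structure", 0.7, 2.0, 6)])
        out = pair_similarity(hand_loop, other, "external_structure", t)
        assert out == (0.7, 2.0, 6.0)
        with pytest.raises(ValueError, match="PairTable"):
            pair_similarity(hand_loop, other, "external_structure")

    def test_unknown_backend(self, hand_loop):
        with pytest.raises(ValueError, match="backend"):
            pair_similarity(hand_loop, hand_loop, "rmsd_only")


class TestSubclusterStats:
    def test_singleton_flagged_and_zeroed(self, hand_loop):
        s = subcluster_stats("sc0", [hand_loop])
        assert s.singleton
        assert s.m == 1
        assert s.sx_score == s.tm_score == 0.0

    def test_averages_match_manual_pair_means(self):
        members = _loops(0, 3, seed=1)
        s = subcluster_stats("sc0", members)
        sx = [pair_similarity(a, b, "interaction_internal") for a, b in combinations(members, 2)]
        tm = [pair_similarity(a, b, "structure_internal") for a, b in combinations(members, 2)]
        assert s.m == 3
        assert s.sx_score == pytest.approx(np.mean([x[0] for x in sx]))
        assert s.sx_rmsd == pytest.approx(np.mean([x[1] for x in sx]))
        assert s.sx_aln_len == pytest.approx(np.mean([x[2] for x in sx]))
        assert s.tm_score == pytest.approx(np.mean([x[0] for x in tm]))
        assert s.tm_rmsd == pytest.approx(np.mean([x[1] for x in tm]))
        assert not s.singleton


def _stats(sid, m, sc, d, al):
    """Identical interaction and structure statistics for hand arithmetic."""
    return SubclusterStats(sid, m, sx_score=sc, sx_rmsd=d, sx_aln_len=al,
                           tm_score=sc, tm_rmsd=d, tm_aln_len=al)


class TestQScores:
    def test_hand_table_oracle(self):
        # A: sc 10, d 1, al 5, M 2;  B: sc 5, d 2, al 5, M 4
        # maxima sc 10, d 2, al 5, M 4
        # Q_A = 10/10 + 5/5 + 2/4 - 1/2 = 2.0 ; Q_B = 5/10 + 5/5 + 4/4 - 2/2 = 1.5
        report = q_scores([_stats("A", 2, 10, 1, 5), _stats("B", 4, 5, 2, 5)])
        np.testing.assert_allclose(report.table["q_score"], [2.0, 1.5])
        np.testing.assert_allclose(report.table["sxq"], report.table["tmq"])
        assert report.maxima["sx_score"] == 10
        assert report.maxima["m"] == 4

    def test_single_subcluster_gets_two(self):
        report = q_scores([_stats("A", 3, 7.0, 1.5, 4)])
        assert report.table["q_score"].iloc[0] == pytest.approx(2.0)

    def test_zero_maxima_contribute_zero(self):
        # two singletons: every statistic is 0, only M/M_max = 1 survives
        report = q_scores([SubclusterStats("A", 1, singleton=True),
                           SubclusterStats("B", 1, singleton=True)])
        np.testing.assert_allclose(report.table["q_score"], [1.0, 1.0])

    def test_scale_invariance_of_scores(self):
        base = [_stats("A", 2, 10, 1, 5), _stats("B", 4, 5, 2, 5)]
        scaled = [_stats("A", 2, 30, 1, 5), _stats("B", 4, 15, 2, 5)]
        r1, r2 = q_scores(base), q_scores(scaled)
        np.testing.assert_allclose(r1.table["q_score"], r2.table["q_score"])

    def test_larger_rmsd_lowers_q(self):
        worse = q_scores([_stats("A", 2, 10, 1.8, 5), _stats("B", 4, 5, 2, 5)])
        better = q_scores([_stats("A", 2, 10, 1.0, 5), _stats("B", 4, 5, 2, 5)])
        assert worse.table["q_score"].iloc[0] < better.table["q_score"].iloc[0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            q_scores([])

    def test_ranking_on_real_synthetic_subclusters(self):
        # a tight 3-member subcluster should outrank a singleton
        tight = _loops(0, 3, seed=4)
        lone = _loops(1, 1, seed=4)
        report = q_scores([subcluster_stats("tight", tight), subcluster_stats("lone", lone)])
        table = report.table.set_index("subcluster_id")
        assert table.loc["tight", "q_score"] > table.loc["lone", "q_score"]
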