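"""Per-subcluster similarity statistics and quality (Q) scores.

Each subcluster i is summarized by averages over all unordered member
pairs: an interaction-alignment score / RMSD / alignment length
(SXsc_i, SXd_i, SXal_i) and a structure-alignment score / RMSD /
alignment length (TMsc_i, TMd_i, TMal_i).  With maxima taken over all
subclusters of the run,

    SXQ_i = SXsc_i/SXsc_max + SXal_i/SXal_max + M_i/M_max - SXd_i/SXd_max
    TMQ_i = TMsc_i/TMsc_max + TMal_i/TMal_max + M_i/M_max - TMd_i/TMd_max
    Q_i   = (SXQ_i + TMQ_i) / 2

where M_i is the member count.  Any ratio with a zero maximum is 0.

Two lightweight internal alignment backends are provided (a base-pair
set matcher and a sequence-order center superposition); the
``external_table`` backend instead reads per-pair values produced by any
external interaction- or structure-alignment tool, reproducing the full
workflow when such outputs are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import Loop
from .geometry import kabsch_rmsd, loop_centers, nucleotide_center

INTERNAL_BACKENDS = ("interaction_internal", "structure_internal")
D0_ANGSTROM = 4.0  # distance scale of the internal structural score


def _interaction_similarity(a: Loop, b: Loop) -> tuple[float, float, int]:
    """Greedy maximum matching of base-pair annotations with equal LW class.

    Score = 2 * matched pairs + 0.5 * matched stackings; alignment length
    is the matched pair count; RMSD is the Kabsch RMSD over the centers of
    the nucleotides of matched pairs (0 when nothing matches).
    """
    used_b: set[int] = set()
    matches: list[tuple] = []
    b_pairs = list(b.base_pairs)
    for pa in sorted(a.base_pairs, key=lambda p: (p.i, p.j, p.lw_class)):
        best, best_cost = None, None
        for idx, pb in enumerate(b_pairs):
            if idx in used_b:
                continue
            rev = pb.reversed()
            if pa.lw_class == pb.lw_class:
                cand = (idx, pb.i, pb.j)
            elif pa.lw_class == rev.lw_class:
                cand = (idx, rev.i, rev.j)
            else:
                continue
            cost = abs(pa.i - cand[1]) + abs(pa.j - cand[2])
            if best_cost is None or cost < best_cost:
                best, best_cost = cand, cost
        if best is not None:
            used_b.add(best[0])
            matches.append(((pa.i, pa.j), (best[1], best[2])))

    stack_a = {}
    for st in a.stackings:
        canon = st if st.i < st.j else st.reversed()
        stack_a[(canon.i, canon.j)] = canon.direction
    stack_matches = 0
    seen = set()
    for st in b.stackings:
        canon = st if st.i < st.j else st.reversed()
        key = (canon.i, canon.j)
        if key in seen:
            continue
        seen.add(key)
        if stack_a.get(key) == canon.direction:
            stack_matches += 1

    score = 2.0 * len(matches) + 0.5 * stack_matches
    length = len(matches)
    if matches:
        P = np.array(
            [nucleotide_center(a.nucleotides[k]) for ij, _ in matches for k in ij]
        )
        Q = np.array(
            [nucleotide_center(b.nucleotides[k]) for _, ij in matches for k in ij]
        )
        rmsd = kabsch_rmsd(P, Q)
    else:
        rmsd = 0.0
    return score, rmsd, length


def _structure_similarity(a: Loop, b: Loop) -> tuple[float, float, int]:
    """Sequence-order center alignment + Kabsch superposition.

    The first min(Na, Nb) nucleotide centers are corresponded by order,
    superposed, and scored by mean(1 / (1 + (d_k/d0)^2)) with d0 = 4 A.
    """
    ca, cb = loop_centers(a), loop_centers(b)
    k = min(len(ca), len(cb))
    P, Q = ca[:k], cb[:k]
    rmsd = kabsch_rmsd(P, Q)
    # recompute per-point deviations under the optimal superposition
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    dists = np.linalg.norm(Pc @ R.T - Qc, axis=1)
    score = float(np.mean(1.0 / (1.0 + (dists / D0_ANGSTROM) ** 2)))
    return score, rmsd, k


class PairTable:
    """External per-pair similarity values, keyed by (loop_a, loop_b, backend).

    TSV layout: ``loop_a  loop_b  backend  score  rmsd  aln_len`` where
    ``backend`` is ``interaction`` or ``structure``.  Lookup is
    order-insensitive in the loop pair.
    """

    def __init__(self, rows=None):
        self._table: dict[tuple, tuple[float, float, float]] = {}
        for row in rows or []:
            self.add(*row)

    def add(self, loop_a, loop_b, backend, score, rmsd, aln_len) -> None:
        key = (frozenset((loop_a, loop_b)), backend)
        self._table[key] = (float(score), float(rmsd), float(aln_len))

    def lookup(self, loop_a: str, loop_b: str, backend: str):
        key = (frozenset((loop_a, loop_b)), backend)
        if key not in self._table:
            raise KeyError(
                f"pair ({loop_a}, {loop_b}) missing from the external "
                f"{backend} table"
            )
        return self._table[key]

    @classmethod
    def from_tsv(cls, path) -> "PairTable":
        table = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                la, lb, backend, score, rmsd, aln = line.split("\t")
                table.add(la, lb, backend, float(score), float(rmsd), float(aln))
        return table


def pair_similarity(
    loop_a: Loop,
    loop_b: Loop,
    backend: str = "structure_internal",
    external_table: PairTable | None = None,
) -> tuple[float, float, float]:
    """(score, rmsd, alignment_length) for one loop pair under a backend."""
    if backend == "interaction_internal":
        return _interaction_similarity(loop_a, loop_b)
    if backend == "structure_internal":
        return _structure_similarity(loop_a, loop_b)
    if backend in ("external_interaction", "external_structure"):
        if external_table is None:
            raise ValueError("external backends need a PairTable")
        kind = "interaction" if backend == "external_interaction" else "structure"
        return external_table.lookup(loop_a.loop_id, loop_b.loop_id, kind)
    raise ValueError(f"unknown backend {backend!r}")


@dataclass
class SubclusterStats:
    """Averaged pairwise similarity statistics of one subcluster."""

    subcluster_id: tuple | int | str
    m: int
    sx_score: float = 0.0
    sx_rmsd: float = 0.0
    sx_aln_len: float = 0.0
    tm_score: float = 0.0
    tm_rmsd: float = 0.0
    tm_aln_len: float = 0.0
    singleton: bool = False


def subcluster_stats(
    subcluster_id,
    members: list[Loop],
    interaction_backend: str = "interaction_internal",
    structure_backend: str = "structure_internal",
    external_table: PairTable | None = None,
) -> SubclusterStats:
    """Average the pairwise statistics over all C(M, 2) member pairs.

    Singletons cannot be averaged; their stats are zeroed and flagged.
    """
    m = len(members)
    if m < 2:
        return SubclusterStats(subcluster_id, m, singleton=True)
    sx, tm = [], []
    for a, b in combinations(members, 2):
        sx.append(pair_similarity(a, b, interaction_backend, external_table))
        tm.append(pair_similarity(a, b, structure_backend, external_table))
    sx_arr, tm_arr = np.array(sx, dtype=float), np.array(tm, dtype=float)
    return SubclusterStats(
        subcluster_id,
        m,
        sx_score=float(sx_arr[:, 0].mean()),
        sx_rmsd=float(sx_arr[:, 1].mean()),
        sx_aln_len=float(sx_arr[:, 2].mean()),
        tm_score=float(tm_arr[:, 0].mean()),
        tm_rmsd=float(tm_arr[:, 1].mean()),
        tm_aln_len=float(tm_arr[:, 2].mean()),
    )


@dataclass
class QScoreReport:
    """Q-scores per subcluster plus the corpus maxima used as normalizers."""

    table: pd.DataFrame
    maxima: dict[str, float]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def q_scores(stats: list[SubclusterStats]) -> QScoreReport:
    """Quality scores of all subclusters from their averaged statistics."""
    if not stats:
        raise ValueError("q_scores needs at least one subcluster")

    def ratio(x: float, xmax: float) -> float:
        return x / xmax if xmax > 0 else 0.0

    maxima = {
        "sx_score": max(s.sx_score for s in stats),
        "sx_rmsd": max(s.sx_rmsd for s in stats),
        "sx_aln_len": max(s.sx_aln_len for s in stats),
        "tm_score": max(s.tm_score for s in stats),
        "tm_rmsd": max(s.tm_rmsd for s in stats),
        "tm_aln_len": max(s.tm_aln_len for s in stats),
        "m": max(s.m for s in stats),
    }
    rows = []
    for s in stats:
        sxq = (
            ratio(s.sx_score, maxima["sx_score"])
            + ratio(s.sx_aln_len, maxima["sx_aln_len"])
            + ratio(s.m, maxima["m"])
            - ratio(s.sx_rmsd, maxima["sx_rmsd"])
        )
        tmq = (
            ratio(s.tm_score, maxima["tm_score"])
            + ratio(s.tm_aln_len, maxima["tm_aln_len"])
            + ratio(s.m, maxima["m"])
            - ratio(s.tm_rmsd, maxima["tm_rmsd"])
        )
        rows.append(
            {
                "subcluster_id": s.subcluster_id,
                "m": s.m,
                "sx_score": s.sx_score,
                "sx_rmsd": s.sx_rmsd,
                "sx_aln_len": s.sx_aln_len,
                "tm_score": s.tm_score,
                "tm_rmsd": s.tm_rmsd,
                "tm_aln_len": s.tm_aln_len,
                "sxq": sxq,
                "tmq": tmq,
                "q_score": (sxq + tmq) / 2.0,
                "singleton": s.singleton,
            }
        )
    return QScoreReport(pd.DataFrame(rows), maxima)
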