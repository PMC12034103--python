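"""Normalizing and merging base-interaction annotations from two sources.

Base-pair and stacking annotations for the same structure typically come
from two independent annotation tools that disagree on spelling and,
occasionally, on the interaction itself.  This module canonicalizes both
inputs to the package vocabularies (18 directional Leontis-Westhof pair
classes, 4 stacking orientations) and merges them, resolving conflicts by
corpus frequency: when two records claim the same nucleotide pair with
different classes, or two pairs compete for the same edge (W, H or S
side) of one nucleotide, the variant whose (base_i, base_j, class)
pattern occurs more often in a reference corpus wins.

Adapter dialect (TSV, both sources)::

    structure_id  chain_i  res_i  base_i  chain_j  res_j  base_j  kind  token

with ``kind`` in {pair, stack}.  Frequency-table dialect (TSV)::

    base_i  base_j  class  count
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import LW_INDEX, LW_REVERSE, STACK_INDEX, STACK_REVERSE

SOURCES = ("FR3D", "DSSR")


class AnnotationError(ValueError):
    """Raised for unmappable tokens or malformed adapter rows."""


_STACK_ALIASES = {
    "upward": "upward", "up": "upward", "s35": "upward",
    "downward": "downward", "down": "downward", "s53": "downward",
    "inward": "inward", "in": "inward", "s33": "inward",
    "outward": "outward", "out": "outward", "s55": "outward",
}


def normalize_pair_token(token: str) -> str:
    """Canonicalize a Leontis-Westhof spelling: ``cW-W``/``tS/H`` -> ``cWW``/``tSH``."""
    compact = token.replace("-", "").replace("/", "").strip()
    if len(compact) == 3:
        candidate = compact[0].lower() + compact[1:].upper()
        if candidate in LW_INDEX:
            return candidate
    raise AnnotationError(f"unmappable base-pair token {token!r}")


def normalize_stack_token(token: str) -> str:
    key = token.strip().lower()
    if key in _STACK_ALIASES:
        return _STACK_ALIASES[key]
    raise AnnotationError(f"unmappable stacking token {token!r}")


@dataclass(frozen=True)
class AnnotationRecord:
    """One normalized base-interaction record, directional from i to j."""

    structure_id: str
    chain_i: str
    res_i: int
    chain_j: str
    res_j: int
    kind: str                 # "pair" | "stack"
    class_token: str          # LW class or stacking direction
    source: str               # "FR3D" | "DSSR"
    base_i: str = "N"
    base_j: str = "N"

    def __post_init__(self) -> None:
        if self.kind not in ("pair", "stack"):
            raise AnnotationError(f"unknown record kind {self.kind!r}")
        vocab = LW_INDEX if self.kind == "pair" else STACK_INDEX
        if self.class_token not in vocab:
            raise AnnotationError(f"class token {self.class_token!r} not canonical")
        if self.source not in SOURCES:
            raise AnnotationError(f"unknown source {self.source!r}")

    @property
    def partner_key(self) -> tuple:
        """Unordered identity of the interacting pair."""
        a = (self.chain_i, self.res_i)
        b = (self.chain_j, self.res_j)
        return (self.structure_id, self.kind) + (tuple(sorted((a, b))),)

    def canonical(self) -> "AnnotationRecord":
        """Reorient so the lower (chain, residue) endpoint comes first."""
        if (self.chain_i, self.res_i) <= (self.chain_j, self.res_j):
            return self
        rev = LW_REVERSE if self.kind == "pair" else STACK_REVERSE
        return replace(
            self,
            chain_i=self.chain_j, res_i=self.res_j, base_i=self.base_j,
            chain_j=self.chain_i, res_j=self.res_i, base_j=self.base_i,
            class_token=rev[self.class_token],
        )


def normalize_records(raw_rows, source: str) -> list[AnnotationRecord]:
    """Convert adapter-dialect rows (sequences of 9 fields) to records.

    Rows may come from a TSV reader or be constructed in memory; both
    sources share the column layout, only token spellings differ and all
    spellings accepted by the normalizers are allowed for either source.
    """
    if source not in SOURCES:
        raise AnnotationError(f"unknown source {source!r}")
    records = []
    for rownum, row in enumerate(raw_rows, start=1):
        fields = list(row)
        if len(fields) != 9:
            raise AnnotationError(f"row {rownum}: expected 9 fields, got {len(fields)}")
        sid, ci, ri, bi, cj, rj, bj, kind, token = fields
        kind = kind.strip().lower()
        if kind == "pair":
            token = normalize_pair_token(token)
        elif kind == "stack":
            token = normalize_stack_token(token)
        else:
            raise AnnotationError(f"row {rownum}: unknown kind {kind!r}")
        records.append(
            AnnotationRecord(
                structure_id=sid.strip(), chain_i=ci.strip(), res_i=int(ri),
                chain_j=cj.strip(), res_j=int(rj), kind=kind,
                class_token=token, source=source,
                base_i=bi.strip().upper() or "N", base_j=bj.strip().upper() or "N",
            )
        )
    return records


def read_annotation_file(path, source: str) -> list[AnnotationRecord]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return normalize_records(rows, source)


@dataclass
class PatternFrequencyTable:
    """Occurrence counts of (base_i, base_j, class) patterns over a corpus.

    Pair patterns are direction-free physically, so lookups consult both
    the stored orientation and its Leontis-Westhof transpose.
    """

    counts: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def count(self, base_i: str, base_j: str, token: str) -> int:
        direct = self.counts.get((base_i, base_j, token), 0)
        if token in LW_REVERSE:
            return direct + self.counts.get((base_j, base_i, LW_REVERSE[token]), 0)
        return direct

    def add(self, base_i: str, base_j: str, token: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("counts must be nonnegative")
        key = (base_i, base_j, token)
        self.counts[key] = self.counts.get(key, 0) + n

    @classmethod
    def from_tsv(cls, path) -> "PatternFrequencyTable":
        table = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                bi, bj, token, count = line.split("\t")
                table.add(bi, bj, token, int(count))
        return table

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for (bi, bj, token), count in sorted(self.counts.items()):
                fh.write(f"{bi}\t{bj}\t{token}\t{count}\n")


# Which LW edge of each endpoint a directional pair class occupies:
# class xYZ on i->j uses edge Y of i and edge Z of j.
def _edge_slots(rec: AnnotationRecord) -> list[tuple]:
    return [
        ((rec.structure_id, rec.chain_i, rec.res_i), rec.class_token[1]),
        ((rec.structure_id, rec.chain_j, rec.res_j), rec.class_token[2]),
    ]


def merge_annotations(
    a: list[AnnotationRecord],
    b: list[AnnotationRecord],
    freq: PatternFrequencyTable | None = None,
) -> tuple[list[AnnotationRecord], list[dict]]:
    """Merge two annotation sets with frequency-based conflict resolution.

    Returns the merged records and a conflict log with one entry per
    dropped record.  Stacking records never conflict (with anything);
    pair records conflict when they disagree on the class of one
    unordered nucleotide pair, or when two distinct pairs claim the same
    Leontis-Westhof edge of one nucleotide.  The record whose base/class
    pattern is more frequent in ``freq`` wins; ties prefer the FR3D
    source, then the lexicographically smaller class token.
    """
    freq = freq or PatternFrequencyTable()

    # Deduplicate: identical physical records (orientation-independent).
    seen: dict[tuple, AnnotationRecord] = {}
    for rec in list(a) + list(b):
        canon = rec.canonical()
        key = canon.partner_key + (canon.class_token,)
        if key not in seen:
            seen[key] = canon
        elif canon.source == "FR3D" and seen[key].source != "FR3D":
            seen[key] = canon  # keep the preferred provenance on true duplicates

    stacks = [r for r in seen.values() if r.kind == "stack"]
    pairs = [r for r in seen.values() if r.kind == "pair"]

    def priority(rec: AnnotationRecord):
        return (
            -freq.count(rec.base_i, rec.base_j, rec.class_token),
            0 if rec.source == "FR3D" else 1,
            rec.class_token,
            rec.structure_id, rec.chain_i, rec.res_i, rec.chain_j, rec.res_j,
        )

    kept: list[AnnotationRecord] = []
    conflict_log: list[dict] = []
    claimed_partner: dict[tuple, AnnotationRecord] = {}
    claimed_edge: dict[tuple, AnnotationRecord] = {}
    for rec in sorted(pairs, key=priority):
        pk = rec.partner_key
        blocker = claimed_partner.get(pk)
        if blocker is None:
            for slot in _edge_slots(rec):
                other = claimed_edge.get(slot)
                # the same unordered pair never blocks itself on an edge slot
                if other is not None and other.partner_key != pk:
                    blocker = other
                    break
        if blocker is not None:
            conflict_log.append(
                {
                    "dropped": rec,
                    "kept": blocker,
                    "reason": "same-pair class conflict"
                    if blocker.partner_key == pk
                    else "edge already claimed",
                }
            )
            continue
        kept.append(rec)
        claimed_partner[pk] = rec
        for slot in _edge_slots(rec):
            claimed_edge[slot] = rec

    merged = sorted(
        kept + stacks,
        key=lambda r: (r.structure_id, r.kind, r.chain_i, r.res_i, r.chain_j, r.res_j, r.class_token),
    )
    return merged, conflict_log
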