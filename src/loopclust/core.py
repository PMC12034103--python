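"""Core domain types for RNA loop motif candidates.

An RNA loop region (hairpin, internal loop, or multiloop) is a motif
candidate: one or more strands of nucleotides, each strand a contiguous
run of residues in one chain, together with the non-covalent base
interactions observed among those nucleotides.  Base pairs are classified
by the Leontis-Westhof scheme (interacting edge Watson-Crick/Hoogsteen/
Sugar on either side, cis or trans glycosidic orientation, read
directionally), and base stacking by the four relative orientations
upward / downward / inward / outward.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

#: The 18 directional Leontis-Westhof base-pair classes, in the canonical
#: order used throughout (edge-feature channels 1-18 of a loop graph).
LW_CLASSES: tuple[str, ...] = (
    "cWW", "cWH", "cHW", "cWS", "cSW", "cHH", "cHS", "cSH", "cSS",
    "tWW", "tWH", "tHW", "tWS", "tSW", "tHH", "tHS", "tSH", "tSS",
)
LW_INDEX: dict[str, int] = {c: i for i, c in enumerate(LW_CLASSES)}

#: Reversing the direction of a pair annotation swaps the two edge letters:
#: an i->j cWH is a j->i cHW.  Orientation (cis/trans) is direction-free.
LW_REVERSE: dict[str, str] = {c: c[0] + c[2] + c[1] for c in LW_CLASSES}

#: The four base-stacking orientations (edge-feature channels 19-22).
STACK_CLASSES: tuple[str, ...] = ("upward", "downward", "inward", "outward")
STACK_INDEX: dict[str, int] = {c: i for i, c in enumerate(STACK_CLASSES)}

#: Direction reversal for stacking: upward/downward swap, inward and
#: outward are self-symmetric.
STACK_REVERSE: dict[str, str] = {
    "upward": "downward",
    "downward": "upward",
    "inward": "inward",
    "outward": "outward",
}

#: Backbone atoms contributing to a nucleotide's geometric center.
BACKBONE_ATOMS: tuple[str, ...] = ("C3'", "C4'", "C5'", "O3'", "O5'", "P")

#: Standard bases carrying a one-hot node feature; anything else is "other"
#: and gets an all-zero row.
STANDARD_BASES: tuple[str, ...] = ("A", "C", "G", "U")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(STANDARD_BASES)}


class LoopParseError(ValueError):
    """Raised when a loop-location string or loop file is malformed."""


_LOCATION_RE = re.compile(
    r"^(?P<pdb>[0-9A-Za-z]{4})_(?P<chain>[^:]+):(?P<segs>\d+-\d+(?:_\d+-\d+)*)$"
)


@dataclass(frozen=True)
class LoopLocation:
    """Location of a loop: structure, chain, and residue-number segments.

    Segment count 1 is a hairpin loop, 2 an internal loop, >= 3 a
    multiloop.  Residue numbers are author numbering, inclusive.
    """

    pdb_id: str
    chain: str
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.pdb_id) != 4:
            raise LoopParseError(f"pdb_id must be 4 characters: {self.pdb_id!r}")
        if not self.segments:
            raise LoopParseError("a loop location needs at least one segment")
        for start, end in self.segments:
            if start > end:
                raise LoopParseError(
                    f"segment start > end in {self.pdb_id}: {start}-{end}"
                )

    @property
    def loop_type(self) -> str:
        n = len(self.segments)
        return "hairpin" if n == 1 else "internal" if n == 2 else "multiloop"

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.segments)

    def __str__(self) -> str:
        return format_loop_location(self)


def parse_loop_location(text: str) -> LoopLocation:
    """Parse ``PDBID_CHAIN:a-b[_c-d...]`` into a :class:`LoopLocation`.

    >>> loc = parse_loop_location("1U9S_A:136-139_161-162")
    >>> loc.pdb_id, loc.chain, loc.segments
    ('1U9S', 'A', ((136, 139), (161, 162)))
    """
    m = _LOCATION_RE.match(text.strip())
    if m is None:
        raise LoopParseError(f"malformed loop location: {text!r}")
    segments = []
    for token in m.group("segs").split("_"):
        start_s, end_s = token.split("-")
        start, end = int(start_s), int(end_s)
        if start > end:
            raise LoopParseError(f"segment start > end in token {token!r} of {text!r}")
        segments.append((start, end))
    return LoopLocation(m.group("pdb"), m.group("chain"), tuple(segments))


def format_loop_location(loc: LoopLocation) -> str:
    segs = "_".join(f"{s}-{e}" for s, e in loc.segments)
    return f"{loc.pdb_id}_{loc.chain}:{segs}"


@dataclass
class Nucleotide:
    """One residue of a loop with its backbone geometry.

    ``backbone_coords`` maps atom names (subset of C3',C4',C5',O3',O5',P)
    to 3-vectors in Angstroms.  A nucleotide is geometrically usable when
    at least one backbone atom is present.  ``insertion_code`` is carried
    opaquely; no arithmetic is ever done on it.
    """

    residue_number: int
    base: str
    backbone_coords: dict[str, np.ndarray] = field(default_factory=dict)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.base not in STANDARD_BASES:
            self.base = "other"
        clean = {}
        for name, xyz in self.backbone_coords.items():
            if name not in BACKBONE_ATOMS:
                raise ValueError(f"unknown backbone atom {name!r}")
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(
                    f"atom {name} of residue {self.residue_number}: "
                    "coordinates must be a finite 3-vector"
                )
            clean[name] = arr
        self.backbone_coords = clean

    @property
    def has_coordinates(self) -> bool:
        return len(self.backbone_coords) > 0

    def one_hot(self) -> np.ndarray:
        row = np.zeros(4)
        if self.base in BASE_INDEX:
            row[BASE_INDEX[self.base]] = 1.0
        return row


@dataclass(frozen=True)
class BasePairAnnotation:
    """Directional base-pair annotation between loop-internal indices.

    ``lw_class`` is read from i to j; the same physical pair seen from j
    is ``LW_REVERSE[lw_class]``.
    """

    i: int
    j: int
    lw_class: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a base pair needs two distinct nucleotides")
        if self.lw_class not in LW_INDEX:
            raise ValueError(f"unknown Leontis-Westhof class {self.lw_class!r}")

    def reversed(self) -> "BasePairAnnotation":
        return BasePairAnnotation(self.j, self.i, LW_REVERSE[self.lw_class])


@dataclass(frozen=True)
class StackingAnnotation:
    """Directional base-stacking annotation between loop-internal indices."""

    i: int
    j: int
    direction: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a stacking needs two distinct nucleotides")
        if self.direction not in STACK_INDEX:
            raise ValueError(f"unknown stacking direction {self.direction!r}")

    def reversed(self) -> "StackingAnnotation":
        return StackingAnnotation(self.j, self.i, STACK_REVERSE[self.direction])


@dataclass
class Loop:
    """A motif candidate: strands of nucleotides plus base interactions.

    Nucleotides are ordered strand by strand (segment order), each strand
    5'->3' (ascending residue number).  Annotation indices are 0-based
    positions in that flattened list.
    """

    location: LoopLocation
    nucleotides: list[Nucleotide]
    base_pairs: list[BasePairAnnotation] = field(default_factory=list)
    stackings: list[StackingAnnotation] = field(default_factory=list)
    family: str | None = None

    def __post_init__(self) -> None:
        expected = sum(self.location.segment_lengths)
        if len(self.nucleotides) != expected:
            raise ValueError(
                f"{self.location}: {len(self.nucleotides)} nucleotides but "
                f"segments cover {expected} residues"
            )
        n = len(self.nucleotides)
        for ann in list(self.base_pairs) + list(self.stackings):
            if not (0 <= ann.i < n and 0 <= ann.j < n):
                raise ValueError(
                    f"{self.location}: annotation index out of range "
                    f"({ann.i},{ann.j}) for {n} nucleotides"
                )

    @property
    def loop_id(self) -> str:
        return format_loop_location(self.location)

    @property
    def n_nucleotides(self) -> int:
        return len(self.nucleotides)

    @property
    def sequence_by_strand(self) -> list[str]:
        seqs, k = [], 0
        for length in self.location.segment_lengths:
            seqs.append(
                "".join(
                    nt.base if nt.base in STANDARD_BASES else "N"
                    for nt in self.nucleotides[k : k + length]
                )
            )
            k += length
        return seqs

    def missing_coordinate_indices(self) -> list[int]:
        return [k for k, nt in enumerate(self.nucleotides) if not nt.has_coordinates]
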