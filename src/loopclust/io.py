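"""Reading and writing loop files, coordinate files, and structures.

Loop file dialect (TSV, one block per loop)::

    >1U9S_A:136-139_161-162<TAB>SR
    SEQ<TAB>GAGA
    SEQ<TAB>GC
    BP<TAB>0<TAB>3<TAB>tHS
    STK<TAB>0<TAB>1<TAB>upward

The ``>`` header carries the loop location and an optional family label.
One ``SEQ`` line per strand (strand order = segment order, 5'->3').  BP
and STK indices are 0-based positions in the flattened nucleotide list.

Coordinate file dialect (TSV, one atom per row)::

    loop_id<TAB>nt_index<TAB>atom_name<TAB>x<TAB>y<TAB>z
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .core import (
    BACKBONE_ATOMS,
    BasePairAnnotation,
    Loop,
    LoopParseError,
    Nucleotide,
    StackingAnnotation,
    parse_loop_location,
)

# ---------------------------------------------------------------------------
# Loop files


def write_loop_file(loops, path) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            header = f">{loop.loop_id}"
            if loop.family is not None:
                header += f"\t{loop.family}"
            fh.write(header + "\n")
            for seq in loop.sequence_by_strand:
                fh.write(f"SEQ\t{seq}\n")
            for bp in loop.base_pairs:
                fh.write(f"BP\t{bp.i}\t{bp.j}\t{bp.lw_class}\n")
            for st in loop.stackings:
                fh.write(f"STK\t{st.i}\t{st.j}\t{st.direction}\n")


def read_loop_file(path) -> list[Loop]:
    loops: list[Loop] = []
    location = None
    family: str | None = None
    seqs: list[str] = []
    pairs: list[BasePairAnnotation] = []
    stacks: list[StackingAnnotation] = []

    def flush(lineno: int) -> None:
        nonlocal location, family, seqs, pairs, stacks
        if location is None:
            return
        lengths = location.segment_lengths
        if len(seqs) != len(lengths):
            raise LoopParseError(
                f"{path}:{lineno}: {location} declares {len(lengths)} strands "
                f"but has {len(seqs)} SEQ lines"
            )
        nucleotides = []
        for (start, _end), seq, length in zip(location.segments, seqs, lengths):
            if len(seq) != length:
                raise LoopParseError(
                    f"{path}:{lineno}: strand length {len(seq)} does not match "
                    f"segment length {length} in {location}"
                )
            for offset, base in enumerate(seq):
                nucleotides.append(Nucleotide(start + offset, base))
        loops.append(Loop(location, nucleotides, pairs, stacks, family))
        location, family, seqs, pairs, stacks = None, None, [], [], []

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                fields = line[1:].split("\t")
                location = parse_loop_location(fields[0])
                family = fields[1].strip() if len(fields) > 1 and fields[1].strip() else None
                continue
            if location is None:
                raise LoopParseError(f"{path}:{lineno}: record line before any '>' header")
            fields = line.split("\t")
            tag = fields[0]
            try:
                if tag == "SEQ":
                    seqs.append(fields[1].strip())
                elif tag == "BP":
                    pairs.append(BasePairAnnotation(int(fields[1]), int(fields[2]), fields[3]))
                elif tag == "STK":
                    stacks.append(StackingAnnotation(int(fields[1]), int(fields[2]), fields[3]))
                else:
                    raise LoopParseError(f"{path}:{lineno}: unknown record tag {tag!r}")
            except (IndexError, ValueError) as exc:
                raise LoopParseError(f"{path}:{lineno}: {exc}") from exc
        flush(lineno + 1)
    return loops


# ---------------------------------------------------------------------------
# Coordinate files


def write_coordinate_file(loops, path) -> None:
    with open(path, "w") as fh:
        for loop in loops:
            for idx, nt in enumerate(loop.nucleotides):
                for atom in BACKBONE_ATOMS:
                    if atom in nt.backbone_coords:
                        x, y, z = nt.backbone_coords[atom]
                        fh.write(
                            f"{loop.loop_id}\t{idx}\t{atom}\t{x:.4f}\t{y:.4f}\t{z:.4f}\n"
                        )


def read_coordinate_file(path) -> dict[str, dict[int, dict[str, np.ndarray]]]:
    """Parse the flat coordinate TSV into loop_id -> nt_index -> atom -> xyz."""
    table: dict[str, dict[int, dict[str, np.ndarray]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise LoopParseError(f"{path}:{lineno}: expected 6 TSV fields")
            loop_id, idx_s, atom, xs, ys, zs = fields
            if atom not in BACKBONE_ATOMS:
                raise LoopParseError(f"{path}:{lineno}: unknown atom {atom!r}")
            xyz = np.array([float(xs), float(ys), float(zs)])
            table.setdefault(loop_id, {}).setdefault(int(idx_s), {})[atom] = xyz
    return table


# ---------------------------------------------------------------------------
# Coordinate attachment


def attach_coordinates(loops, coordinate_source) -> list[Loop]:
    """Fill ``backbone_coords`` of every loop nucleotide in place.

    ``coordinate_source`` is either the nested dict returned by
    :func:`read_coordinate_file` (or a path to such a file), or a path to a
    PDB/mmCIF structure file (extension .pdb / .cif / .ent), or an already
    parsed ``gemmi.Structure``.  Residues absent from the source are left
    without coordinates and merely flagged (query them with
    ``Loop.missing_coordinate_indices``); a missing chain is an error.
    """
    if isinstance(coordinate_source, gemmi.Structure):
        for loop in loops:
            _attach_from_structure(loop, coordinate_source)
        return loops
    if isinstance(coordinate_source, (str, Path)):
        p = Path(coordinate_source)
        if p.suffix.lower() in {".pdb", ".cif", ".ent", ".mmcif"}:
            structure = gemmi.read_structure(str(p))
            for loop in loops:
                _attach_from_structure(loop, structure)
            return loops
        coordinate_source = read_coordinate_file(p)
    for loop in loops:
        per_loop = coordinate_source.get(loop.loop_id, {})
        for idx, nt in enumerate(loop.nucleotides):
            atoms = per_loop.get(idx)
            if atoms:
                nt.backbone_coords = dict(atoms)
                nt.__post_init__()
    return loops


def _attach_from_structure(loop: Loop, structure: gemmi.Structure) -> None:
    model = structure[0]
    chain = model.find_chain(loop.location.chain)
    if chain is None:
        raise KeyError(
            f"chain {loop.location.chain!r} not found in structure "
            f"{structure.name or loop.location.pdb_id}"
        )
    by_seqid: dict[int, gemmi.Residue] = {}
    for residue in chain:
        num = residue.seqid.num
        by_seqid.setdefault(num, residue)
    idx = 0
    for (start, end) in loop.location.segments:
        for resnum in range(start, end + 1):
            nt = loop.nucleotides[idx]
            residue = by_seqid.get(resnum)
            if residue is not None:
                coords = {}
                for atom in residue:
                    if atom.name in BACKBONE_ATOMS:
                        coords[atom.name] = np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]
                        )
                if coords:
                    nt.backbone_coords = coords
                    nt.__post_init__()
            idx += 1
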