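"""Synthetic labelled loop families for testing the full pipeline offline.

Eight built-in family templates (six internal-loop, two hairpin) emulate
what distinguishes real motif families: each has its own base-pair /
stacking signature AND its own backbone shape.  Backbones are parametric
per-strand helices (rise, twist, radius, optional kink) -- deliberately
not physical RNA; they exist to exercise the distance, superposition and
graph machinery, with six backbone atoms placed at fixed offsets around
each nucleotide center so the per-atom code paths run too.

Sampling adds isotropic Gaussian jitter to every nucleotide (the atoms of
a nucleotide move rigidly) and drop/flip noise to the base-pair pattern.
Everything is deterministic under the supplied seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import PatternFrequencyTable
from .core import (
    LW_CLASSES,
    BasePairAnnotation,
    Loop,
    LoopLocation,
    Nucleotide,
    StackingAnnotation,
)
from .geometry import kabsch_rmsd, loop_centers

# Fixed local offsets (Angstrom) of the six backbone atoms around the
# nucleotide center; zero-mean so the geometric center is the center.
_RAW_OFFSETS = {
    "P": np.array([1.2, 0.0, -0.4]),
    "O5'": np.array([0.7, 0.6, -0.2]),
    "C5'": np.array([0.2, 0.9, 0.1]),
    "C4'": np.array([-0.3, 0.5, 0.4]),
    "C3'": np.array([-0.8, -0.2, 0.3]),
    "O3'": np.array([-1.0, -1.8, -0.2]),
}
_MEAN_OFFSET = np.mean(list(_RAW_OFFSETS.values()), axis=0)
ATOM_OFFSETS = {k: v - _MEAN_OFFSET for k, v in _RAW_OFFSETS.items()}


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model for sampled loops."""

    coord_sd: float = 0.3        # Angstrom, isotropic per-nucleotide jitter
    pair_drop_prob: float = 0.05
    pair_flip_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coord_sd < 0:
            raise ValueError("coord_sd must be >= 0")
        for p in (self.pair_drop_prob, self.pair_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class FamilyTemplate:
    """Blueprint of one synthetic motif family."""

    name: str
    strand_lengths: tuple[int, ...]
    sequences: tuple[str, ...]
    base_pairs: tuple[tuple[int, int, str], ...]
    stackings: tuple[tuple[int, int, str], ...]
    rise: float = 3.0
    twist: float = 0.6           # radians per step
    radius: float = 4.0
    kink_at: int | None = None   # flattened index after which the kink applies
    kink_angle: float = 0.0      # radians, about the x axis
    strand_gap: float = 9.0      # Angstrom between the two strands

    def __post_init__(self) -> None:
        n = sum(self.strand_lengths)
        if tuple(len(s) for s in self.sequences) != tuple(self.strand_lengths):
            raise ValueError(f"{self.name}: sequences do not match strand lengths")
        for i, j, cls in self.base_pairs:
            if not (0 <= i < n and 0 <= j < n) or i == j or cls not in LW_CLASSES:
                raise ValueError(f"{self.name}: invalid base-pair entry ({i},{j},{cls})")
        for i, j, _d in self.stackings:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"{self.name}: invalid stacking entry ({i},{j})")

    @property
    def n_nucleotides(self) -> int:
        return sum(self.strand_lengths)

    @property
    def loop_type(self) -> str:
        return "hairpin" if len(self.strand_lengths) == 1 else "internal"

    def mean_centers(self) -> np.ndarray:
        """Noiseless backbone centers of the template."""
        strands = []
        offset = np.zeros(3)
        for s, length in enumerate(self.strand_lengths):
            pts = _helix(length, self.rise, self.twist, self.radius, phase=1.3 * s)
            if s == 1:
                # antiparallel partner strand, displaced sideways
                pts = pts[::-1] * np.array([-1.0, 1.0, 1.0])
                offset = np.array([self.strand_gap, 0.0, 0.0])
            strands.append(pts + offset)
        centers = np.vstack(strands)
        if self.kink_at is not None and self.kink_angle:
            centers = _apply_kink(centers, self.kink_at, self.kink_angle)
        return centers


def _helix(n: int, rise: float, twist: float, radius: float, phase: float = 0.0) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack(
        [radius * np.cos(phase + t * twist), radius * np.sin(phase + t * twist), t * rise]
    )


def _apply_kink(centers: np.ndarray, at: int, angle: float) -> np.ndarray:
    """Rotate all centers after index ``at`` about the x axis through that point."""
    out = centers.copy()
    pivot = centers[at]
    c, s = np.cos(angle), np.sin(angle)
    R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    out[at + 1 :] = (centers[at + 1 :] - pivot) @ R.T + pivot
    return out


def builtin_templates() -> list[FamilyTemplate]:
    """Six internal-loop and two hairpin family templates.

    Families carry the standard family codes (SR, KT, TS, HT, EL, CL
    internal; TL, GL hairpin) but their shapes and patterns are synthetic
    stand-ins, not the real family geometries.
    """
    up = "upward"
    return [
        FamilyTemplate(
            "SR", (5, 4), ("CUGAG", "CGAA"),
            ((0, 8, "cWW"), (1, 7, "tHS"), (2, 6, "tWH"), (3, 5, "tSS")),
            ((0, 1, up), (1, 2, up), (5, 6, up)),
            rise=3.2, twist=0.55, radius=4.0,
        ),
        FamilyTemplate(
            "KT", (5, 4), ("GGAUC", "GAGC"),
            ((0, 8, "cWW"), (1, 7, "tHS"), (2, 6, "tSH"), (4, 5, "cWW")),
            ((0, 1, up), (2, 3, up), (6, 7, up)),
            rise=2.8, twist=0.75, radius=3.5, kink_at=2, kink_angle=1.1,
        ),
        FamilyTemplate(
            "TS", (4, 4), ("CAGG", "CAGG"),
            ((0, 7, "cWW"), (1, 6, "tSH"), (2, 5, "tHS"), (3, 4, "cWW")),
            ((0, 1, up), (4, 5, up)),
            rise=3.6, twist=0.40, radius=4.5,
        ),
        FamilyTemplate(
            "HT", (5, 3), ("UAAGC", "GCU"),
            ((0, 7, "cWW"), (2, 6, "tWH"), (3, 5, "cSS")),
            ((1, 2, up), (2, 3, up)),
            rise=2.5, twist=0.95, radius=3.0, kink_at=3, kink_angle=0.6,
        ),
        FamilyTemplate(
            "EL", (5, 5), ("CAGUA", "GAUGG"),
            ((0, 9, "cWW"), (1, 8, "tSH"), (2, 7, "tHW"), (3, 6, "tHS")),
            ((0, 1, up), (5, 6, up), (7, 8, up)),
            rise=3.4, twist=0.65, radius=5.0,
        ),
        FamilyTemplate(
            "CL", (3, 6), ("GCA", "UGGCAC"),
            ((0, 8, "cWW"), (1, 6, "cSW"), (2, 4, "tWS")),
            ((3, 4, up), (4, 5, up)),
            rise=3.0, twist=1.10, radius=3.8, kink_at=4, kink_angle=0.45,
        ),
        FamilyTemplate(
            "TL", (7,), ("CUGGGAG",),
            ((0, 6, "cWW"), (1, 5, "tWH"), (2, 4, "cSS")),
            ((2, 3, up), (3, 4, up)),
            rise=2.6, twist=1.30, radius=4.2,
        ),
        FamilyTemplate(
            "GL", (6,), ("CGAAAG",),
            ((0, 5, "cWW"), (1, 4, "tSH")),
            ((1, 2, up), (2, 3, up), (3, 4, up)),
            rise=2.2, twist=0.85, radius=3.2, kink_at=2, kink_angle=0.9,
        ),
    ]


def internal_templates() -> list[FamilyTemplate]:
    return [t for t in builtin_templates() if t.loop_type == "internal"]


def hairpin_templates() -> list[FamilyTemplate]:
    return [t for t in builtin_templates() if t.loop_type == "hairpin"]


_B36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _location_for(template: FamilyTemplate, instance: int) -> LoopLocation:
    code = instance % (36**4)
    chars = []
    for _ in range(4):
        code, r = divmod(code, 36)
        chars.append(_B36[r])
    pdb_id = "".join(reversed(chars))
    segments, start = [], 1
    for length in template.strand_lengths:
        segments.append((start, start + length - 1))
        start += length + 4  # gap mimicking the intervening helix
    return LoopLocation(pdb_id, template.name, tuple(segments))


def sample_loop(
    template: FamilyTemplate,
    noise: NoiseSpec = NoiseSpec(),
    instance_seed: int = 0,
) -> Loop:
    """Draw one loop: template backbone + jitter, pattern + drop/flip noise."""
    rng = np.random.default_rng([noise.seed, instance_seed])
    centers = template.mean_centers()
    if noise.coord_sd > 0:
        centers = centers + rng.normal(0.0, noise.coord_sd, size=centers.shape)

    location = _location_for(template, instance_seed)
    sequence = "".join(template.sequences)
    nucleotides = []
    idx = 0
    for (start, _end), length in zip(location.segments, template.strand_lengths):
        for offset in range(length):
            coords = {name: centers[idx] + delta for name, delta in ATOM_OFFSETS.items()}
            nucleotides.append(Nucleotide(start + offset, sequence[idx], coords))
            idx += 1

    pairs = []
    for i, j, cls in template.base_pairs:
        if rng.random() < noise.pair_drop_prob:
            continue
        if rng.random() < noise.pair_flip_prob:
            others = [c for c in LW_CLASSES if c != cls]
            cls = others[int(rng.integers(len(others)))]
        pairs.append(BasePairAnnotation(i, j, cls))
    stacks = [StackingAnnotation(i, j, d) for i, j, d in template.stackings]
    return Loop(location, nucleotides, pairs, stacks, family=template.name)


def nearest_template(loop: Loop, templates) -> str:
    """Classify a loop by center-RMSD to the template mean shapes."""
    centers = loop_centers(loop)
    best, best_rmsd = None, None
    for t in templates:
        ref = t.mean_centers()
        k = min(len(ref), len(centers))
        r = kabsch_rmsd(centers[:k], ref[:k])
        # penalize size mismatch so shorter templates cannot win on a prefix
        r += 2.0 * abs(len(ref) - len(centers))
        if best_rmsd is None or r < best_rmsd:
            best, best_rmsd = t.name, r
    return best


@dataclass
class SyntheticDataset:
    loops: list[Loop]
    labels: list[str]
    split: dict[str, np.ndarray]           # "train" / "val" / "test" index arrays
    manifest: pd.DataFrame = field(repr=False, default=None)


def generate_dataset(
    templates=None,
    n_per_family: int = 50,
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SyntheticDataset:
    """Sample a labelled corpus with a stratified train/val/test split."""
    templates = list(templates) if templates is not None else internal_templates()
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    # instance seeds drawn once so regeneration is reproducible
    inst_seeds = rng.integers(0, 2**31 - 1, size=len(templates) * n_per_family)

    loops, labels = [], []
    k = 0
    for template in templates:
        for _ in range(n_per_family):
            loops.append(sample_loop(template, noise, int(inst_seeds[k])))
            labels.append(template.name)
            k += 1

    split: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    labels_arr = np.asarray(labels)
    for name in sorted(set(labels)):
        members = np.flatnonzero(labels_arr == name)
        members = members[rng.permutation(len(members))]
        n = len(members)
        n_val = max(1, int(round(fractions[1] * n)))
        n_test = max(1, int(round(fractions[2] * n)))
        split["val"].extend(members[:n_val])
        split["test"].extend(members[n_val : n_val + n_test])
        split["train"].extend(members[n_val + n_test :])
    split_arrays = {k2: np.array(sorted(v), dtype=int) for k2, v in split.items()}

    role = np.empty(len(loops), dtype=object)
    for part, idxs in split_arrays.items():
        role[idxs] = part
    manifest = pd.DataFrame(
        {
            "loop_id": [lp.loop_id for lp in loops],
            "family": labels,
            "split": role,
            "n_nucleotides": [lp.n_nucleotides for lp in loops],
        }
    )
    return SyntheticDataset(loops, labels, split_arrays, manifest)


# ---------------------------------------------------------------------------
# Adapter-dialect exports for exercising the annotation merge


def _index_to_residue(loop: Loop) -> list[int]:
    numbers = []
    for start, end in loop.location.segments:
        numbers.extend(range(start, end + 1))
    return numbers


def adapter_rows(loop: Loop, source: str) -> list[list[str]]:
    """Render a loop's annotations in one source's adapter dialect.

    The FR3D-style rows use compact tokens (``tHS``, ``upward``); the
    DSSR-style rows use separator spellings (``tH-S``, ``up``).
    """
    numbers = _index_to_residue(loop)
    chain = loop.location.chain
    sid = loop.location.pdb_id
    rows = []
    for bp in loop.base_pairs:
        token = bp.lw_class if source == "FR3D" else f"{bp.lw_class[0]}{bp.lw_class[1]}-{bp.lw_class[2]}"
        rows.append(
            [sid, chain, str(numbers[bp.i]), loop.nucleotides[bp.i].base,
             chain, str(numbers[bp.j]), loop.nucleotides[bp.j].base, "pair", token]
        )
    short = {"upward": "up", "downward": "down", "inward": "in", "outward": "out"}
    for st in loop.stackings:
        token = st.direction if source == "FR3D" else short[st.direction]
        rows.append(
            [sid, chain, str(numbers[st.i]), loop.nucleotides[st.i].base,
             chain, str(numbers[st.j]), loop.nucleotides[st.j].base, "stack", token]
        )
    return rows


def corpus_frequency_table(loops) -> PatternFrequencyTable:
    """Frequency table of (base_i, base_j, class) patterns over given loops."""
    table = PatternFrequencyTable()
    for loop in loops:
        for bp in loop.base_pairs:
            table.add(loop.nucleotides[bp.i].base, loop.nucleotides[bp.j].base, bp.lw_class)
    return table
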