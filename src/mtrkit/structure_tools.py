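"""Protein structure ingestion, sequence-structure mapping and geometry.

A :class:`StructureModel` holds one chain's residues with author numbering
(insertion codes preserved as part of the residue identity), a
representative atom per residue (Cα by default) for distance work, and the
full atom list with van der Waals radii for solvent accessibility.

Mapping a gene's protein sequence onto a structure uses a global alignment
with free end gaps, so partial structures (a single domain of a long
protein) pair only the residues they actually cover.  When several
candidate structures exist, experimentally resolved ones are preferred
over homology models, and within the preferred class the structure whose
aligned residues best match the gene sequence wins; for a specific variant
the choice is additionally restricted to structures covering its position,
since different partial structures best fit different variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .variant_model import GeneModel

EXPERIMENTAL = "experimental"
HOMOLOGY = "homology"

#: Theoretical maximum accessible surface areas (Å²) per residue,
#: Tien et al. 2013, used to normalise SASA into relative accessibility.
MAX_ASA: dict[str, float] = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

DEFAULT_RADIUS = 8.0  # Å, spatial neighborhood default
PROBE_RADIUS = 1.4  # Å, water probe for SASA
N_SPHERE_POINTS = 960


@dataclass
class Atom:
    element: str
    coord: np.ndarray  # (3,) Å
    radius: float  # van der Waals, Å


@dataclass
class Residue:
    """One residue: author-numbered identity, 1-letter code, atoms."""

    residue_number: str  # author number + insertion code, e.g. "52", "52A"
    amino_acid: str
    rep_coord: np.ndarray | None  # representative atom (None if absent)
    atoms: list[Atom] = field(default_factory=list)

    @property
    def has_rep(self) -> bool:
        return self.rep_coord is not None


@dataclass
class StructureModel:
    structure_id: str
    source_kind: str  # experimental | homology
    residues: list[Residue]

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def residue(self, residue_number: str | int) -> Residue:
        key = str(residue_number)
        for r in self.residues:
            if r.residue_number == key:
                return r
        raise KeyError(f"no residue {key!r} in {self.structure_id}")

    def rep_coords(self) -> tuple[list[str], np.ndarray]:
        """Residue numbers and coordinates for residues with a representative atom."""
        ids = [r.residue_number for r in self.residues if r.has_rep]
        coords = np.array(
            [r.rep_coord for r in self.residues if r.has_rep], dtype=float
        ).reshape(-1, 3)
        return ids, coords


@dataclass
class SeqStructMap:
    """Sequence-position to structure-residue correspondence for one gene.

    ``pairs`` is a one-to-one list of ``(codon_index, residue_number)``;
    ``match_fraction`` is the proportion of paired positions whose amino
    acids agree between the gene's protein sequence and the structure.
    """

    gene_id: str
    structure_id: str
    pairs: list[tuple[int, str]]
    match_fraction: float

    @property
    def codon_to_residue(self) -> dict[int, str]:
        return dict(self.pairs)

    @property
    def residue_to_codon(self) -> dict[str, int]:
        return {r: c for c, r in self.pairs}

    def covers(self, codon_index: int) -> bool:
        return any(c == codon_index for c, _ in self.pairs)


@dataclass
class SpatialNeighborhood:
    focal: str
    members: set[str]
    radius: float


# ---------------------------------------------------------------------------
# PDB reading

def _one_letter(resname: str) -> str | None:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def read_structure(
    path: str | Path,
    rep_atom_rule: str = "CA",
    chain_id: str | None = None,
    source_kind: str = EXPERIMENTAL,
    structure_id: str | None = None,
) -> StructureModel:
    """Read one protein chain from a PDB file.

    Only the first model is used.  For alternate locations the
    highest-occupancy conformer of each atom is kept.  Residues lacking
    the representative atom (default Cα) keep their atoms for SASA but are
    flagged (``rep_coord is None``) and excluded from spatial
    neighborhoods.  Insertion codes yield distinct residue identities
    ("52" vs "52A").
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    chain = None
    for ch in model:
        if chain_id is not None and ch.name != chain_id:
            continue
        if any(_one_letter(res.name) for res in ch):
            chain = ch
            break
    if chain is None:
        raise ValueError(f"{path}: no protein chain found")

    residues: list[Residue] = []
    for res in chain:
        aa = _one_letter(res.name)
        if aa is None:
            continue  # waters, ligands
        # keep the highest-occupancy conformer per atom name
        best: dict[str, gemmi.Atom] = {}
        for atom in res:
            prev = best.get(atom.name)
            if prev is None or atom.occ > prev.occ:
                best[atom.name] = atom
        atoms = [
            Atom(
                element=a.element.name,
                coord=np.array([a.pos.x, a.pos.y, a.pos.z]),
                radius=a.element.vdw_r,
            )
            for a in best.values()
        ]
        rep = best.get(rep_atom_rule)
        rep_coord = (
            np.array([rep.pos.x, rep.pos.y, rep.pos.z]) if rep is not None else None
        )
        num = f"{res.seqid.num}{res.seqid.icode.strip()}"
        residues.append(
            Residue(residue_number=num, amino_acid=aa, rep_coord=rep_coord, atoms=atoms)
        )
    if not residues:
        raise ValueError(f"{path}: chain {chain.name} has no amino-acid residues")
    return StructureModel(
        structure_id=structure_id or f"{Path(path).stem}_{chain.name}",
        source_kind=source_kind,
        residues=residues,
    )


# ---------------------------------------------------------------------------
# Sequence <-> structure mapping

def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # free end gaps: partial structures align where they belong
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_sequence_to_structure(
    gene: GeneModel, structure: StructureModel
) -> SeqStructMap:
    """Align the gene's protein sequence to the structure's residue sequence.

    Pairs cover aligned, non-gap positions only.  ``match_fraction`` is the
    fraction of paired positions with identical amino acids (0 when no
    positions align).
    """
    seq = gene.protein_seq
    struct_seq = structure.sequence
    aligner = _identity_aligner()
    alignment = aligner.align(seq, struct_seq)[0]
    pairs: list[tuple[int, str]] = []
    n_match = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            codon_index = t0 + offset + 1
            residue = structure.residues[q0 + offset]
            pairs.append((codon_index, residue.residue_number))
            if seq[codon_index - 1] == residue.amino_acid:
                n_match += 1
    match_fraction = n_match / len(pairs) if pairs else 0.0
    return SeqStructMap(
        gene_id=gene.gene_id,
        structure_id=structure.structure_id,
        pairs=pairs,
        match_fraction=match_fraction,
    )


def select_structure(
    maps: Sequence[SeqStructMap],
    kinds: Mapping[str, str],
    variant_position: int | None = None,
) -> SeqStructMap:
    """Pick the best sequence-structure map among candidates.

    Experimental structures are preferred over homology models; within the
    preferred class the highest ``match_fraction`` wins, ties broken by
    larger pair count then lexicographically smaller structure_id.  When
    ``variant_position`` is given, candidates covering that codon are
    considered first (per-variant selection for partial structures).
    """
    if not maps:
        raise ValueError("no candidate maps")
    candidates = list(maps)
    if variant_position is not None:
        covering = [m for m in candidates if m.covers(variant_position)]
        if covering:
            candidates = covering
    experimental = [m for m in candidates if kinds.get(m.structure_id) == EXPERIMENTAL]
    pool = experimental if experimental else candidates
    return max(
        pool,
        key=lambda m: (m.match_fraction, len(m.pairs), _neg_lex(m.structure_id)),
    )


class _neg_lex(str):
    """Reverse lexicographic ordering so max() prefers the smaller id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Spatial neighborhoods

def spatial_neighbors(
    structure: StructureModel, focal: str | int, radius: float
) -> SpatialNeighborhood:
    """Residues whose representative atoms lie within ``radius`` Å of the focal's.

    The focal residue is always a member.  Residues without a
    representative atom are excluded.
    """
    focal = str(focal)
    ids, coords = structure.rep_coords()
    try:
        focal_idx = ids.index(focal)
    except ValueError:
        raise ValueError(
            f"focal residue {focal!r} has no representative atom"
        ) from None
    d = np.linalg.norm(coords - coords[focal_idx], axis=1)
    members = {ids[i] for i in np.nonzero(d <= radius)[0]}
    members.add(focal)
    return SpatialNeighborhood(focal=focal, members=members, radius=radius)


def all_neighborhoods(
    structure: StructureModel, radius: float
) -> dict[str, set[str]]:
    """Spatial neighborhoods for every residue at once (KD-tree ball query)."""
    ids, coords = structure.rep_coords()
    if not ids:
        return {}
    tree = cKDTree(coords)
    groups = tree.query_ball_point(coords, r=radius)
    return {ids[i]: {ids[j] for j in grp} for i, grp in enumerate(groups)}


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-spiral construction."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²).

    Each atom's sphere of radius ``r + probe`` is sampled at ``n_points``
    quasi-uniform points; a point is accessible if it lies outside every
    neighbouring atom's expanded sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise ValueError("empty atom list")
    n = len(coords)
    expanded = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        neighbor_idx = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r) if j != i]
        if neighbor_idx:
            nb = np.array(neighbor_idx)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            n_accessible = int((~buried).sum())
        else:
            n_accessible = n_points
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * n_accessible / n_points
    return areas


def compute_rsa(
    structure: StructureModel,
    probe: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> dict[str, float]:
    """Relative solvent accessibility per residue.

    Residue SASA (sum over its atoms) divided by the amino acid's
    theoretical maximum accessible area.  Values are >= 0 and can modestly
    exceed 1 for exposed termini.
    """
    coords, radii, owner = [], [], []
    for ri, res in enumerate(structure.residues):
        for atom in res.atoms:
            coords.append(atom.coord)
            radii.append(atom.radius)
            owner.append(ri)
    if not coords:
        raise ValueError(f"{structure.structure_id}: no atoms")
    areas = shrake_rupley_sasa(np.array(coords), np.array(radii), probe, n_points)
    per_res = np.zeros(len(structure.residues))
    np.add.at(per_res, np.array(owner), areas)
    rsa = {}
    for ri, res in enumerate(structure.residues):
        max_asa = MAX_ASA.get(res.amino_acid)
        if max_asa is None:
            continue
        rsa[res.residue_number] = float(per_res[ri] / max_asa)
    return rsa


def write_mapping(
    mapping: SeqStructMap, gene: GeneModel, structure: StructureModel, path: str | Path
) -> None:
    """TSV export of a sequence-structure map with per-pair match flags."""
    struct_aa = {r.residue_number: r.amino_acid for r in structure.residues}
    with open(path, "w") as fh:
        fh.write("gene\tcodon_index\tstructure_id\tresidue_number\tmatch_flag\n")
        for codon_index, residue_number in mapping.pairs:
            flag = int(
                gene.protein_seq[codon_index - 1] == struct_aa.get(residue_number)
            )
            fh.write(
                f"{mapping.gene_id}\t{codon_index}\t{mapping.structure_id}\t"
                f"{residue_number}\t{flag}\n"
            )
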