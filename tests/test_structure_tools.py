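"""Structure ingestion, mapping, neighborhoods and solvent accessibility."""

import math

import numpy as np
import pytest

from mtrkit import synthetic_data as sd
from mtrkit.structure_tools import (
    EXPERIMENTAL,
    HOMOLOGY,
    MAX_ASA,
    Atom,
    Residue,
    SeqStructMap,
    StructureModel,
    all_neighborhoods,
    compute_rsa,
    map_sequence_to_structure,
    read_structure,
    select_structure,
    shrake_rupley_sasa,
    spatial_neighbors,
    write_mapping,
)
from mtrkit.variant_model import GeneModel


def _pdb_line(serial, name, resname, resnum, icode, x, y, z, occ=1.0, element=None):
    element = element or name[0]
    return (
        f"ATOM  {serial:>5} {name:^4} {resname} A{resnum:>4}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2}\n"
    )


# ---------------------------------------------------------------------------
# reading

def test_generator_pdb_round_trip(tmp_path):
    gene = GeneModel.from_codons("helix30", ["GCT"] * 30)
    structure, _ = sd.generate_structure(gene, topology="helix")
    path = tmp_path / "helix.pdb"
    sd.write_structure_pdb(structure, path)
    back = read_structure(path)
    assert len(back) == 30
    assert [r.residue_number for r in back.residues] == [str(i) for i in range(1, 31)]
    assert back.sequence == "A" * 30
    for orig, rt in zip(structure.residues, back.residues):
        assert np.allclose(orig.rep_coord, rt.rep_coord, atol=1e-3)


def test_residue_missing_rep_atom_is_flagged(tmp_path):
    lines = []
    serial = 1
    for i in range(1, 31):
        # residue 10 has only a backbone N: present but unusable spatially
        if i != 10:
            lines.append(_pdb_line(serial, "CA", "ALA", i, " ", i * 3.8, 0, 0))
            serial += 1
        lines.append(_pdb_line(serial, "N", "ALA", i, " ", i * 3.8, 1.0, 0))
        serial += 1
    path = tmp_path / "gap.pdb"
    path.write_text("".join(lines) + "END\n")
    structure = read_structure(path)
    assert len(structure) == 30
    flagged = [r for r in structure.residues if not r.has_rep]
    assert [r.residue_number for r in flagged] == ["10"]
    ids, coords = structure.rep_coords()
    assert len(ids) == 29 and "10" not in ids
    assert "10" not in all_neighborhoods(structure, 5.0)


def test_insertion_codes_are_distinct_residues(tmp_path):
    lines = [
        _pdb_line(1, "CA", "ALA", 52, " ", 0, 0, 0),
        _pdb_line(2, "CA", "GLY", 52, "A", 3.8, 0, 0),
        _pdb_line(3, "CA", "VAL", 53, " ", 7.6, 0, 0),
    ]
    path = tmp_path / "icode.pdb"
    path.write_text("".join(lines) + "END\n")
    structure = read_structure(path)
    assert [r.residue_number for r in structure.residues] == ["52", "52A", "53"]
    assert structure.sequence == "AGV"


def test_altloc_keeps_highest_occupancy(tmp_path):
    raw = (
        "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
        "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
        "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    path = tmp_path / "altloc.pdb"
    path.write_text(raw)
    structure = read_structure(path)
    assert structure.residue("1").rep_coord[0] == pytest.approx(5.0)


def test_read_structure_requires_protein(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(
        "HETATM    1  O   HOH A   1       0.000   0.000   0.000  1.00  0.00           O\nEND\n"
    )
    with pytest.raises(ValueError):
        read_structure(path)


# ---------------------------------------------------------------------------
# mapping and selection

def test_identity_mapping(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="extended")
    mapping = map_sequence_to_structure(small_gene, structure)
    assert mapping.match_fraction == 1.0
    assert mapping.pairs == [(i + 1, str(i + 1)) for i in range(len(small_gene))]


def test_partial_structure_pairs_only_covered_span():
    gene = sd.generate_gene(300, seed=21, gene_id="G300")
    full, _ = sd.generate_structure(gene, topology="extended")
    partial = StructureModel(
        "partial", EXPERIMENTAL, [r for r in full.residues if 50 <= int(r.residue_number) <= 150]
    )
    mapping = map_sequence_to_structure(gene, partial)
    covered = [c for c, _ in mapping.pairs]
    assert min(covered) == 50 and max(covered) == 150
    assert mapping.match_fraction == 1.0


def test_engineered_substitutions_lower_match_fraction():
    gene = sd.generate_gene(100, seed=22, gene_id="G100")
    structure, _ = sd.generate_structure(gene, topology="extended")
    for idx in (29, 59):  # two engineered substitutions
        res = structure.residues[idx]
        res.amino_acid = "A" if res.amino_acid != "A" else "G"
    mapping = map_sequence_to_structure(gene, structure)
    assert len(mapping.pairs) == 100
    assert mapping.match_fraction == pytest.approx(0.98)


def _map(sid, fraction, span=(1, 100), gene_id="g"):
    return SeqStructMap(
        gene_id=gene_id,
        structure_id=sid,
        pairs=[(i, str(i)) for i in range(span[0], span[1] + 1)],
        match_fraction=fraction,
    )


def test_select_structure_prefers_experimental():
    maps = [_map("exp1", 0.90), _map("hom1", 0.99)]
    kinds = {"exp1": EXPERIMENTAL, "hom1": HOMOLOGY}
    assert select_structure(maps, kinds).structure_id == "exp1"


def test_select_structure_max_match_fraction_and_tie_break():
    kinds = {"a": EXPERIMENTAL, "b": EXPERIMENTAL, "c": EXPERIMENTAL}
    assert (
        select_structure([_map("a", 0.90), _map("b", 0.95)], kinds).structure_id == "b"
    )
    # equal fraction, equal coverage: lexicographically smaller id wins
    assert (
        select_structure([_map("b", 0.9), _map("a", 0.9), _map("c", 0.9)], kinds).structure_id
        == "a"
    )
    # equal fraction, larger coverage wins
    assert (
        select_structure(
            [_map("a", 0.9, span=(1, 50)), _map("b", 0.9, span=(1, 80))], kinds
        ).structure_id
        == "b"
    )


def test_select_structure_per_variant_coverage():
    kinds = {"nterm": EXPERIMENTAL, "cterm": EXPERIMENTAL}
    maps = [_map("nterm", 0.99, span=(1, 100)), _map("cterm", 0.90, span=(150, 300))]
    assert select_structure(maps, kinds, variant_position=200).structure_id == "cterm"
    assert select_structure(maps, kinds, variant_position=50).structure_id == "nterm"
    with pytest.raises(ValueError):
        select_structure([], kinds)


# ---------------------------------------------------------------------------
# spatial neighborhoods

def test_radius_zero_is_focal_only(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="extended")
    assert spatial_neighbors(structure, 7, 0.0).members == {"7"}


def test_extended_chain_radius_matches_two_sequence_neighbors(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="extended")
    nb = spatial_neighbors(structure, 30, 2 * 3.8 + 0.01)
    assert nb.members == {str(i) for i in range(28, 33)}


@pytest.mark.parametrize("topology", ["helix", "packed"])
def test_neighbors_match_all_pairs_oracle(topology, small_gene):
    structure, _ = sd.generate_structure(small_gene, topology=topology)
    ids, coords = structure.rep_coords()
    radius = 7.5
    for focal_idx in (0, 17, 42):
        oracle = {
            ids[j]
            for j in range(len(ids))
            if np.linalg.norm(coords[j] - coords[focal_idx]) <= radius
        }
        nb = spatial_neighbors(structure, ids[focal_idx], radius)
        assert nb.members == oracle


def test_neighbor_symmetry(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="helix")
    hoods = all_neighborhoods(structure, 6.0)
    for i, members in hoods.items():
        for j in members:
            assert i in hoods[j]


def test_missing_rep_atom_raises(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="extended")
    structure.residues[4].rep_coord = None
    with pytest.raises(ValueError):
        spatial_neighbors(structure, 5, 8.0)


# ---------------------------------------------------------------------------
# solvent accessibility

def test_isolated_sphere_matches_closed_form():
    r, probe = 1.7, 1.4
    area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([r]), probe=probe)
    assert area[0] == pytest.approx(4 * math.pi * (r + probe) ** 2, rel=0.01)


def test_single_isolated_residue_rsa_near_one():
    gene = GeneModel.from_codons("ala1", ["GCT"] * 10)
    res = Residue("1", "A", np.zeros(3), [Atom("C", np.zeros(3), 1.7)])
    structure = StructureModel("single", EXPERIMENTAL, [res])
    rsa = compute_rsa(structure)
    assert rsa["1"] == pytest.approx(1.0, abs=0.15)


def test_buried_core_has_lower_rsa_than_surface():
    gene = sd.generate_gene(60, seed=30, gene_id="G60")
    structure, _ = sd.generate_structure(gene, topology="packed")
    rsa = compute_rsa(structure)
    # residue 1 sits at the lattice core; the last-placed residues are on the hull
    core = rsa["1"]
    surface = np.mean([rsa[str(i)] for i in range(56, 61)])
    assert core < surface


def test_rsa_values_bounded_and_complete(small_gene):
    structure, _ = sd.generate_structure(small_gene, topology="helix")
    rsa = compute_rsa(structure)
    assert set(rsa) == {str(i + 1) for i in range(len(small_gene))}
    values = np.array(list(rsa.values()))
    assert (values >= 0).all() and (values <= 1.3).all()


def test_compute_rsa_empty_structure_errors():
    with pytest.raises(ValueError):
        compute_rsa(StructureModel("empty", EXPERIMENTAL, []))


def test_mapping_writer(tmp_path, small_gene):
    structure, mapping = sd.generate_structure(small_gene, topology="extended")
    path = tmp_path / "map.tsv"
    write_mapping(mapping, small_gene, structure, path)
    lines = path.read_text().splitlines()
    assert len(lines) == len(small_gene) + 1
    assert all(line.endswith("\t1") for line in lines[1:])
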