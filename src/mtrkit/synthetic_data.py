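"""Synthetic study generators with planted ground truth.

Every input the pipeline consumes can be generated here: genes as random
sense-codon sequences, standing population variation depleted of missense
variants inside planted intolerant regions, case cohorts preferentially
drawn from those regions with uniform control cohorts, toy protein
structures with controllable spatial neighborhoods, and alignments with
planted conserved blocks.  Each generator is a pure function of its
parameters and seed, so fixtures are byte-reproducible and every planted
signal is recoverable for testing.

The default :class:`SyntheticCohortSpec` emulates the scale of a de novo
mutation study of a 34-gene disease panel: 276 case-ascertained variants
against control cohorts of 454 and 762, with one depleted region per gene
covering a quarter of its codons where missense variants are observed at
a fifth of the background rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .structure_tools import SeqStructMap, StructureModel, Residue, Atom, EXPERIMENTAL
from .variant_model import (
    BASES,
    MISSENSE,
    NONSENSE,
    SENSE_CODONS,
    GeneModel,
    Variant,
    VariantSet,
    classify_substitution,
    translate_codon,
)

CA_RADIUS = 1.70  # carbon vdW, Å
CA_SPACING = 3.8  # consecutive-residue Cα distance, Å

AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for the synthetic cohorts.

    ``population_density`` is the expected number of observed
    (missense+synonymous) population variants per codon outside depleted
    regions; inside a depleted region the per-SNV missense observation
    probability is multiplied by ``depletion_multiplier`` while
    synonymous observation is unaffected.  ``case_enrichment`` is the
    relative probability that a case variant falls inside a depleted
    region versus outside.
    """

    n_genes: int = 34
    gene_length_range: tuple[int, int] = (300, 600)
    region_fraction: float = 0.25
    depletion_multiplier: float = 0.2
    population_density: float = 1.0
    case_enrichment: float = 3.0
    n_case: int = 276
    n_control1: int = 454
    n_control2: int = 762
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.depletion_multiplier < 1.0):
            raise ValueError("depletion_multiplier must be in (0, 1)")
        if not (0.0 <= self.region_fraction < 1.0):
            raise ValueError("region_fraction must be in [0, 1)")
        if self.case_enrichment <= 0:
            raise ValueError("case_enrichment must be positive")


def _codon_snv_outcomes(codon: str) -> tuple[tuple[str, str, str], ...]:
    """All 9 SNV outcomes of a codon as (alt_codon, consequence, alt_aa)."""
    out = []
    for pos in (1, 2, 3):
        for base in BASES:
            if base == codon[pos - 1]:
                continue
            consequence, alt_aa = classify_substitution(codon, pos, base)
            alt_codon = codon[: pos - 1] + base + codon[pos:]
            out.append((alt_codon, consequence, alt_aa))
    return tuple(out)


# precomputed for all sense codons so generation is table-driven
_SNV_TABLE: dict[str, tuple[tuple[int, str, str, str], ...]] = {
    c: _codon_snv_outcomes(c) for c in SENSE_CODONS
}


def generate_gene(
    length: int,
    gc_bias: float = 0.5,
    seed: int = 0,
    gene_id: str = "GENE1",
    is_dee_gene: bool = False,
) -> GeneModel:
    """Random gene of ``length`` sense codons (no internal stops).

    ``gc_bias`` is the per-base probability of drawing G or C; codons
    that would be stops are redrawn.
    """
    if length < 10:
        raise ValueError("gene length must be >= 10 codons")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2]
    )  # A C G T
    bases = np.array(list("ACGT"))
    codons: list[str] = []
    while len(codons) < length:
        batch = rng.choice(bases, size=(length - len(codons) + 8, 3), p=p)
        for triplet in batch:
            draw = "".join(triplet)
            if translate_codon(draw) != "*" and len(codons) < length:
                codons.append(draw)
    return GeneModel.from_codons(gene_id, codons, is_dee_gene=is_dee_gene)


def place_regions(
    gene_length: int, fraction: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """One contiguous depleted region covering ``fraction`` of the codons."""
    if fraction <= 0:
        return []
    span = max(1, round(fraction * gene_length))
    start = int(rng.integers(1, gene_length - span + 2))
    return [(start, start + span - 1)]


def _in_regions(pos: int, regions: Sequence[tuple[int, int]]) -> bool:
    return any(a <= pos <= b for a, b in regions)


def generate_population_variants(
    gene: GeneModel,
    density: float = 1.0,
    depletion_regions: Sequence[tuple[int, int]] = (),
    depletion_multiplier: float = 0.2,
    seed: int = 0,
) -> VariantSet:
    """Standing population variation with planted missense depletion.

    Each possible missense or synonymous SNV is observed independently
    with probability ``density / 9``; inside a depleted region the
    missense probability is multiplied by ``depletion_multiplier``.
    Nonsense SNVs are never emitted (the tolerance ratio ignores them).
    """
    rng = np.random.default_rng(seed)
    q = density / 9.0
    probs = []
    template = []
    for i, codon in enumerate(gene.codons):
        pos = i + 1
        depleted = _in_regions(pos, depletion_regions)
        ref_aa = gene.protein_seq[i]
        for alt_codon, consequence, alt_aa in _SNV_TABLE[codon]:
            if consequence == NONSENSE:
                continue
            p = q * depletion_multiplier if (consequence == MISSENSE and depleted) else q
            probs.append(p)
            template.append((pos, ref_aa, alt_aa, consequence, f"{codon}>{alt_codon}"))
    u = rng.random(len(probs))
    variants = [
        Variant(
            gene_id=gene.gene_id,
            codon_index=pos,
            ref_aa=ref,
            alt_aa=alt,
            consequence=consequence,
            cohort="population",
            codon_change=change,
        )
        for (pos, ref, alt, consequence, change), ui, pi in zip(template, u, probs)
        if ui < pi
    ]
    return VariantSet(
        f"{gene.gene_id}-population",
        variants,
        provenance=f"synthetic population, density={density}, seed={seed}",
    )


def possible_missense_keys(gene: GeneModel) -> list[tuple[int, str, str]]:
    """Unique (codon_index, ref_aa, alt_aa) missense SNV keys of a gene."""
    keys = []
    seen = set()
    for i, codon in enumerate(gene.codons):
        pos = i + 1
        ref_aa = gene.protein_seq[i]
        for _alt_codon, consequence, alt_aa in _SNV_TABLE[codon]:
            if consequence != MISSENSE:
                continue
            key = (pos, ref_aa, alt_aa)
            if key not in seen:
                seen.add(key)
                keys.append(key)
    return keys


def generate_cohorts(
    genes: Sequence[GeneModel],
    regions: Mapping[str, Sequence[tuple[int, int]]],
    spec: SyntheticCohortSpec,
    seed: int = 0,
) -> dict[str, VariantSet]:
    """Case and control cohorts of unique missense variants.

    Case variants are drawn without replacement with probability weighted
    ``case_enrichment``-fold inside depleted regions; controls are drawn
    uniformly over all possible missense SNVs.  Cohort sizes are honoured
    exactly or an error is raised.
    """
    rng = np.random.default_rng(seed)
    all_keys: list[tuple[str, int, str, str]] = []
    weights: list[float] = []
    for gene in genes:
        gene_regions = regions.get(gene.gene_id, ())
        for pos, ref, alt in possible_missense_keys(gene):
            all_keys.append((gene.gene_id, pos, ref, alt))
            weights.append(
                spec.case_enrichment if _in_regions(pos, gene_regions) else 1.0
            )
    n_possible = len(all_keys)
    sizes = {"case": spec.n_case, "control1": spec.n_control1, "control2": spec.n_control2}
    for label, size in sizes.items():
        if size > n_possible:
            raise ValueError(
                f"{label} cohort of {size} exceeds {n_possible} possible unique variants"
            )
    w = np.array(weights)
    cohorts: dict[str, VariantSet] = {}
    for label, size in sizes.items():
        p = w / w.sum() if label == "case" else None
        idx = rng.choice(n_possible, size=size, replace=False, p=p)
        variants = [
            Variant(
                gene_id=all_keys[i][0],
                codon_index=all_keys[i][1],
                ref_aa=all_keys[i][2],
                alt_aa=all_keys[i][3],
                consequence=MISSENSE,
                cohort=label,
            )
            for i in idx
        ]
        cohorts[label] = VariantSet(
            label,
            variants,
            provenance=f"synthetic cohort, enrichment="
            f"{spec.case_enrichment if label == 'case' else 1.0}, seed={seed}",
        )
    return cohorts


# ---------------------------------------------------------------------------
# Structures

def _coords_for_topology(
    length: int,
    topology: str,
    contact_pairs: Sequence[tuple[int, int]] | None,
    contact_distance: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if topology == "extended":
        coords = np.zeros((length, 3))
        coords[:, 0] = np.arange(length) * CA_SPACING
        return coords
    if topology == "helix":
        # ideal alpha helix: 100 deg twist and 1.5 A rise per residue, 2.3 A radius
        i = np.arange(length)
        theta = np.deg2rad(100.0) * i
        return np.column_stack(
            [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
        )
    if topology == "folded_contact_pairs":
        if not contact_pairs:
            raise ValueError("folded_contact_pairs topology needs contact_pairs")
        sums = {a + b for a, b in contact_pairs}
        if len(sums) != 1:
            raise ValueError(
                "infeasible contact specification: pairs must share one hairpin fold"
            )
        fold_sum = sums.pop()
        fold_at = fold_sum // 2
        for a, b in contact_pairs:
            if not (1 <= a <= fold_at < b <= length):
                raise ValueError(
                    f"infeasible contact specification: pair ({a}, {b}) does not "
                    f"straddle the fold at {fold_at}"
                )
        coords = np.zeros((length, 3))
        for idx in range(length):
            pos = idx + 1
            if pos <= fold_at:
                coords[idx] = (pos * CA_SPACING, 0.0, 0.0)
            else:
                coords[idx] = ((fold_sum - pos) * CA_SPACING, contact_distance, 0.0)
        return coords
    if topology == "packed":
        # residues on a cubic lattice filling a ball outward from the origin:
        # residue 1 is buried at the core, the last residues sit on the surface
        n_side = int(np.ceil(length ** (1 / 3))) + 2
        grid = np.arange(-n_side, n_side + 1)
        pts = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T * CA_SPACING
        order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
        return pts[order[:length]].astype(float)
    raise ValueError(f"unknown topology {topology!r}")


def generate_structure(
    gene: GeneModel,
    topology: str = "extended",
    seed: int = 0,
    contact_pairs: Sequence[tuple[int, int]] | None = None,
    contact_distance: float = 5.0,
) -> tuple[StructureModel, SeqStructMap]:
    """Toy Cα-only structure realising a controllable topology.

    Topologies: ``extended`` (straight chain, 3.8 Å spacing), ``helix``
    (ideal α-helix), ``folded_contact_pairs`` (hairpin placing the given
    residue pairs at ``contact_distance`` Å) and ``packed`` (lattice ball
    with residue 1 buried at the core).  Returns the structure and the
    true identity sequence-structure mapping.
    """
    rng = np.random.default_rng(seed)
    length = len(gene)
    coords = _coords_for_topology(length, topology, contact_pairs, contact_distance, rng)
    residues = [
        Residue(
            residue_number=str(i + 1),
            amino_acid=gene.protein_seq[i],
            rep_coord=coords[i].copy(),
            atoms=[Atom(element="C", coord=coords[i].copy(), radius=CA_RADIUS)],
        )
        for i in range(length)
    ]
    structure = StructureModel(
        structure_id=f"{gene.gene_id}-{topology}",
        source_kind=EXPERIMENTAL,
        residues=residues,
    )
    mapping = SeqStructMap(
        gene_id=gene.gene_id,
        structure_id=structure.structure_id,
        pairs=[(i + 1, str(i + 1)) for i in range(length)],
        match_fraction=1.0,
    )
    return structure, mapping


def write_structure_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal single-chain PDB ATOM records."""
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            resname = AA3.get(res.amino_acid, "UNK")
            num = res.residue_number
            icode = " "
            if num and num[-1].isalpha():
                icode = num[-1]
                num = num[:-1]
            for atom in res.atoms:
                name = "CA" if atom.element == "C" and len(res.atoms) == 1 else atom.element
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:>5} {name:^4} {resname} A{int(num):>4}{icode}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Alignments

def generate_alignment(
    gene: GeneModel,
    conserved_blocks: Sequence[tuple[int, int]] = (),
    n_sequences: int = 50,
    substitution_rate: float = 0.3,
    gap_rate: float = 0.05,
    conserved_multiplier: float = 0.1,
    seed: int = 0,
) -> list[str]:
    """Aligned homolog set with planted conserved blocks.

    The first row is the gene's protein sequence; the others mutate each
    column at ``substitution_rate`` (times ``conserved_multiplier`` inside
    conserved blocks) and gap it at ``gap_rate``.
    """
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    ref = gene.protein_seq
    length = len(ref)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    rows = [ref]
    rates = np.array(
        [
            substitution_rate * conserved_multiplier
            if _in_regions(i + 1, conserved_blocks)
            else substitution_rate
            for i in range(length)
        ]
    )
    for _ in range(n_sequences - 1):
        chars = list(ref)
        gaps = rng.random(length) < gap_rate
        subs = rng.random(length) < rates
        for i in range(length):
            if gaps[i]:
                chars[i] = "-"
            elif subs[i]:
                alternatives = aa[aa != ref[i]]
                chars[i] = str(rng.choice(alternatives))
        rows.append("".join(chars))
    return rows


def write_alignment_fasta(rows: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(rows):
            fh.write(f">seq{i}\n{row}\n")


# ---------------------------------------------------------------------------
# Whole-study convenience

@dataclass
class SyntheticStudy:
    """A complete generated study: genes, planted regions, variants, cohorts."""

    spec: SyntheticCohortSpec
    genes: list[GeneModel]
    regions: dict[str, list[tuple[int, int]]]
    population: dict[str, VariantSet]  # per gene
    cohorts: dict[str, VariantSet]  # case, control1, control2

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def in_region(self, gene_id: str, codon_index: int) -> bool:
        return _in_regions(codon_index, self.regions.get(gene_id, ()))


def generate_study(spec: SyntheticCohortSpec | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate genes, planted regions, population variation and cohorts.

    A single master seed (``seed`` or ``spec.seed``) drives per-component
    child seeds, so the whole study is a pure function of (spec, seed).
    """
    spec = spec or SyntheticCohortSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    master = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    genes: list[GeneModel] = []
    regions: dict[str, list[tuple[int, int]]] = {}
    population: dict[str, VariantSet] = {}
    for g in range(spec.n_genes):
        length = int(master.integers(lo, hi + 1))
        gene = generate_gene(
            length,
            seed=int(master.integers(2**31)),
            gene_id=f"G{g + 1:03d}",
            is_dee_gene=True,
        )
        genes.append(gene)
        regions[gene.gene_id] = place_regions(length, spec.region_fraction, master)
        population[gene.gene_id] = generate_population_variants(
            gene,
            density=spec.population_density,
            depletion_regions=regions[gene.gene_id],
            depletion_multiplier=spec.depletion_multiplier,
            seed=int(master.integers(2**31)),
        )
    cohorts = generate_cohorts(genes, regions, spec, seed=int(master.integers(2**31)))
    return SyntheticStudy(
        spec=spec, genes=genes, regions=regions, population=population, cohorts=cohorts
    )
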