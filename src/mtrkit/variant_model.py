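"""Domain types for genes, amino-acid-level variants and variant sets.

The coordinate frame for every downstream score is the codon index of a
single protein-coding transcript: a gene is an ordered list of DNA codons
whose translation is the protein sequence.  Variants are amino-acid
substitutions keyed by ``(gene_id, codon_index, ref_aa, alt_aa)``; genomic
records must be reduced to this key by a reader adapter before entering the
analysis.  One transcript per gene is required — multi-transcript genes are
collapsed upstream and the chosen transcript recorded on the gene model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

BASES = "ACGT"

#: codon -> single-letter amino acid, standard genetic code, stops as "*"
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

MISSENSE = "missense"
SYNONYMOUS = "synonymous"
NONSENSE = "nonsense"

RETAINED_SIGNIFICANCE = frozenset(
    {"benign", "likely_benign", "pathogenic", "likely_pathogenic"}
)


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code ("*" for stop)."""
    codon = codon.upper()
    try:
        return CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"invalid codon {codon!r}") from None


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered codon sequence.

    Parameters
    ----------
    gene_id, transcript_id : str
        Identifiers; one transcript per gene defines the coordinate frame.
    codons : tuple of str
        Uppercase DNA triplets, terminal stop excluded; no internal stops.
    protein_seq : str
        Single-letter translation of ``codons``; same length.
    is_dee_gene : bool
        Membership in the configured disease gene panel.
    """

    gene_id: str
    transcript_id: str
    codons: tuple[str, ...]
    protein_seq: str
    is_dee_gene: bool = False

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError("gene must have at least one codon")
        if len(self.codons) != len(self.protein_seq):
            raise ValueError("codon and protein lengths differ")
        for i, codon in enumerate(self.codons):
            aa = translate_codon(codon)
            if aa == "*":
                raise ValueError(f"internal stop codon at position {i + 1}")
            if aa != self.protein_seq[i]:
                raise ValueError(
                    f"codon {codon} at position {i + 1} translates to {aa}, "
                    f"protein_seq has {self.protein_seq[i]}"
                )

    @classmethod
    def from_codons(
        cls,
        gene_id: str,
        codons: Iterable[str],
        transcript_id: str | None = None,
        is_dee_gene: bool = False,
    ) -> "GeneModel":
        codons = tuple(c.upper() for c in codons)
        protein = "".join(translate_codon(c) for c in codons)
        return cls(
            gene_id=gene_id,
            transcript_id=transcript_id or f"{gene_id}-tx1",
            codons=codons,
            protein_seq=protein,
            is_dee_gene=is_dee_gene,
        )

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class Variant:
    """One amino-acid-level substitution; the atomic unit of all counting.

    ``codon_change`` (e.g. ``"GCT>GCA"``) is optional: amino-acid-level
    sources (annotated de novo lists, ClinVar-style tables) leave it unset
    and are unique on ``(gene_id, codon_index, ref_aa, alt_aa)``; sources
    with nucleotide resolution set it so that distinct synonymous SNVs at
    one codon remain distinct observations, as the tolerance ratio
    requires.  Sets being compared must share one convention.
    """

    gene_id: str
    codon_index: int  # 1-based
    ref_aa: str
    alt_aa: str
    consequence: str
    cohort: str = "population"
    clinvar_significance: str | None = None
    codon_change: str | None = None

    def __post_init__(self) -> None:
        if self.codon_index < 1:
            raise ValueError("codon_index is 1-based and must be >= 1")
        if self.consequence == MISSENSE:
            if self.ref_aa == self.alt_aa or self.alt_aa == "*":
                raise ValueError("missense requires ref_aa != alt_aa, alt not stop")
        elif self.consequence == SYNONYMOUS:
            if self.ref_aa != self.alt_aa:
                raise ValueError("synonymous requires ref_aa == alt_aa")
        elif self.consequence != NONSENSE:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def key(self) -> tuple:
        base = (self.gene_id, self.codon_index, self.ref_aa, self.alt_aa)
        return base + (self.codon_change,) if self.codon_change else base


class VariantSet:
    """A uniquely-keyed collection of variants with provenance notes.

    Uniqueness is on ``(gene_id, codon_index, ref_aa, alt_aa)``; adding a
    duplicate key is a silent no-op so that re-reading overlapping sources
    cannot inflate counts.
    """

    def __init__(
        self,
        label: str,
        variants: Iterable[Variant] = (),
        provenance: str = "",
    ) -> None:
        self.label = label
        self.provenance = provenance
        self._by_key: dict[tuple, Variant] = {}
        for v in variants:
            self._by_key.setdefault(v.key, v)

    def add(self, variant: Variant) -> None:
        self._by_key.setdefault(variant.key, variant)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self._by_key.values())

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, variant: Variant) -> bool:
        return variant.key in self._by_key

    @property
    def keys(self) -> set[tuple]:
        return set(self._by_key)

    def for_gene(self, gene_id: str) -> "VariantSet":
        return VariantSet(
            self.label,
            (v for v in self if v.gene_id == gene_id),
            provenance=self.provenance,
        )

    def with_consequence(self, *consequences: str) -> "VariantSet":
        wanted = set(consequences)
        return VariantSet(
            self.label,
            (v for v in self if v.consequence in wanted),
            provenance=self.provenance,
        )


def classify_substitution(
    codon: str, base_position: int, alt_base: str
) -> tuple[str, str]:
    """Classify a single-nucleotide substitution within one codon.

    Parameters
    ----------
    codon : str
        A valid sense codon (uppercase ACGT triplet).
    base_position : int
        1-based position within the codon (1..3).
    alt_base : str
        The substituted base; must differ from the reference base.

    Returns
    -------
    (consequence, alt_aa)
        Consequence is ``missense``/``synonymous``/``nonsense`` under the
        standard genetic code; ``alt_aa`` is the resulting amino acid
        ("*" for nonsense).
    """
    codon = codon.upper()
    alt_base = alt_base.upper()
    ref_aa = translate_codon(codon)
    if ref_aa == "*":
        raise ValueError("stop codons are not valid input")
    if base_position not in (1, 2, 3):
        raise ValueError("base_position must be 1, 2 or 3")
    if alt_base not in BASES:
        raise ValueError(f"invalid base {alt_base!r}")
    if codon[base_position - 1] == alt_base:
        raise ValueError("alt_base equals the reference base")
    alt_codon = codon[: base_position - 1] + alt_base + codon[base_position:]
    alt_aa = translate_codon(alt_codon)
    if alt_aa == "*":
        return NONSENSE, alt_aa
    if alt_aa == ref_aa:
        return SYNONYMOUS, alt_aa
    return MISSENSE, alt_aa


def enumerate_codon_snvs(codon: str) -> dict[str, int]:
    """Count the 9 possible single-nucleotide substitutions of a sense codon.

    Returns ``{"n_missense": ., "n_synonymous": ., "n_nonsense": .}``,
    summing to 9.  This is the possibility (expected-side) denominator for
    the tolerance ratio.
    """
    codon = codon.upper()
    if translate_codon(codon) == "*":
        raise ValueError("stop codons are not valid input")
    counts = {"n_missense": 0, "n_synonymous": 0, "n_nonsense": 0}
    for pos in (1, 2, 3):
        for base in BASES:
            if base == codon[pos - 1]:
                continue
            consequence, _ = classify_substitution(codon, pos, base)
            counts[f"n_{consequence}"] += 1
    return counts


def filter_significance(records: VariantSet) -> VariantSet:
    """Keep missense records with benign/likely_benign/pathogenic/likely_pathogenic labels.

    Records with unknown or conflicting clinical significance are removed,
    as are non-missense records.  Records lacking the significance field
    entirely are dropped with a logged count.
    """
    kept, missing = [], 0
    for v in records:
        if v.clinvar_significance is None:
            missing += 1
            continue
        if v.consequence == MISSENSE and v.clinvar_significance in RETAINED_SIGNIFICANCE:
            kept.append(v)
    if missing:
        logger.warning(
            "%d record(s) in %s lacked a significance label and were dropped",
            missing,
            records.label,
        )
    return VariantSet(
        records.label,
        kept,
        provenance=records.provenance + " | significance-filtered",
    )


def subtract_sets(a: VariantSet, b: VariantSet) -> VariantSet:
    """Return a \\ b by variant key (e.g. population minus case-ascertained)."""
    b_keys = b.keys
    return VariantSet(
        a.label,
        (v for v in a if v.key not in b_keys),
        provenance=a.provenance + f" | minus {b.label}",
    )


def subset_to_genes(
    variant_set: VariantSet, genes: Iterable[str]
) -> tuple[VariantSet, dict[str, int]]:
    """Restrict a set to a gene panel and tally variants per panel gene.

    Returns the restricted set and a ``gene_id -> count`` tally over genes
    with at least one variant; the tally sums to the restricted set size.
    """
    panel = set(genes)
    subset = VariantSet(
        variant_set.label,
        (v for v in variant_set if v.gene_id in panel),
        provenance=variant_set.provenance + " | gene-panel subset",
    )
    tally: dict[str, int] = {}
    for v in subset:
        tally[v.gene_id] = tally.get(v.gene_id, 0) + 1
    return subset, tally


# ---------------------------------------------------------------------------
# Tabular IO

VARIANT_COLUMNS = ["gene", "protein_position", "ref_aa", "alt_aa"]


def read_variant_table(
    path: str | Path,
    label: str | None = None,
    gene_models: Mapping[str, GeneModel] | None = None,
) -> VariantSet:
    """Read a tab-separated variant table into a VariantSet.

    Required columns: ``gene``, ``protein_position``, ``ref_aa``, ``alt_aa``;
    optional: ``consequence``, ``cohort``, ``significance``.  Lines starting
    with ``#`` are treated as a provenance header.  Multi-residue alleles
    (MNVs/indels) are dropped with a logged count — the analysis is
    missense-only.  When ``gene_models`` is given, records whose ``ref_aa``
    disagrees with the gene model at that position are rejected with a
    logged error rather than silently kept.
    """
    path = Path(path)
    provenance_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                provenance_lines.append(line.lstrip("# ").rstrip())
            else:
                break
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    variants = []
    n_multi = n_mismatch = 0
    for row in df.itertuples(index=False):
        ref, alt = str(row.ref_aa), str(row.alt_aa)
        if len(ref) != 1 or len(alt) != 1:
            n_multi += 1
            continue
        pos = int(row.protein_position)
        if gene_models is not None and row.gene in gene_models:
            model = gene_models[row.gene]
            if pos > len(model) or model.protein_seq[pos - 1] != ref:
                n_mismatch += 1
                continue
        if hasattr(row, "consequence") and isinstance(row.consequence, str):
            consequence = row.consequence
        elif alt == "*":
            consequence = NONSENSE
        elif ref == alt:
            consequence = SYNONYMOUS
        else:
            consequence = MISSENSE
        cohort = getattr(row, "cohort", None)
        sig = getattr(row, "significance", None)
        change = getattr(row, "codon_change", None)
        variants.append(
            Variant(
                gene_id=str(row.gene),
                codon_index=pos,
                ref_aa=ref,
                alt_aa=alt,
                consequence=consequence,
                cohort=cohort if isinstance(cohort, str) else "population",
                clinvar_significance=sig if isinstance(sig, str) else None,
                codon_change=change if isinstance(change, str) else None,
            )
        )
    if n_multi:
        logger.info("%s: dropped %d multi-residue record(s)", path, n_multi)
    if n_mismatch:
        logger.error(
            "%s: rejected %d record(s) whose ref_aa disagrees with the gene "
            "model (transcript mismatch)",
            path,
            n_mismatch,
        )
    return VariantSet(
        label or path.stem, variants, provenance="\n".join(provenance_lines)
    )


def write_variant_table(variant_set: VariantSet, path: str | Path) -> None:
    """Write a VariantSet as TSV with a provenance header block."""
    path = Path(path)
    rows = [
        {
            "gene": v.gene_id,
            "protein_position": v.codon_index,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "consequence": v.consequence,
            "cohort": v.cohort,
            "significance": v.clinvar_significance or "",
            "codon_change": v.codon_change or "",
        }
        for v in sorted(variant_set, key=lambda v: (v.gene_id, v.codon_index, v.ref_aa, v.alt_aa, v.codon_change or ""))
    ]
    with open(path, "w") as fh:
        fh.write(f"# label: {variant_set.label}\n")
        for line in variant_set.provenance.splitlines():
            fh.write(f"# {line}\n")
        pd.DataFrame(
            rows,
            columns=[
                "gene",
                "protein_position",
                "ref_aa",
                "alt_aa",
                "consequence",
                "cohort",
                "significance",
                "codon_change",
            ],
        ).to_csv(fh, sep="\t", index=False)
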