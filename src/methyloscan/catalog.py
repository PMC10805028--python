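"""Curated reference catalog of corrinoid-dependent methyltransferase genes.

Anaerobic methylotrophy — in methanogenic archaea and in bacteria feeding
methyl groups into the Wood-Ljungdahl pathway — runs through three-component
(corrinoid-dependent) methyltransferase systems: a substrate:corrinoid
methyltransferase (MtxB), a corrinoid-binding protein (MtxC) and a
methylcorrinoid:carbon-carrier methyltransferase (MtxA), reactivated by a
reductive activase (RamX).  The "x" varies with substrate (mtaB = methanol,
mttB = trimethylamine, ...).  Methyl-sulfide metabolism additionally occurs
as tri-functional fused proteins (MtsD/MtsF/MtsH) that combine the three
activities in one polypeptide.

This module loads, validates and indexes a reference catalog of such genes
(protein FASTA + TSV metadata) and a substrate chemistry table mapping
methylated compounds to their number of microbially available methyl
groups, which bounds the stoichiometry of CH4 formation from each compound.

The packaged default catalog is a synthetic stand-in that reproduces the
family composition of the curated field catalog (20 mtxB-family genes, 16
mtxC, 10 mtxA, 7 ramX; 53 gene types in total); users with access to the
original curated FASTA/metadata can load it with :func:`load_catalog`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class SystemRole(str, enum.Enum):
    """Component role within a three-component methyltransferase system."""

    MTXB = "MtxB"
    MTXC = "MtxC"
    MTXA = "MtxA"
    RAMX = "RamX"
    #: tri-functional fused methyl-sulfide methyltransferases (MtsD/MtsF/MtsH)
    MTS_FUSED = "MtsFused"


class SubstrateCategory(str, enum.Enum):
    METHYL_N = "methyl_N"
    METHYL_O = "methyl_O"
    METHYL_S = "methyl_S"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReferenceGene:
    """One curated methylotrophy reference gene.

    ``substrate_subtype`` carries the specific identity (e.g. "mtaB
    methanol", "mttB Pyl trimethylamine"); it is empty for the ambiguous
    category, which by construction carries no subtype.
    """

    id: str
    role: SystemRole
    substrate_category: SubstrateCategory
    substrate_subtype: str
    protein_seq: str
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.protein_seq:
            raise ValueError(f"reference gene {self.id!r} has an empty sequence")
        bad = set(self.protein_seq) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"reference gene {self.id!r} has non-amino-acid characters: {sorted(bad)}"
            )
        if self.substrate_category is SubstrateCategory.AMBIGUOUS and self.substrate_subtype:
            raise ValueError(
                f"reference gene {self.id!r}: ambiguous category carries no subtype"
            )


class CatalogError(ValueError):
    pass


@dataclass
class ReferenceCatalog:
    """Indexed collection of :class:`ReferenceGene` entries."""

    genes: dict[str, ReferenceGene] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[ReferenceGene]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> ReferenceGene:
        return self.genes[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def add(self, gene: ReferenceGene) -> None:
        if gene.id in self.genes:
            raise CatalogError(f"duplicate reference gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def role_counts(self) -> dict[SystemRole, int]:
        """Raw entry count per :class:`SystemRole`."""
        counts: dict[SystemRole, int] = {}
        for g in self:
            counts[g.role] = counts.get(g.role, 0) + 1
        return counts

    def family_counts(self) -> dict[str, int]:
        """Catalog composition over the four gene families (B/C/A/Ram).

        The tri-functional fused methyl-sulfide proteins carry the
        substrate:corrinoid methyltransferase (B) activity, so composition
        bookkeeping counts them with the mtxB family; the curated field
        catalog is described the same way (20 mtxB / 16 mtxC / 10 mtxA /
        7 ramX = 53 gene types).
        """
        counts = {"MtxB": 0, "MtxC": 0, "MtxA": 0, "RamX": 0}
        for g in self:
            key = "MtxB" if g.role is SystemRole.MTS_FUSED else g.role.value
            counts[key] += 1
        return counts


def _parse_enum(cls, token: str, what: str, gene_id: str):
    try:
        return cls(token)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise CatalogError(
            f"unknown {what} {token!r} for reference gene {gene_id!r} (valid: {valid})"
        ) from None


def load_catalog(fasta_path, metadata_path) -> ReferenceCatalog:
    """Load and validate a reference catalog from FASTA + metadata TSV.

    Metadata columns: id, role, substrate_category, substrate_subtype,
    source_note.  FASTA ids and metadata rows must match 1:1.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise CatalogError(f"duplicate reference gene id {rec.id!r} in FASTA")
        seqs[rec.id] = str(rec.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"id", "role", "substrate_category", "substrate_subtype", "source_note"}
    missing = required - set(meta.columns)
    if missing:
        raise CatalogError(f"metadata is missing columns: {sorted(missing)}")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise CatalogError(f"duplicate reference gene id {dup!r} in metadata")

    catalog = ReferenceCatalog()
    for row in meta.itertuples(index=False):
        if row.id not in seqs:
            raise CatalogError(f"metadata row {row.id!r} has no FASTA sequence")
        catalog.add(
            ReferenceGene(
                id=row.id,
                role=_parse_enum(SystemRole, row.role, "role", row.id),
                substrate_category=_parse_enum(
                    SubstrateCategory, row.substrate_category, "substrate category", row.id
                ),
                substrate_subtype=row.substrate_subtype,
                protein_seq=seqs[row.id],
                source_note=row.source_note,
            )
        )
    orphans = set(seqs) - set(meta["id"])
    if orphans:
        raise CatalogError(f"FASTA sequences without metadata rows: {sorted(orphans)}")
    return catalog


def write_catalog(catalog: ReferenceCatalog, fasta_path, metadata_path) -> None:
    """Write a catalog back to FASTA + metadata TSV (inverse of load)."""
    records = [
        SeqRecord(Seq(g.protein_seq), id=g.id, description="") for g in catalog
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "id": g.id,
            "role": g.role.value,
            "substrate_category": g.substrate_category.value,
            "substrate_subtype": g.substrate_subtype,
            "source_note": g.source_note,
        }
        for g in catalog
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def default_catalog() -> ReferenceCatalog:
    """The packaged synthetic stand-in catalog (53 gene types, 20/16/10/7)."""
    data = resources.files("methyloscan.data")
    with resources.as_file(data / "reference_catalog_synthetic.faa") as fa, resources.as_file(
        data / "reference_catalog_synthetic.tsv"
    ) as tsv:
        return load_catalog(fa, tsv)


# ---------------------------------------------------------------------------
# substrate chemistry


def load_chem_table(path=None) -> pd.DataFrame:
    """Load a substrate chemistry table (name, category, methyl_equivalents).

    ``methyl_equivalents`` is the number of microbially available methyl
    groups per molecule, e.g. 1 for methanol, 3 for trimethylamine.  With
    ``path=None`` the packaged table is loaded.
    """
    if path is None:
        data = resources.files("methyloscan.data")
        with resources.as_file(data / "substrate_chemistry.tsv") as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"name", "category", "methyl_equivalents"}
    if missing := required - set(table.columns):
        raise CatalogError(f"chemistry table missing columns: {sorted(missing)}")
    if (table["methyl_equivalents"] < 0).any() or not pd.api.types.is_integer_dtype(
        table["methyl_equivalents"]
    ):
        raise CatalogError("methyl_equivalents must be non-negative integers")
    return table


def methyl_equivalents(substrate_name: str, chem_table: pd.DataFrame) -> int:
    """Microbially available methyl groups per molecule of a substrate."""
    match = chem_table.loc[chem_table["name"] == substrate_name, "methyl_equivalents"]
    if match.empty:
        known = ", ".join(sorted(chem_table["name"]))
        raise KeyError(f"unknown substrate {substrate_name!r}; known substrates: {known}")
    return int(match.iloc[0])


def ch4_yield_ratio(a: str, b: str, chem_table: pd.DataFrame) -> Fraction:
    """Molar CH4-yield ratio of substrate ``a`` relative to substrate ``b``.

    One molar equivalent of a compound can support CH4 production in
    proportion to its available methyl groups, so e.g. a tri-methoxylated
    compound supports three times as much CH4 as methanol.
    """
    num = methyl_equivalents(a, chem_table)
    den = methyl_equivalents(b, chem_table)
    if den == 0:
        raise ZeroDivisionError(f"substrate {b!r} carries no available methyl groups")
    return Fraction(num, den)
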