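"""Substrate-resolved gene identity assignment with synteny and Pyl evidence.

Filtered homology hits are converted into per-gene assignments: the role
and substrate category of the best-scoring reference, guarded by a
cross-category bitscore margin that replaces manual phylogenetic
inspection — when the best hit outscores the best hit from any *other*
substrate category by less than the margin, the gene is called substrate
ambiguous (methylotrophy-relevant but substrate-nonspecific), exactly the
fate of equivocal tree placements in manual curation.

Synteny: mtxBCA/ramX genes are frequently co-encoded, so assigned genes
clustered on one contig are recorded as operon evidence and flagged
syntenic.  Synteny is confidence metadata; it does not gate the
methylotrophy call.

Pyl resolution: trimethylamine methyltransferase (mttB) genes encode the
22nd amino acid pyrrolysine via an in-frame amber (TAG) codon, which
truncates naive gene calls.  ``detect_pyl`` inspects the nucleotide CDS
(with downstream context) for the truncation + amber + readthrough
signature distinguishing Pyl-MttB (tri/di/monomethylamine) from non-Pyl
MttB homologs (quaternary amines such as glycine betaine and choline).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .catalog import ReferenceCatalog, SubstrateCategory, SystemRole
from .screen import Hit


class PylStatus(str, enum.Enum):
    PYL = "pyl"
    NON_PYL = "non_pyl"
    NOT_APPLICABLE = "not_applicable"


@dataclass
class GeneAssignment:
    gene_id: str
    mag_id: str
    role: SystemRole
    substrate: SubstrateCategory
    subtype: str
    best_reference_id: str
    best_bitscore: float
    #: best bitscore minus best competing bitscore from a different
    #: substrate category; +inf when no cross-category competitor exists
    margin_bits: float
    syntenic: bool = False
    pyl_status: PylStatus = PylStatus.NOT_APPLICABLE


@dataclass
class OperonEvidence:
    mag_id: str
    contig_id: str
    member_gene_ids: list[str]
    roles_present: set[SystemRole]
    max_intergenic_genes: int


class AssignmentError(ValueError):
    pass


def assign_identity(
    hits_for_gene: Sequence[Hit],
    catalog: ReferenceCatalog,
    margin_threshold: float = 10.0,
) -> GeneAssignment:
    """Resolve one gene's identity from its (bitscore-filtered) hits.

    The role comes from the best-bitscore reference (ties broken
    lexicographically by reference id, so the result is independent of hit
    ordering).  The substrate category is the best reference's category iff
    the cross-category margin is at least ``margin_threshold`` bits or all
    competitors within the margin share that category; otherwise the gene
    is substrate ambiguous.  RamX hits never resolve a substrate: activases
    are promiscuous across corrinoid proteins.
    """
    if not hits_for_gene:
        raise AssignmentError("cannot assign identity from an empty hit list")
    ordered = sorted(hits_for_gene, key=lambda h: (-h.bitscore, h.reference_id))
    best = ordered[0]
    best_ref = catalog[best.reference_id]

    competing = [
        h for h in ordered[1:]
        if catalog[h.reference_id].substrate_category != best_ref.substrate_category
    ]
    margin = best.bitscore - competing[0].bitscore if competing else math.inf

    if best_ref.role is SystemRole.RAMX:
        substrate, subtype = SubstrateCategory.AMBIGUOUS, ""
    elif margin >= margin_threshold:
        substrate, subtype = best_ref.substrate_category, best_ref.substrate_subtype
    else:
        substrate, subtype = SubstrateCategory.AMBIGUOUS, ""

    return GeneAssignment(
        gene_id=best.query_gene_id,
        mag_id=best.mag_id,
        role=best_ref.role,
        substrate=substrate,
        subtype=subtype,
        best_reference_id=best.reference_id,
        best_bitscore=best.bitscore,
        margin_bits=margin,
    )


def assign_all(
    hits: Sequence[Hit], catalog: ReferenceCatalog, margin_threshold: float = 10.0
) -> list[GeneAssignment]:
    """Group hits by gene and assign each; sorted by (mag, gene)."""
    by_gene: dict[str, list[Hit]] = {}
    for h in hits:
        by_gene.setdefault(h.query_gene_id, []).append(h)
    assignments = [
        assign_identity(gene_hits, catalog, margin_threshold)
        for gene_hits in by_gene.values()
    ]
    assignments.sort(key=lambda a: (a.mag_id, a.gene_id))
    return assignments


# ---------------------------------------------------------------------------
# operon / synteny evidence


def _gene_order_from_gff(gff) -> dict[str, tuple[str, int]]:
    """gene id -> (contig, ordinal position along the contig).

    ``gff`` is a GFF3 file path, or the GFF3 text itself (detected by an
    embedded newline).
    """
    from_string = isinstance(gff, str) and "\n" in gff
    db = gffutils.create_db(
        gff if from_string else str(gff), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", from_string=from_string,
    )
    per_contig: dict[str, list[tuple[int, str]]] = {}
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        per_contig.setdefault(feat.seqid, []).append((feat.start, gene_id))
    order: dict[str, tuple[str, int]] = {}
    for contig, entries in per_contig.items():
        entries.sort()
        for ordinal, (_, gene_id) in enumerate(entries):
            order[gene_id] = (contig, ordinal)
    return order


def detect_operons(
    assignments: Sequence[GeneAssignment],
    gff_path,
    max_intergenic: int = 2,
) -> tuple[list[OperonEvidence], list[GeneAssignment]]:
    """Cluster assigned genes into operon evidence and set syntenic flags.

    Assigned genes on one contig separated by at most ``max_intergenic``
    intervening (unassigned) genes are clustered; clusters spanning >= 2
    distinct roles become :class:`OperonEvidence` and their members are
    flagged syntenic.  The intervening-gene count is strand-agnostic and
    invariant to reversing contig coordinates.

    Returns (operons, assignments-with-flags); input assignments are not
    mutated.
    """
    order = _gene_order_from_gff(gff_path)
    for a in assignments:
        if a.gene_id not in order:
            raise AssignmentError(f"assigned gene {a.gene_id!r} is missing from the GFF")

    by_contig: dict[tuple[str, str], list[tuple[int, GeneAssignment]]] = {}
    for a in assignments:
        contig, ordinal = order[a.gene_id]
        by_contig.setdefault((a.mag_id, contig), []).append((ordinal, a))

    operons: list[OperonEvidence] = []
    syntenic_genes: set[str] = set()
    for (mag_id, contig), entries in sorted(by_contig.items()):
        entries.sort()
        cluster: list[tuple[int, GeneAssignment]] = []
        chunks: list[list[tuple[int, GeneAssignment]]] = []
        for ordinal, a in entries:
            if cluster and ordinal - cluster[-1][0] - 1 > max_intergenic:
                chunks.append(cluster)
                cluster = []
            cluster.append((ordinal, a))
        if cluster:
            chunks.append(cluster)
        for chunk in chunks:
            roles = {a.role for _, a in chunk}
            if len(chunk) >= 2 and len(roles) >= 2:
                members = [a.gene_id for _, a in chunk]
                operons.append(
                    OperonEvidence(
                        mag_id=mag_id,
                        contig_id=contig,
                        member_gene_ids=members,
                        roles_present=roles,
                        max_intergenic_genes=max(
                            (b[0] - a[0] - 1 for a, b in zip(chunk, chunk[1:])),
                            default=0,
                        ),
                    )
                )
                syntenic_genes.update(members)

    flagged = [replace(a, syntenic=a.gene_id in syntenic_genes) for a in assignments]
    return operons, flagged


# ---------------------------------------------------------------------------
# pyrrolysine amber-codon detection

_STOPS = {"TAA", "TAG", "TGA"}
_NT = frozenset("ACGT")


@dataclass
class PylResult:
    status: PylStatus
    low_confidence: bool = False
    called_length_aa: int = 0
    stop_codon: str = ""
    readthrough_aa: int = 0


def detect_pyl(
    cds_nt: str,
    reference_length_aa: int,
    min_truncation: float = 0.7,
    min_readthrough_aa: int = 30,
) -> PylResult:
    """Classify an mttB-family CDS as Pyl or non-Pyl from its nucleotides.

    ``cds_nt`` is the annotated CDS *with downstream context* appended, so
    the annotated stop is the first in-frame stop codon.  The Pyl signature
    is threefold: the called protein is truncated (shorter than
    ``min_truncation`` x the reference length), the terminating codon is
    amber (TAG), and in-frame translation past the amber continues for at
    least ``min_readthrough_aa`` codons before the next stop.  Full-length
    calls, or genes terminated by TAA/TGA, are non-Pyl.  A truncated amber
    gene without enough downstream context (or with ambiguous nucleotides
    in frame) is still called, flagged low-confidence.

    Pure function of the nucleotide string and parameters.
    """
    if reference_length_aa <= 0:
        raise AssignmentError("reference_length_aa must be positive")
    nt = cds_nt.upper().replace("U", "T")
    codons = [nt[i : i + 3] for i in range(0, len(nt) - len(nt) % 3, 3)]

    low_confidence = False
    stop_idx = None
    for i, codon in enumerate(codons):
        if set(codon) - _NT:
            low_confidence = True
            continue
        if codon in _STOPS:
            stop_idx = i
            break

    if stop_idx is None:
        # no stop within the provided sequence: treat as full-length-like
        return PylResult(
            PylStatus.NON_PYL, low_confidence=True,
            called_length_aa=len(codons), stop_codon="",
        )

    called_len = stop_idx
    stop = codons[stop_idx]
    truncated = called_len < min_truncation * reference_length_aa

    if not truncated or stop in ("TAA", "TGA"):
        return PylResult(
            PylStatus.NON_PYL, low_confidence=low_confidence,
            called_length_aa=called_len, stop_codon=stop,
        )

    # truncated + amber: count clean readthrough codons after the TAG
    readthrough = 0
    for codon in codons[stop_idx + 1 :]:
        if set(codon) - _NT:
            low_confidence = True
            break
        if codon in _STOPS:
            break
        readthrough += 1

    context_codons = len(codons) - stop_idx - 1
    if context_codons < min_readthrough_aa and readthrough == context_codons:
        # ran out of context before the readthrough criterion could resolve
        return PylResult(
            PylStatus.PYL if readthrough > 0 else PylStatus.NON_PYL,
            low_confidence=True,
            called_length_aa=called_len, stop_codon=stop,
            readthrough_aa=readthrough,
        )

    status = PylStatus.PYL if readthrough >= min_readthrough_aa else PylStatus.NON_PYL
    return PylResult(
        status, low_confidence=low_confidence,
        called_length_aa=called_len, stop_codon=stop, readthrough_aa=readthrough,
    )


_MTTB_SUBTYPES = ("mttB", "non-Pyl mttB")


def refine_mttb_substrate(
    assignment: GeneAssignment, pyl_status: PylStatus
) -> GeneAssignment:
    """Split an mttB-family assignment into Pyl vs non-Pyl subtypes.

    Pyl-MttB homologs demethylate tri/di/monomethylamine; non-Pyl MttB
    homologs are specific for quaternary amines.  Both remain methyl-N.
    """
    if assignment.role is not SystemRole.MTXB or not any(
        assignment.subtype.startswith(s) for s in _MTTB_SUBTYPES
    ):
        raise AssignmentError(
            f"gene {assignment.gene_id!r} is not an mttB-family assignment "
            f"(role {assignment.role.value}, subtype {assignment.subtype!r})"
        )
    if pyl_status is PylStatus.PYL:
        subtype = "Pyl-MttB (tri/di/monomethylamine)"
    else:
        subtype = "non-Pyl MttB (quaternary amine)"
    return replace(
        assignment,
        substrate=SubstrateCategory.METHYL_N,
        subtype=subtype,
        pyl_status=pyl_status,
    )


# ---------------------------------------------------------------------------
# TSV interchange

_COLUMNS = [
    "gene_id", "mag_id", "role", "substrate", "subtype", "best_reference_id",
    "best_bitscore", "margin_bits", "syntenic", "pyl_status",
]


def write_assignments(assignments: Iterable[GeneAssignment], path) -> None:
    rows = [
        {
            "gene_id": a.gene_id,
            "mag_id": a.mag_id,
            "role": a.role.value,
            "substrate": a.substrate.value,
            "subtype": a.subtype,
            "best_reference_id": a.best_reference_id,
            "best_bitscore": a.best_bitscore,
            "margin_bits": a.margin_bits,
            "syntenic": a.syntenic,
            "pyl_status": a.pyl_status.value,
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> list[GeneAssignment]:
    df = pd.read_csv(path, sep="\t").fillna({"subtype": ""})
    return [
        GeneAssignment(
            gene_id=str(r.gene_id),
            mag_id=str(r.mag_id),
            role=SystemRole(r.role),
            substrate=SubstrateCategory(r.substrate),
            subtype=str(r.subtype),
            best_reference_id=str(r.best_reference_id),
            best_bitscore=float(r.best_bitscore),
            margin_bits=float(r.margin_bits),
            syntenic=bool(r.syntenic),
            pyl_status=PylStatus(r.pyl_status),
        )
        for r in df.itertuples(index=False)
    ]
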