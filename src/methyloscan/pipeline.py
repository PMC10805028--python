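"""End-to-end orchestration: screen -> assign -> classify -> quantify.

Glue over the stage modules, used by the command-line interface and by the
round-trip validation against synthetic communities.  Archaeal MAGs are
screened against the full catalog at bitscore > 60 with the mtxB-gate
filter; bacterial MAGs are screened against the mtxB-family references
only, at bitscore > 200.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import assign as assign_mod
from . import classify as classify_mod
from . import quant as quant_mod
from .assign import GeneAssignment, OperonEvidence, PylStatus
from .catalog import ReferenceCatalog, SystemRole, default_catalog
from .classify import MarkerConfig, MethylotrophyCall
from .screen import Hit, ScoringScheme, filter_archaeal_hits, screen_proteome

ARCHAEAL_MIN_BITSCORE = 60.0
BACTERIAL_MIN_BITSCORE = 200.0


def mtxb_subcatalog(catalog: ReferenceCatalog) -> ReferenceCatalog:
    """Catalog restricted to mtxB-family references (incl. fused MtsDFH)."""
    sub = ReferenceCatalog()
    for g in catalog:
        if g.role in (SystemRole.MTXB, SystemRole.MTS_FUSED):
            sub.add(g)
    return sub


def screen_community(
    proteomes: dict[str, list[tuple[str, str]]],
    catalog: ReferenceCatalog,
    domains: dict[str, str],
    scheme: ScoringScheme | None = None,
) -> list[Hit]:
    """Domain-aware screen of per-MAG proteomes.

    Archaea: full catalog, bitscore > 60, then the mtxB-gate MAG filter.
    Bacteria: mtxB-family references only, bitscore > 200 (single best
    marker gene; avoids nonspecific hits to other cobalamin-binding
    proteins).
    """
    scheme = scheme or ScoringScheme()
    bac_catalog = mtxb_subcatalog(catalog)
    archaeal_hits: list[Hit] = []
    bacterial_hits: list[Hit] = []
    for mag_id in sorted(proteomes):
        domain = domains.get(mag_id, "archaeal")
        if domain == "bacterial":
            bacterial_hits += screen_proteome(
                proteomes[mag_id], bac_catalog, scheme,
                min_bitscore=BACTERIAL_MIN_BITSCORE, mag_id=mag_id,
            )
        else:
            archaeal_hits += screen_proteome(
                proteomes[mag_id], catalog, scheme,
                min_bitscore=ARCHAEAL_MIN_BITSCORE, mag_id=mag_id,
            )
    return filter_archaeal_hits(archaeal_hits, catalog) + bacterial_hits


def assign_with_evidence(
    hits: list[Hit],
    catalog: ReferenceCatalog,
    gff_path,
    cds: dict[str, str] | None = None,
    margin_threshold: float = 10.0,
    max_intergenic: int = 2,
) -> tuple[list[GeneAssignment], list[OperonEvidence]]:
    """Hits -> assignments with synteny flags and Pyl-refined mttB calls."""
    assignments = assign_mod.assign_all(hits, catalog, margin_threshold)
    operons, assignments = assign_mod.detect_operons(assignments, gff_path, max_intergenic)
    if cds:
        refined = []
        for a in assignments:
            is_mttb = a.role is SystemRole.MTXB and (
                a.subtype.startswith("mttB") or a.subtype.startswith("non-Pyl mttB")
            )
            if is_mttb and a.gene_id in cds:
                ref_len = len(catalog[a.best_reference_id].protein_seq)
                result = assign_mod.detect_pyl(cds[a.gene_id], ref_len)
                a = assign_mod.refine_mttb_substrate(a, result.status)
            refined.append(a)
        assignments = refined
    return assignments, operons


@dataclass
class PipelineResult:
    hits: list[Hit]
    assignments: list[GeneAssignment]
    operons: list[OperonEvidence]
    calls: list[MethylotrophyCall]
    physiology: pd.DataFrame


def run_genotype_pipeline(
    proteomes: dict[str, list[tuple[str, str]]],
    annotation_table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    gff,
    cds: dict[str, str] | None = None,
    catalog: ReferenceCatalog | None = None,
    cfg: MarkerConfig | None = None,
    margin_threshold: float = 10.0,
) -> PipelineResult:
    """Screen, assign and classify a community of MAG proteomes.

    ``gff`` is a path or the GFF3 text itself.
    """
    catalog = catalog or default_catalog()
    domains = {
        str(r.mag_id): "bacterial" if str(r.gtdb_taxonomy).startswith("d__Bacteria")
        else "archaeal"
        for r in taxonomy.itertuples(index=False)
    }
    hits = screen_community(proteomes, catalog, domains)
    assignments, operons = assign_with_evidence(
        hits, catalog, gff, cds, margin_threshold
    )
    calls = classify_mod.classify_community(
        assignments, annotation_table, taxonomy, cfg, domains
    )
    return PipelineResult(
        hits=hits,
        assignments=assignments,
        operons=operons,
        calls=calls,
        physiology=classify_mod.calls_to_frame(calls),
    )


def run_activity(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sample_design: pd.DataFrame,
    assignments: list[GeneAssignment],
    operons: list[OperonEvidence] = (),
    params: quant_mod.NormalizationParams | None = None,
) -> pd.DataFrame:
    """Counts -> geTMM -> active-methylotroph calls per MAG and group."""
    getmm_matrix = quant_mod.getmm(counts, lengths, params)
    return quant_mod.classify_active_methylotroph(
        getmm_matrix, assignments, sample_design, operons
    )
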