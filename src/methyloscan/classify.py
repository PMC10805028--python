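"""Rule-based per-MAG physiology calls.

Combines annotation-derived methanogenesis markers with substrate-resolved
methyltransferase assignments into a per-MAG verdict:

* ``is_methanogen`` — Mcr and Hdr complex marker sets both meet their
  presence thresholds;
* pathway potentials — hydrogenotrophic / acetoclastic marker sets, plus
  methylotrophic from the methyltransferase gene content;
* ``is_methylotroph`` — for archaea, at least two of the three core system
  members (MtxB, MtxC, MtxA), one of which must be the substrate-
  demethylating mtxB, OR a single tri-functional fused methyl-sulfide gene
  (MtsD/F/H), OR at least one of mtsA/mtsB; for bacteria, mtxB alone is the
  marker gene (the screen's higher bitscore bar provides the specificity);
* substrate profile — union of non-ambiguous MtxB/MtsFused/mtsAB substrate
  categories; RamX and ambiguous MtxA/MtxC never contribute;
* lifestyle — obligate methylotroph when methylotrophy is the only encoded
  methanogenesis pathway, facultative when other pathways are co-encoded.

Every call carries an ordered rule trace so verdicts can be replayed and
audited.  Marker gene sets and thresholds are configuration, not code:
hydrogenotrophic and acetoclastic indicator sets vary between studies, so
the defaults here are documented, swappable sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .assign import GeneAssignment
from .catalog import SubstrateCategory, SystemRole

LIFESTYLES = ("obligate_methylotroph", "facultative_methylotroph", "non_methylotroph")


@dataclass
class MarkerSet:
    """A named indicator gene set with a presence threshold (fraction)."""

    name: str
    genes: frozenset[str]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} is empty")
        if not 0 < self.threshold <= 1:
            raise ValueError(f"marker set {self.name!r}: threshold must be in (0, 1]")

    def met(self, symbols: set[str]) -> bool:
        present = len(self.genes & symbols)
        return present / len(self.genes) >= self.threshold


@dataclass
class MarkerConfig:
    """Marker sets for methanogen detection and pathway typing.

    ``methanogen_core`` sets must *all* be met (default: Mcr and Hdr
    complexes).  ``hydrogenotrophic`` / ``acetoclastic`` are lists of
    alternative indicator sets; meeting any one set adds the pathway
    (acetoclastic defaults offer two routes: ackA+pta, or the CO
    dehydrogenase / acetyl-CoA decarbonylase complex).
    """

    methanogen_core: list[MarkerSet] = field(default_factory=lambda: [
        MarkerSet("mcr", frozenset({"mcrA", "mcrB", "mcrG"}), 2 / 3),
        MarkerSet("hdr", frozenset({"hdrA", "hdrB", "hdrC"}), 2 / 3),
    ])
    hydrogenotrophic: list[MarkerSet] = field(default_factory=lambda: [
        MarkerSet(
            "hydrogenotrophic",
            frozenset({"fwdA", "fmdA", "ftr", "mch", "mtd", "mer", "frhA", "echA"}),
            0.5,
        ),
    ])
    acetoclastic: list[MarkerSet] = field(default_factory=lambda: [
        MarkerSet("ackA_pta", frozenset({"ackA", "pta"}), 1.0),
        MarkerSet("cdh", frozenset({"cdhA", "cdhB", "cdhC", "cdhD", "cdhE"}), 0.6),
    ])

    @classmethod
    def from_yaml(cls, path) -> "MarkerConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def parse(entries) -> list[MarkerSet]:
            return [
                MarkerSet(e["name"], frozenset(e["genes"]), float(e.get("threshold", 0.5)))
                for e in entries
            ]

        return cls(
            methanogen_core=parse(raw["methanogen_core"]),
            hydrogenotrophic=parse(raw["hydrogenotrophic"]),
            acetoclastic=parse(raw["acetoclastic"]),
        )


@dataclass
class MethylotrophyCall:
    mag_id: str
    is_methanogen: bool
    pathways: set[str]
    is_methylotroph: bool
    substrate_profile: set[SubstrateCategory]
    lifestyle: str
    rule_trace: list[str] = field(default_factory=list)


class ClassificationError(ValueError):
    pass


def classify_methanogen(
    annotation_symbols: Mapping[str, set[str]] | pd.DataFrame,
    mag_id: str,
    cfg: MarkerConfig | None = None,
    trace: list[str] | None = None,
) -> tuple[bool, set[str]]:
    """Methanogen yes/no and marker-derived pathway potentials for one MAG.

    ``annotation_symbols`` maps MAG -> set of annotated gene symbols, or is
    a DataFrame with ``mag_id`` / ``gene_symbol`` columns (DRAM-style
    distilled annotations consumed as TSV).
    """
    cfg = cfg or MarkerConfig()
    trace = trace if trace is not None else []
    if isinstance(annotation_symbols, pd.DataFrame):
        table = annotation_symbols
        if mag_id not in set(table["mag_id"]):
            raise ClassificationError(f"MAG {mag_id!r} absent from the annotation table")
        symbols = set(table.loc[table["mag_id"] == mag_id, "gene_symbol"])
    else:
        if mag_id not in annotation_symbols:
            raise ClassificationError(f"MAG {mag_id!r} absent from the annotation table")
        symbols = set(annotation_symbols[mag_id])

    core_met = [ms.met(symbols) for ms in cfg.methanogen_core]
    is_methanogen = all(core_met)
    for ms, ok in zip(cfg.methanogen_core, core_met):
        trace.append(f"core marker set {ms.name}: {'met' if ok else 'not met'}")
    pathways: set[str] = set()
    if is_methanogen:
        if any(ms.met(symbols) for ms in cfg.hydrogenotrophic):
            pathways.add("hydrogenotrophic")
            trace.append("hydrogenotrophic markers met")
        if any(ms.met(symbols) for ms in cfg.acetoclastic):
            pathways.add("acetoclastic")
            trace.append("acetoclastic markers met")
    return is_methanogen, pathways


def _is_mts_two_part(a: GeneAssignment) -> bool:
    return a.role is SystemRole.MTXB and a.subtype.split()[0:1] in (["mtsA"], ["mtsB"])


def call_methylotrophy(
    assignments: Sequence[GeneAssignment],
    domain: str = "archaeal",
    trace: list[str] | None = None,
) -> bool:
    """Methylotrophy verdict for one MAG from its gene assignments.

    Archaeal rule: genes for at least two of the three core system members
    (MtxB, MtxC, MtxA) with MtxB mandatory; the methyl-sulfide exception
    accepts a single tri-functional MtsDFH gene or at least one of
    mtsA/mtsB.  Bacterial rule: any MtxB homolog suffices (the screen is
    restricted to mtxB as the best single marker gene).
    """
    if domain not in ("archaeal", "bacterial"):
        raise ClassificationError(f"unknown domain {domain!r}")
    trace = trace if trace is not None else []
    roles = {a.role for a in assignments}
    has_b = SystemRole.MTXB in roles

    if domain == "bacterial":
        verdict = has_b or SystemRole.MTS_FUSED in roles
        trace.append(
            "bacterial rule: mtxB homolog "
            + ("present -> methylotroph" if verdict else "absent -> not methylotroph")
        )
        return verdict

    core_present = roles & {SystemRole.MTXB, SystemRole.MTXC, SystemRole.MTXA}
    if len(core_present) >= 2 and has_b:
        trace.append(
            f"completeness rule: {len(core_present)}/3 core members incl. mtxB -> methylotroph"
        )
        return True
    if SystemRole.MTS_FUSED in roles:
        trace.append("methyl-sulfide exception: tri-functional MtsDFH gene -> methylotroph")
        return True
    if any(_is_mts_two_part(a) for a in assignments):
        trace.append("methyl-sulfide exception: mtsA/mtsB gene -> methylotroph")
        return True
    trace.append(
        f"completeness rule not met ({len(core_present)}/3 core members, "
        f"mtxB {'present' if has_b else 'absent'}) -> not methylotroph"
    )
    return False


def substrate_profile(assignments: Sequence[GeneAssignment]) -> set[SubstrateCategory]:
    """Union of substrate categories supported by substrate-informative genes.

    Only non-ambiguous MtxB/MtsFused (and mtsA/mtsB) assignments inform the
    profile; RamX and substrate-ambiguous MtxA/MtxC genes are evidence of
    methylotrophy but never of a specific substrate.
    """
    profile: set[SubstrateCategory] = set()
    for a in assignments:
        if a.substrate is SubstrateCategory.AMBIGUOUS:
            continue
        if a.role in (SystemRole.MTXB, SystemRole.MTS_FUSED):
            profile.add(a.substrate)
    return profile


def classify_lifestyle(is_methanogen: bool, pathways: set[str]) -> str:
    """Obligate vs facultative methylotroph from pathway potentials."""
    if not is_methanogen:
        raise ClassificationError("lifestyle is defined only for methanogens")
    if "methylotrophic" not in pathways:
        return "non_methylotroph"
    if pathways == {"methylotrophic"}:
        return "obligate_methylotroph"
    return "facultative_methylotroph"


def classify_mag(
    mag_id: str,
    assignments: Sequence[GeneAssignment],
    annotation_symbols: Mapping[str, set[str]] | pd.DataFrame,
    cfg: MarkerConfig | None = None,
    domain: str = "archaeal",
) -> MethylotrophyCall:
    """Full physiology call for one MAG (verdicts invariant to row order)."""
    trace: list[str] = []
    assignments = sorted(assignments, key=lambda a: a.gene_id)
    is_methanogen, pathways = classify_methanogen(annotation_symbols, mag_id, cfg, trace)
    is_methylotroph = call_methylotrophy(assignments, domain, trace)
    profile = substrate_profile(assignments)
    if is_methylotroph and is_methanogen:
        pathways = pathways | {"methylotrophic"}
    if is_methanogen:
        lifestyle = classify_lifestyle(is_methanogen, pathways)
    else:
        lifestyle = "non_methylotroph"
    trace.append(f"lifestyle: {lifestyle}")
    return MethylotrophyCall(
        mag_id=mag_id,
        is_methanogen=is_methanogen,
        pathways=pathways,
        is_methylotroph=is_methylotroph,
        substrate_profile=profile,
        lifestyle=lifestyle,
        rule_trace=trace,
    )


def classify_community(
    assignments: Sequence[GeneAssignment],
    annotation_table: pd.DataFrame,
    taxonomy: pd.DataFrame | None = None,
    cfg: MarkerConfig | None = None,
    domains: Mapping[str, str] | None = None,
) -> list[MethylotrophyCall]:
    """Classify every MAG in the annotation table.

    ``taxonomy`` (columns mag_id, gtdb_taxonomy) determines each MAG's
    domain when ``domains`` is not given; MAGs whose taxonomy string starts
    with ``d__Bacteria`` use the bacterial single-marker rule.
    """
    by_mag: dict[str, list[GeneAssignment]] = {}
    for a in assignments:
        by_mag.setdefault(a.mag_id, []).append(a)
    if domains is None:
        domains = {}
        if taxonomy is not None:
            for r in taxonomy.itertuples(index=False):
                domains[str(r.mag_id)] = (
                    "bacterial" if str(r.gtdb_taxonomy).startswith("d__Bacteria")
                    else "archaeal"
                )
    calls = []
    for mag_id in sorted(set(annotation_table["mag_id"])):
        calls.append(
            classify_mag(
                mag_id,
                by_mag.get(mag_id, []),
                annotation_table,
                cfg,
                domains.get(mag_id, "archaeal"),
            )
        )
    return calls


def calls_to_frame(calls: Iterable[MethylotrophyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mag_id": c.mag_id,
                "is_methanogen": c.is_methanogen,
                "pathways": ";".join(sorted(c.pathways)),
                "is_methylotroph": c.is_methylotroph,
                "substrate_profile": ";".join(sorted(s.value for s in c.substrate_profile)),
                "lifestyle": c.lifestyle,
            }
            for c in calls
        ]
    )


def write_rule_traces(calls: Iterable[MethylotrophyCall], path) -> None:
    with open(path, "w") as fh:
        json.dump({c.mag_id: c.rule_trace for c in calls}, fh, indent=2)
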