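"""Synthetic labeled communities for end-to-end pipeline validation.

Real inputs to the pipeline are MAG proteomes, CDS nucleotide FASTAs,
GFF3 gene coordinates, DRAM-style annotation tables, metatranscriptome
count matrices and per-contig depth tables.  This module fabricates all of
them from an explicit :class:`CommunityDesign` whose every label is known:

* planted methyltransferase genes are mutated copies of catalog references
  at a controlled amino-acid identity, back-translated to nucleotide CDS
  (uniform synonymous codon choice under the seed), optionally with an
  in-frame amber (TAG) codon to emulate pyrrolysine-encoding mttB genes —
  the annotated protein is then the truncated pre-amber prefix, as a naive
  gene caller would produce;
* decoy proteins are both random sequences and low-identity (30-45%)
  mutants of corrinoid-binding (mtxC) references, stressing screen
  specificity the way environmental cobalamin-binding proteins do;
* methanogenesis marker annotations are emitted to match each MAG's
  designed pathway set;
* counts are negative binomial with group means proportional to designed
  activity x abundance (inactive systems get mean zero); depth vectors are
  drawn so trimmed-mean coverage recovers the designed relative abundance.

Seeds fully determine every output; a zero-noise mode replaces sampling
with expectations for exact round-trip tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Data import CodonTable

from .catalog import (
    ReferenceCatalog,
    ReferenceGene,
    SubstrateCategory,
    SystemRole,
    default_catalog,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: marker symbols emitted per designed pathway (match the classifier defaults)
MARKER_SYMBOLS = {
    "core": ["mcrA", "mcrB", "mcrG", "hdrA", "hdrB", "hdrC"],
    "hydrogenotrophic": ["fwdA", "fmdA", "ftr", "mch", "mtd", "mer", "frhA", "echA"],
    "acetoclastic": ["ackA", "pta", "cdhA", "cdhB", "cdhC", "cdhD", "cdhE"],
}

_DOWNSTREAM_CONTEXT_NT = 120


class SimulationError(ValueError):
    pass


def _exchange_probs() -> tuple[np.ndarray, dict[str, int]]:
    from Bio.Align import substitution_matrices

    b62 = substitution_matrices.load("BLOSUM62")
    n = len(_AA)
    probs = np.zeros((n, n))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            if i != j:
                probs[i, j] = np.exp(float(b62[a, b]))
        probs[i] /= probs[i].sum()
    return probs, {a: i for i, a in enumerate(_AA)}


_EXCHANGE, _AA_INDEX = _exchange_probs()

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()


def mutate_protein(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute residues (BLOSUM62-exchangeable) to hit a target identity.

    The realized identity is within +-2% of the target; shorter sequences
    for which the rounding error alone exceeds that band raise.
    """
    if not 0.2 < target_identity <= 1.0:
        raise SimulationError("target identity must be in (0.2, 1.0]")
    n = len(seq)
    if 0.5 / n > 0.02:
        raise SimulationError(f"sequence of length {n} too short for a +-2% identity target")
    n_mut = int(round(n * (1.0 - target_identity)))
    pos = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        current = out[p]
        if current not in _AA_INDEX:  # X etc.: replace uniformly
            out[p] = _AA[rng.integers(len(_AA))]
            continue
        out[p] = _AA[rng.choice(len(_AA), p=_EXCHANGE[_AA_INDEX[current]])]
    return "".join(out)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide CDS under the standard code, uniform synonymous codons."""
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS.get(aa)
        if options is None:  # X and friends: arbitrary codon
            options = _AA_TO_CODONS["A"]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


@dataclass
class MutatedGene:
    """A planted gene derived from a reference."""

    reference_id: str
    protein_full: str        # true protein (Pyl position included, as K)
    protein_called: str      # what a naive gene caller annotates
    cds_with_context: str    # annotated CDS + stop + downstream context
    called_cds_length_nt: int
    is_pyl: bool


def mutate_reference(
    reference: ReferenceGene,
    target_identity: float,
    rng: np.random.Generator | int,
    pyl_codon_fraction: float | None = None,
) -> MutatedGene:
    """Derive a planted gene from a catalog reference.

    With ``pyl_codon_fraction`` set, the codon at that fraction of the gene
    is replaced by the amber (TAG) codon; the called protein is the prefix
    before it and the remainder of the gene becomes downstream context, so
    the Pyl signature (truncation + amber + clean readthrough) is present
    by construction.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    protein = mutate_protein(reference.protein_seq, target_identity, rng)
    nt = back_translate(protein, rng)
    if pyl_codon_fraction is None:
        cds = nt + "TAA"
        context = back_translate(
            "".join(_AA[rng.integers(len(_AA))] for _ in range(_DOWNSTREAM_CONTEXT_NT // 3)),
            rng,
        )
        return MutatedGene(
            reference_id=reference.id,
            protein_full=protein,
            protein_called=protein,
            cds_with_context=cds + context,
            called_cds_length_nt=len(cds),
            is_pyl=False,
        )
    pyl_at = int(len(protein) * pyl_codon_fraction)
    if not 0 < pyl_at < len(protein) - 1:
        raise SimulationError("pyl_codon_fraction places the amber codon outside the gene")
    nt_amber = nt[: pyl_at * 3] + "TAG" + nt[(pyl_at + 1) * 3 :]
    full_nt = nt_amber + "TAA"
    return MutatedGene(
        reference_id=reference.id,
        protein_full=protein,
        protein_called=protein[:pyl_at],
        cds_with_context=full_nt,
        called_cds_length_nt=pyl_at * 3 + 3,
        is_pyl=True,
    )


# ---------------------------------------------------------------------------
# community design


@dataclass
class PlantedGene:
    reference_id: str
    identity: float = 0.8
    syntenic: bool = True
    pyl: bool = False
    pyl_codon_fraction: float = 0.3


@dataclass
class MAGDesign:
    mag_id: str
    order: str
    domain: str = "archaeal"
    #: designed methanogenesis pathway potentials
    pathways: set[str] = field(default_factory=set)
    planted: list[PlantedGene] = field(default_factory=list)
    #: designed relative abundance per replicate group (sums to 1 per group
    #: over the whole community)
    abundance: dict[str, float] = field(default_factory=dict)
    #: designed expression of the planted methyltransferase system(s)
    active: bool = True
    n_decoys_random: int = 2
    n_decoys_corrinoid: int = 1

    @property
    def is_methanogen(self) -> bool:
        return self.domain == "archaeal" and bool(self.pathways)


@dataclass
class CommunityDesign:
    mags: list[MAGDesign]
    groups: list[str] = field(default_factory=lambda: [
        f"{h}_{d}" for h in ("bog", "fen") for d in ("surface", "middle", "deep")
    ])
    replicates: int = 3
    #: negative-binomial size parameter (variance = m + m^2 / dispersion)
    nb_dispersion: float = 2.0
    #: lognormal sigma on per-sample coverage
    depth_jitter: float = 0.1
    #: expected counts for an expressed gene at relative abundance 1
    count_scale: float = 2000.0
    #: trimmed-mean coverage for a MAG at relative abundance 1
    coverage_scale: float = 500.0
    contig_positions: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m.mag_id for m in self.mags]
        if len(ids) != len(set(ids)):
            raise SimulationError("duplicate MAG ids in design")
        for g in self.groups:
            total = sum(m.abundance.get(g, 0.0) for m in self.mags)
            if self.mags and abs(total - 1.0) > 1e-6:
                raise SimulationError(
                    f"designed abundances in group {g!r} sum to {total}, not 1"
                )


def design_from_yaml(path) -> CommunityDesign:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mags = [
        MAGDesign(
            mag_id=m["mag_id"],
            order=m.get("order", "unclassified"),
            domain=m.get("domain", "archaeal"),
            pathways=set(m.get("pathways", [])),
            planted=[PlantedGene(**p) for p in m.get("planted", [])],
            abundance=dict(m.get("abundance", {})),
            active=bool(m.get("active", True)),
            n_decoys_random=int(m.get("n_decoys_random", 2)),
            n_decoys_corrinoid=int(m.get("n_decoys_corrinoid", 1)),
        )
        for m in raw["mags"]
    ]
    kwargs = {k: raw[k] for k in (
        "groups", "replicates", "nb_dispersion", "depth_jitter",
        "count_scale", "coverage_scale", "contig_positions", "seed",
    ) if k in raw}
    return CommunityDesign(mags=mags, **kwargs)


# ---------------------------------------------------------------------------
# community construction


@dataclass
class SyntheticCommunity:
    design: CommunityDesign
    #: mag -> [(gene_id, called protein sequence)]
    proteomes: dict[str, list[tuple[str, str]]]
    #: gene_id -> annotated CDS + downstream context
    cds: dict[str, str]
    gff_text: str
    annotations: pd.DataFrame     # mag_id, gene_id, gene_symbol
    taxonomy: pd.DataFrame        # mag_id, gtdb_taxonomy
    truth: pd.DataFrame
    gene_truth: pd.DataFrame      # per planted gene
    gene_lengths: pd.Series       # called CDS length (bp) per gene
    gene_to_mag: dict[str, str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "proteins.faa", "w") as fh:
            for mag in sorted(self.proteomes):
                for gid, seq in self.proteomes[mag]:
                    fh.write(f">{gid}\n{seq}\n")
        with open(outdir / "cds.fna", "w") as fh:
            for gid in sorted(self.cds):
                fh.write(f">{gid}\n{self.cds[gid]}\n")
        (outdir / "genes.gff").write_text(self.gff_text)
        self.annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        self.taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)
        self.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)


def _truth_substrates(
    mag: MAGDesign, catalog: ReferenceCatalog
) -> set[SubstrateCategory]:
    out = set()
    for p in mag.planted:
        ref = catalog[p.reference_id]
        if ref.role in (SystemRole.MTXB, SystemRole.MTS_FUSED) and (
            ref.substrate_category is not SubstrateCategory.AMBIGUOUS
        ):
            out.add(ref.substrate_category)
    return out


def _truth_lifestyle(mag: MAGDesign) -> str:
    if not mag.is_methanogen:
        return "non_methylotroph"
    if "methylotrophic" not in mag.pathways:
        return "non_methylotroph"
    if mag.pathways == {"methylotrophic"}:
        return "obligate_methylotroph"
    return "facultative_methylotroph"


def build_community(
    design: CommunityDesign, catalog: ReferenceCatalog | None = None
) -> SyntheticCommunity:
    """Materialize a design into the file set the pipeline consumes."""
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(design.seed)
    mtxc_refs = sorted(
        (g for g in catalog if g.role is SystemRole.MTXC), key=lambda g: g.id
    )

    proteomes: dict[str, list[tuple[str, str]]] = {}
    cds: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    ann_rows, tax_rows, truth_rows, gene_truth_rows = [], [], [], []
    gene_lengths: dict[str, int] = {}
    gene_to_mag: dict[str, str] = {}

    for mag in design.mags:
        genes: list[tuple[str, str]] = []  # (gene_id, protein)
        counter = 0

        def next_id() -> str:
            nonlocal counter
            counter += 1
            return f"{mag.mag_id}_gene{counter}"

        def make_decoy(corrinoid: bool) -> tuple[str, str]:
            if corrinoid and mtxc_refs:
                ref = mtxc_refs[rng.integers(len(mtxc_refs))]
                seq = mutate_protein(ref.protein_seq, rng.uniform(0.30, 0.45), rng)
            else:
                seq = "".join(rng.choice(list(_AA), size=250))
            return next_id(), seq

        def register(gid: str, mut: MutatedGene, planted: PlantedGene) -> None:
            cds[gid] = mut.cds_with_context
            gene_lengths[gid] = mut.called_cds_length_nt
            ref = catalog[planted.reference_id]
            gene_truth_rows.append(
                {
                    "mag_id": mag.mag_id,
                    "gene_id": gid,
                    "reference_id": planted.reference_id,
                    "role": ref.role.value,
                    "substrate_category": ref.substrate_category.value,
                    "target_identity": planted.identity,
                    "syntenic": planted.syntenic,
                    "pyl": planted.pyl,
                }
            )

        # contig 1: leading decoy, syntenic planted genes adjacent, decoys after
        contigs: list[list[str]] = []
        contig1: list[str] = []
        gid, seq = make_decoy(corrinoid=False)
        genes.append((gid, seq))
        gene_lengths[gid] = 3 * (len(seq) + 1)
        contig1.append(gid)

        syntenic = [p for p in mag.planted if p.syntenic]
        lone = [p for p in mag.planted if not p.syntenic]
        role_order = {SystemRole.MTXB: 0, SystemRole.MTS_FUSED: 0,
                      SystemRole.MTXC: 1, SystemRole.MTXA: 2, SystemRole.RAMX: 3}
        syntenic.sort(key=lambda p: (role_order[catalog[p.reference_id].role], p.reference_id))
        for planted in syntenic:
            mut = mutate_reference(
                catalog[planted.reference_id],
                planted.identity,
                rng,
                planted.pyl_codon_fraction if planted.pyl else None,
            )
            gid = next_id()
            genes.append((gid, mut.protein_called))
            register(gid, mut, planted)
            contig1.append(gid)
        for k in range(mag.n_decoys_corrinoid):
            gid, seq = make_decoy(corrinoid=True)
            genes.append((gid, seq))
            gene_lengths[gid] = 3 * (len(seq) + 1)
            contig1.append(gid)
        for k in range(mag.n_decoys_random):
            gid, seq = make_decoy(corrinoid=False)
            genes.append((gid, seq))
            gene_lengths[gid] = 3 * (len(seq) + 1)
            contig1.append(gid)
        contigs.append(contig1)

        # non-syntenic planted genes: one per extra contig
        for planted in lone:
            mut = mutate_reference(
                catalog[planted.reference_id],
                planted.identity,
                rng,
                planted.pyl_codon_fraction if planted.pyl else None,
            )
            gid = next_id()
            genes.append((gid, mut.protein_called))
            register(gid, mut, planted)
            contigs.append([gid])

        # GFF coordinates: genes laid end to end with 50 nt spacers
        for c_idx, contig_genes in enumerate(contigs, start=1):
            contig_id = f"{mag.mag_id}_contig{c_idx}"
            pos = 1
            for gid in contig_genes:
                length = gene_lengths[gid]
                gff_lines.append(
                    "\t".join(
                        [
                            contig_id, "methyloscan_sim", "CDS",
                            str(pos), str(pos + length - 1), ".", "+", "0",
                            f"ID={gid}",
                        ]
                    )
                )
                pos += length + 50

        proteomes[mag.mag_id] = genes
        for gid, _ in genes:
            gene_to_mag[gid] = mag.mag_id

        # marker annotations per designed pathway set
        symbols: list[str] = []
        if mag.is_methanogen:
            symbols += MARKER_SYMBOLS["core"]
            if "hydrogenotrophic" in mag.pathways:
                symbols += MARKER_SYMBOLS["hydrogenotrophic"]
            if "acetoclastic" in mag.pathways:
                symbols += MARKER_SYMBOLS["acetoclastic"]
        for i, sym in enumerate(symbols, start=1):
            ann_rows.append(
                {"mag_id": mag.mag_id, "gene_id": f"{mag.mag_id}_marker{i}",
                 "gene_symbol": sym}
            )
        if not symbols:  # keep every MAG present in the annotation table
            ann_rows.append(
                {"mag_id": mag.mag_id, "gene_id": f"{mag.mag_id}_marker0",
                 "gene_symbol": "none"}
            )

        dom = "d__Archaea" if mag.domain == "archaeal" else "d__Bacteria"
        tax_rows.append(
            {"mag_id": mag.mag_id,
             "gtdb_taxonomy": f"{dom};p__;c__;o__{mag.order};f__;g__;s__"}
        )
        truth_rows.append(
            {
                "mag_id": mag.mag_id,
                "domain": mag.domain,
                "order": mag.order,
                "is_methanogen": mag.is_methanogen,
                "pathways": ";".join(sorted(mag.pathways)),
                "is_methylotroph": "methylotrophic" in mag.pathways
                or (mag.domain == "bacterial" and bool(mag.planted)),
                "substrate_profile": ";".join(
                    sorted(s.value for s in _truth_substrates(mag, catalog))
                ),
                "lifestyle": _truth_lifestyle(mag),
                "active_methylotroph": mag.active and bool(mag.planted),
            }
        )

    return SyntheticCommunity(
        design=design,
        proteomes=proteomes,
        cds=cds,
        gff_text="\n".join(gff_lines) + "\n",
        annotations=pd.DataFrame(
            ann_rows, columns=["mag_id", "gene_id", "gene_symbol"]
        ),
        taxonomy=pd.DataFrame(tax_rows, columns=["mag_id", "gtdb_taxonomy"]),
        truth=pd.DataFrame(truth_rows),
        gene_truth=pd.DataFrame(
            gene_truth_rows,
            columns=["mag_id", "gene_id", "reference_id", "role",
                     "substrate_category", "target_identity", "syntenic", "pyl"],
        ),
        gene_lengths=pd.Series(gene_lengths, name="length"),
        gene_to_mag=gene_to_mag,
    )


# ---------------------------------------------------------------------------
# count and depth simulation


@dataclass
class CountSim:
    counts: pd.DataFrame          # gene x sample
    lengths: pd.Series            # bp
    sample_design: pd.DataFrame   # sample, habitat, depth, replicate, group
    coverages: pd.DataFrame       # mag x sample trimmed-mean-style coverage
    depth_vectors: dict[tuple[str, str], np.ndarray]  # (mag, sample) -> depths


def simulate_counts(
    community: SyntheticCommunity,
    seed: int | None = None,
    zero_noise: bool = False,
) -> CountSim:
    """Draw a count matrix and depth tables consistent with the design.

    Expressed genes (all genes of a present MAG except methyltransferase
    genes of designed-inactive MAGs) get negative-binomial counts with
    group mean ``count_scale x designed abundance``; inactive systems get
    mean zero.  Depth vectors are Poisson around ``coverage_scale x
    abundance`` with lognormal per-sample jitter.  ``zero_noise`` replaces
    every draw with its expectation.
    """
    design = community.design
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)

    samples, rows = [], []
    for group in design.groups:
        habitat, _, depth = group.partition("_")
        for rep in range(1, design.replicates + 1):
            name = f"{group}_r{rep}"
            samples.append(name)
            rows.append(
                {"sample": name, "habitat": habitat, "depth": depth,
                 "replicate": rep, "group": group}
            )
    sample_design = pd.DataFrame(rows)

    planted_ids = set(community.gene_truth["gene_id"])
    mag_by_id = {m.mag_id: m for m in design.mags}
    genes = list(community.gene_lengths.index)

    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for gid in genes:
        mag = mag_by_id[community.gene_to_mag[gid]]
        is_system_gene = gid in planted_ids
        for row in rows:
            ab = mag.abundance.get(row["group"], 0.0)
            mean = design.count_scale * ab
            if is_system_gene and not mag.active:
                mean = 0.0
            if mean <= 0:
                continue
            if zero_noise:
                counts.loc[gid, row["sample"]] = int(round(mean))
            else:
                r = design.nb_dispersion
                p = r / (r + mean)
                counts.loc[gid, row["sample"]] = int(rng.negative_binomial(r, p))

    depth_vectors: dict[tuple[str, str], np.ndarray] = {}
    cov_rows = {}
    from .quant import trimmed_mean_coverage

    for mag in design.mags:
        cov_row = {}
        for row in rows:
            ab = mag.abundance.get(row["group"], 0.0)
            cov = design.coverage_scale * ab
            if zero_noise:
                vec = np.full(design.contig_positions, cov)
            else:
                jitter = np.exp(
                    rng.normal(0.0, design.depth_jitter) - design.depth_jitter**2 / 2
                )
                vec = rng.poisson(cov * jitter, size=design.contig_positions).astype(float)
            depth_vectors[(mag.mag_id, row["sample"])] = vec
            cov_row[row["sample"]] = (
                trimmed_mean_coverage(vec) if vec.size else 0.0
            )
        cov_rows[mag.mag_id] = cov_row

    coverages = pd.DataFrame.from_dict(cov_rows, orient="index").reindex(columns=samples)
    coverages.index.name = "mag_id"
    return CountSim(
        counts=counts,
        lengths=community.gene_lengths.copy(),
        sample_design=sample_design,
        coverages=coverages,
        depth_vectors=depth_vectors,
    )


def write_counts(sim: CountSim, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = sim.counts.copy()
    table.insert(0, "length", sim.lengths)
    table.index.name = "gene_id"
    table.to_csv(outdir / "counts.tsv", sep="\t")
    sim.sample_design.to_csv(outdir / "sample_design.tsv", sep="\t", index=False)
    sim.coverages.to_csv(outdir / "coverage.tsv", sep="\t")


# ---------------------------------------------------------------------------
# a ready-made community emulating the study conditions


def default_community_design(seed: int = 0) -> CommunityDesign:
    """A 30-MAG community covering every physiology the classifier knows.

    Composition (mirroring the kinds of genomes the field data contain):
    5 obligate methylotrophs (Methanomassiliicoccales-like, one of them a
    fused-MtsDFH-only genome and one mtsA-only), 8 facultative
    hydrogenotrophic methylotrophs (Methanobacteriales-like), 3 facultative
    acetoclastic+hydrogenotrophic methylotrophs (Methanosarcinales-like),
    5 hydrogenotrophic-only methanogens, 2 acetoclastic-only methanogens,
    4 methylotrophic bacteria (two with Pyl mttB, one non-Pyl mttB, one
    mtaB) and 3 non-methylotrophic bacteria.  A quarter of the
    methylotrophs are designed inactive.  Abundances are a fixed seeded
    Dirichlet draw per habitat x depth group.
    """
    rng = np.random.default_rng(seed)
    mags: list[MAGDesign] = []

    def planted_system(b: str, c: str, a: str, ram: str | None = None,
                       identity: float = 0.8, pyl_b: bool = False) -> list[PlantedGene]:
        out = [
            PlantedGene(b, identity=identity, pyl=pyl_b),
            PlantedGene(c, identity=identity),
            PlantedGene(a, identity=identity),
        ]
        if ram:
            out.append(PlantedGene(ram, identity=identity))
        return out

    # obligate methylotrophs (Methanomassiliicoccales-like)
    mags.append(MAGDesign("MAG001", "Methanomassiliicoccales",
                          pathways={"methylotrophic"},
                          planted=planted_system("mttB_1", "mttC_1", "mtbA_1", "ramA_1",
                                                 pyl_b=True)))
    mags.append(MAGDesign("MAG002", "Methanomassiliicoccales",
                          pathways={"methylotrophic"},
                          planted=planted_system("mtaB_1", "mtaC_1", "mtaA_1", "ramM_1")))
    mags.append(MAGDesign("MAG003", "Methanomassiliicoccales",
                          pathways={"methylotrophic"},
                          planted=[PlantedGene("mtsD_1")]))  # fused methyl-S route
    mags.append(MAGDesign("MAG004", "Methanomassiliicoccales",
                          pathways={"methylotrophic"},
                          planted=[PlantedGene("mtsA_1"), PlantedGene("ramA_2")]))
    mags.append(MAGDesign("MAG005", "Methanomassiliicoccales",
                          pathways={"methylotrophic"},
                          planted=planted_system("mtbB_1", "mtbC_1", "mtbA_2"),
                          active=False))

    # facultative hydrogenotrophic methylotrophs (Methanobacteriales-like)
    for i in range(6, 14):
        planted = planted_system(
            "mtaB_2" if i % 2 == 0 else "mtoB_1",
            "mtaC_2" if i % 2 == 0 else "mtoC_1",
            "mtaA_2" if i % 2 == 0 else "mtoA_1",
            "ramM_2" if i % 3 == 0 else None,
        )
        if i == 13:
            for p in planted:
                p.syntenic = False
        mags.append(MAGDesign(f"MAG{i:03d}", "Methanobacteriales",
                              pathways={"methylotrophic", "hydrogenotrophic"},
                              planted=planted, active=(i % 4 != 0)))

    # facultative Methanosarcinales-like (all three modes)
    for i in range(14, 17):
        mags.append(MAGDesign(f"MAG{i:03d}", "Methanosarcinales",
                              pathways={"methylotrophic", "hydrogenotrophic",
                                        "acetoclastic"},
                              planted=planted_system("mtaB_3", "mtaC_3", "mtaA_3")))

    # hydrogenotrophic-only (Methanoflorens/Methanomicrobiales-like)
    for i in range(17, 22):
        mags.append(MAGDesign(f"MAG{i:03d}",
                              "Methanomicrobiales" if i % 2 else "Methanocellales",
                              pathways={"hydrogenotrophic"}))

    # acetoclastic-only (Methanotrichales-like)
    for i in range(22, 24):
        mags.append(MAGDesign(f"MAG{i:03d}", "Methanotrichales",
                              pathways={"acetoclastic"}))

    # methylotrophic bacteria
    mags.append(MAGDesign("MAG024", "Acetobacterales", domain="bacterial",
                          planted=[PlantedGene("mttB_2", pyl=True)]))
    mags.append(MAGDesign("MAG025", "Clostridiales", domain="bacterial",
                          planted=[PlantedGene("mttB_3", pyl=True)], active=False))
    mags.append(MAGDesign("MAG026", "Rhizobiales", domain="bacterial",
                          planted=[PlantedGene("mttB-nonPyl_1")]))
    mags.append(MAGDesign("MAG027", "Acidobacteriales", domain="bacterial",
                          planted=[PlantedGene("mtaB_1", identity=0.75)]))

    # non-methylotrophic bacteria
    for i in range(28, 31):
        mags.append(MAGDesign(f"MAG{i:03d}", "Burkholderiales", domain="bacterial",
                              n_decoys_corrinoid=0))

    groups = [f"{h}_{d}" for h in ("bog", "fen") for d in ("surface", "middle", "deep")]
    for group in groups:
        weights = rng.dirichlet(np.full(len(mags), 2.0))
        for mag, w in zip(mags, weights):
            mag.abundance[group] = float(w)
    return CommunityDesign(mags=mags, groups=groups, seed=seed)
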