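# Methods

`methyloscan` profiles anaerobic, corrinoid-dependent methylotrophy in
metagenome-assembled genomes (MAGs): which genomes encode substrate-specific
three-component methyltransferase systems, which substrates those systems
demethylate, whether the host is an obligate or facultative methylotrophic
methanogen (or a methylotrophic bacterium), and whether the systems are
expressed in paired metatranscriptomes. This note documents the models and
rules each stage implements, the tunable parameters and their defaults, what
the synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## The biological model

Methanogens using methylated substrates (and anaerobic bacteria feeding
methyl groups into the Wood–Ljungdahl pathway) rely on three-component
methyltransferase systems: a substrate:corrinoid methyltransferase (MtxB)
that demethylates the substrate, a corrinoid-binding protein (MtxC) that
carries the methyl group, and a methylcorrinoid:carbon-carrier
methyltransferase (MtxA) that passes it into central metabolism; a reductive
activase (RamX) rescues adventitiously oxidised corrinoid. The "x" encodes
substrate specificity (mtaB = methanol, mttB = trimethylamine, mtbB =
dimethylamine, mtmB = monomethylamine, methoxy-type homologs for
methoxylated aromatics). Methyl-sulfide metabolism occurs both as a
two-part system (mtsA/mtsB) and as tri-functional fused proteins
(MtsD/MtsF/MtsH) that combine the three activities in one polypeptide.
Substrates group into three categories — methylated amines (methyl-N),
methylated oxygen compounds (methyl-O: methanol plus methoxylated
compounds), and methylated sulfides (methyl-S) — plus a "substrate
ambiguous" bin for genes whose homology evidence cannot separate
categories.

Trimethylamine-type mttB genes encode pyrrolysine (Pyl) through an in-frame
amber (TAG) codon; naive gene callers truncate them at that codon. MttB
homologs *lacking* Pyl are a distinct functional class specific for
quaternary amines (glycine betaine, choline). The truncation signature is
therefore informative, and the package detects it directly from the
nucleotide CDS.

## Reference catalog

The screen runs against a curated catalog of 53 methylotrophy gene types:
20 mtxB-family genes (including mtsA/mtsB and the three fused MtsDFH
types), 16 mtxC, 10 mtxA and 7 ramX. The original curated protein
sequences live in a journal supplement and are not redistributable here, so
the packaged catalog (`data/reference_catalog_synthetic.*`) is a clearly
labelled **synthetic stand-in** with the same family composition, substrate
annotations and realistic lengths: each family descends from a random
ancestor, members sit at 75–90% identity to it, and cross-family identity
is at random background. Screening against it behaves qualitatively like
screening against the real catalog (strong within-family hits, negligible
cross-family hits), which is what the round-trip tests need. Users with
the real catalog load it with `load_catalog(fasta, metadata)`; every
downstream stage is agnostic to which catalog is in use. Composition
bookkeeping (`family_counts`) counts the fused MtsDFH entries with the
mtxB family, since they carry the substrate-demethylating B activity — this
reproduces the 20/16/10/7 description of the curated catalog.

Substrate chemistry is table-driven (`data/substrate_chemistry.tsv`): each
compound carries an integer count of microbially available methyl groups
(methanol 1, dimethyl sulfide 2, trimethylamine / glycine betaine /
choline 3, a tri-methoxylated aromatic 3, ...). `ch4_yield_ratio(a, b)` is
the ratio of those counts — the stoichiometric ceiling on CH₄ per mole of
substrate — returned as an exact rational. No structure parsing is
attempted; methyl groups are counted by inspection when the table is
curated.

## Homology screen

Every MAG protein is aligned to every catalog reference with local
Smith–Waterman alignment (affine gaps) using BLOSUM62, gap open 11, gap
extend 1 in the BLAST convention (a gap of length k costs 11 + k). The
aligner is Biopython's `PairwiseAligner` (`open_gap_score = −12`,
`extend_gap_score = −1` reproduces that convention); `X` scores 0 against
everything. Raw scores S become bitscores through the Karlin–Altschul
transform, bits = (λ·S − ln K)/ln 2 with the gapped-BLOSUM62(11,1)
constants λ = 0.267, K = 0.041. Exact parity with any particular external
search tool is not claimed — what downstream stages consume is the
threshold semantics:

* **archaeal screen** — keep hits with bitscore strictly > 60; then drop
  *all* hits of any MAG that has no hit to an mtxB-family (MtxB or fused
  MtsDFH) reference;
* **bacterial screen** — mtxB-family references only, bitscore strictly
  > 200. mtxB is the single best marker gene for the metabolism, and
  restricting the bacterial screen to it avoids nonspecific hits to other
  cobalamin-binding proteins.

All passing references per gene are retained (not just the best); identity
resolution happens downstream. Score-only alignment runs first and the
traceback (for identity and coverage) only for passing pairs, which keeps
the screen O(passing hits) in the expensive step. Precomputed 12-column
tabular search output (BLAST outfmt-6 dialect) can be ingested in place of
the internal aligner.

## Gene identity assignment

The study this pipeline systematises confirmed gene identities by building
phylogenies and inspecting them manually. That step is replaced by an
automated, reproducible surrogate: the gene takes the role and substrate
category of its best-bitscore reference **unless** a reference from a
*different* substrate category scores within `margin_threshold` bits
(default 10) of the best, in which case the gene is called substrate
ambiguous — the same fate an equivocal tree placement had. Ties break
lexicographically by reference id, so assignment is deterministic and
invariant to hit order. RamX hits never resolve a substrate: activases are
promiscuous across corrinoid proteins, so they count as evidence of
methylotrophy but not of a substrate.

Synteny: assigned genes on one contig separated by at most
`max_intergenic` (default 2) unassigned genes are clustered; clusters with
at least two distinct roles are recorded as operon evidence and their
members flagged syntenic. The count of intervening genes is strand-agnostic
(operons in draft bins are not reliably single-strand) and invariant to
reversing contig coordinates. Synteny is confidence metadata only — the
methylotrophy call is gated on component completeness, not on synteny.

Pyl detection (`detect_pyl`) is a pure function of the nucleotide CDS (with
downstream context) and three parameters: a gene is Pyl-type iff the called
protein is truncated below `min_truncation` (default 0.7) of the reference
length **and** the terminating codon is TAG **and** in-frame translation
past the TAG runs at least `min_readthrough_aa` (default 30) codons before
the next stop. Full-length-like genes, or genes terminated by TAA/TGA, are
non-Pyl (quaternary-amine class). Insufficient downstream context or
ambiguous nucleotides in frame degrade the call to low-confidence rather
than erroring. The 0.7/30 defaults are this package's choices — the
original analysis used visual inspection in a sequence editor — and both
are exposed.

## Physiology classification

A MAG is a **methanogen** when the Mcr and Hdr complex marker sets both
meet their presence thresholds in its (DRAM-style) annotations. Marker sets
are configuration, not code, because indicator sets vary between studies;
the defaults are: Mcr {mcrA, mcrB, mcrG} at 2/3, Hdr {hdrA, hdrB, hdrC} at
2/3; hydrogenotrophic indicator {fwdA, fmdA, ftr, mch, mtd, mer, frhA,
echA} at 1/2; acetoclastic via either route {ackA, pta} complete or the CO
dehydrogenase/acetyl-CoA decarbonylase complex {cdhA–E} at 3/5. Any set
can be swapped through a YAML file.

A MAG is a **methylotroph** when:

* (archaea) it encodes at least two of the three core system members
  (MtxB, MtxC, MtxA) *including* the substrate-demethylating MtxB; or a
  single tri-functional fused MtsDFH gene; or at least one of mtsA/mtsB
  (the methyl-sulfide exceptions — "at least one of mtsAB" is read
  literally as mtsA *or* mtsB);
* (bacteria) it encodes any mtxB-family homolog at the bacterial screen's
  higher bar.

The **substrate profile** is the union of categories of non-ambiguous
MtxB/MtsFused/mtsAB assignments; RamX and ambiguous MtxC/MtxA contribute
nothing. **Lifestyle** is genotype-only: obligate methylotroph when
methylotrophy is the only encoded methanogenesis pathway, facultative when
hydrogenotrophic and/or acetoclastic potential is co-encoded. Every call
carries an ordered rule trace naming the rules that fired, so verdicts are
replayable.

## Quantification

**Counts.** Metatranscriptome counts are floor-filtered per cell (counts
< 5 set to zero; strict inequality, applied per gene×sample cell — a
row-wise variant is available) and converted to geTMM: reads per kilobase
(RPK = count/(length/1000)), TMM factors computed *on the RPK matrix*, and

    geTMM[g, s] = RPK[g, s] / (Σ_g RPK[g, s] · f_s) × 10⁶

so column s sums to 10⁶/f_s. The TMM factors follow the canonical recipe:
reference sample = the one whose 75th-percentile count fraction is closest
to the mean of those; M (log-ratio) and A (mean log-intensity) over genes
positive in both sample and reference; rank-trim the top and bottom 30% of
M and 5% of A (keep ranks in [⌊n·trim⌋+1, n+1−(⌊n·trim⌋+1)]); factor =
2^(precision-weighted mean M) with delta-method weights; rescale factors to
geometric mean 1. The implementation agrees with edgeR's
`calcNormFactors`/`cpm` to better than 1e-8 on the frozen fixtures in the
test suite. Precision weighting (the canonical default) makes factors
depend weakly on absolute counts, so a pure depth change is absorbed
exactly only in the unweighted mode (`tmm_weighted=False`); weighted
factors move by well under a percent. Normalization is run jointly across
all samples by default; per-group runs are a caller choice. geTMM > 0
after the count floor defines "expressed" — no further threshold.

**Activity.** A MAG is an *active methylotroph* in a replicate group when,
for at least one identified system — an operon cluster containing a
B-family member, or, failing operon evidence, the MAG's full assigned gene
set — more than half the member genes have group-mean geTMM > 0 *and* the
mtxB member is among them. Group means are means over replicates (field
design n = 3); missing replicates fall back to the mean of available ones
with a logged warning.

**Abundance.** MAG abundance is trimmed-mean per-base coverage: sort the
depth vector and average the values with sorted index in
[⌊0.1·n⌋, ⌈0.9·n⌉) — an inclusive-exclusive convention that degenerates to
the plain value for n = 1. Relative abundance divides by the summed
coverage of a configurable denominator set (all MAGs, all archaea, all
methanogens), reporting a sample as missing (with a warning) when the
denominator is zero — the "below detection" case. Read mapping and BAM
processing are upstream of this package; depth tables are inputs.

**Rollups.** Order-level activity fractions divide each order's summed
group-mean geTMM by the summed group-mean geTMM of all methanogen genes
(columns sum to 1 where defined). Abundance-normalized expression divides
group-mean geTMM by the gene's MAG relative abundance in the matched
metagenome group (habitat×depth group means, since matched-core pairing is
not always available), reporting zero-abundance/nonzero-expression cells
as missing rather than infinite. `pearson_r2` is the squared Pearson
correlation (n ≥ 3, nonzero variance required).

## Porewater CH₄

Dissolved CH₄ is recovered from headspace equilibration by mass balance:
µmol in the measured headspace divided by (water volume × extraction
efficiency), default efficiency 0.95. Henry's-law partitioning is not
modelled separately — the residual dissolved fraction is folded into the
single efficiency constant, which is how the field protocol reports it.
Headspace concentration can be given in µM of headspace or as a mol
fraction (ideal gas, 1 atm, 298.15 K). The result is linear in the
measured concentration and inversely proportional to efficiency.

## Synthetic communities

The generator (`simulate`) fabricates every input the pipeline consumes,
with known labels:

* planted genes are catalog references mutated to a target amino-acid
  identity (substitutions sampled proportional to BLOSUM62
  exchangeability; realized identity within ±2% of target, which bounds
  usable sequences to ≥ 25 aa), back-translated with uniform synonymous
  codon choice under the seed (codon bias is irrelevant to every
  downstream operation);
* Pyl genes get an in-frame TAG at a configurable codon fraction
  (default 0.3); the "annotated" protein is the truncated prefix, exactly
  what a naive gene caller would emit;
* decoys are both random proteins and 30–45%-identity mutants of
  corrinoid-binding (mtxC) references, stressing the screen the way
  environmental cobalamin-binding proteins do;
* syntenic systems are laid out adjacently on one contig (role order
  B–C–A–Ram) flanked by decoys; non-syntenic planted genes go on their own
  contigs; marker annotations are emitted to match each MAG's designed
  pathway set;
* counts are negative binomial (default dispersion 2, i.e. variance
  m + m²/2) with group mean = `count_scale` (default 2000) × designed
  relative abundance for expressed genes; methyltransferase genes of
  designed-inactive MAGs get mean zero; depth vectors (default 200
  positions) are Poisson around `coverage_scale` (default 500) × abundance
  with lognormal per-sample jitter (σ = 0.1). A zero-noise mode replaces
  every draw with its expectation for exact round trips.

The default community (`default_community_design`) has 30 MAGs covering
every physiology the classifier distinguishes — obligate methylotrophs
(including fused-MtsDFH-only and mtsA-only genomes), facultative
methylotrophs of both kinds, hydrogenotrophic-only and acetoclastic-only
methanogens, Pyl and non-Pyl methylotrophic bacteria, and
non-methylotrophic bacteria — under a 2-habitat × 3-depth × 3-replicate
sample design with seeded Dirichlet abundances. Planted identities default
to 80%.

**What the generator does not emulate** — and hence what passing round
trips do and do not show: there are no assembly artifacts, chimeras,
frameshifts or partial genes (beyond Pyl truncation); no real phylogenetic
structure within gene families (the catalog stand-in is star-shaped around
family ancestors, so the margin rule faces easier cross-family
discrimination than a real tree would); no compositional codon or GC
structure; no read-level simulation. Exact recovery on these communities
demonstrates that the rule engine, thresholds, normalization and plumbing
are correct, not that the screen's sensitivity/specificity on real
environmental diversity matches the study's.

## Problem sizes and numerical choices

The shipped validation runs at desk scale: a 30-MAG community (~200
proteins vs 53 references ≈ 10⁴ alignments, ~10 s), 20 count-noise
replicates for activity-label accuracy, 100 random matrices for the
normalization invariants, and an alignment-vs-enumeration check that is
exhaustive over all peptide pairs up to length 3 on a 4-letter alphabet
plus a seeded sample of longer pairs (the enumeration oracle is
exponential; full exhaustion at length 8 is combinatorially out of reach).
Floating-point contracts: TMM fixtures to 1e-6 relative (they agree to
~1e-9), geometric-mean-1 to 1e-12, exact integer raw scores for
alignments, exact rational stoichiometry ratios. Degenerate inputs are
defined, not undefined: empty proteome → empty hit list with a warning;
single-sample geTMM → factor 1; length-1 depth vector → the value itself;
zero-denominator abundance → missing with a warning.

## Known limitations

* The packaged catalog is synthetic; real-catalog behaviour (hit rates,
  margins) will differ quantitatively. All thresholds are exposed.
* The bitscore constants (λ, K) approximate the external tool's gapped
  BLOSUM62 statistics; scores near the 60/200 thresholds could flip
  relative to a BLAST run. Threshold semantics, not score parity, are the
  contract.
* The margin surrogate is not the study's manual tree inspection; it is a
  documented, reproducible stand-in, and the optional distance report it
  can emit is for audit, not calls.
* Lifestyle calls are genotype-only; expression evidence feeds the
  separate activity call.
* Full-scale reproduction of the study's headline counts requires the
  deposited ~13k-MAG database and 27 metatranscriptomes; the package's
  interfaces accept those inputs but the repository ships only desk-scale
  validation.
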