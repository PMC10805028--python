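"""Homology screening of MAG proteomes against the reference catalog.

Scores every MAG protein against every catalog reference with local
Smith-Waterman alignment (affine gaps, BLOSUM62 by default) and applies the
bitscore filters used for methylotrophy profiling: archaeal MAG screening
retains hits with bitscore > 60 and keeps a MAG's hits only when the MAG
encodes an mtxB-family homolog; bacterial screening uses mtxB alone as the
marker gene at bitscore > 200 (handled by the caller via ``min_bitscore``).

Raw alignment scores are converted to bitscores with the Karlin-Altschul
transform, bits = (lambda * S - ln K) / ln 2, using the gapped BLOSUM62
(open 11, extend 1) parameters lambda = 0.267, K = 0.041.  Exact parity
with any particular external search tool is not claimed; the threshold
semantics (strict ">") are what matters downstream.

Precomputed 12-column tabular search output (BLAST outfmt-6 dialect) can be
ingested in place of the internal aligner.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

log = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(_AA + "X")

#: default MAG-id pattern: ids shaped like "MAGID_geneN"
DEFAULT_ID_PATTERN = r"^(?P<mag>.+)_(?P<gene>[^_]+)$"

TABULAR_COLUMNS = [
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _blosum62_x_neutral() -> substitution_matrices.Array:
    """BLOSUM62 restricted to the 20 AA + X, with X scoring 0 against all."""
    b62 = substitution_matrices.load("BLOSUM62")
    alphabet = _AA + "X"
    out = substitution_matrices.Array(alphabet, dims=2)
    for a in _AA:
        for b in _AA:
            out[a, b] = b62[a, b]
    # X rows/cols stay 0
    return out


@dataclass
class ScoringScheme:
    """Alignment scoring and bitscore parameters.

    ``gap_open`` / ``gap_extend`` follow the BLAST convention: a gap of
    length k costs ``gap_open + k * gap_extend``.
    """

    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041
    matrix: substitution_matrices.Array = field(default_factory=_blosum62_x_neutral)

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        arr = np.asarray(self.matrix)
        if not np.array_equal(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = self.matrix
        # PairwiseAligner charges open_gap_score for the first gap position,
        # extend for each further one; BLAST charges open + k*extend.
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2)


@dataclass
class Hit:
    """One protein-vs-reference local alignment passing a bitscore filter."""

    query_gene_id: str
    mag_id: str
    reference_id: str
    bitscore: float
    raw_score: int | None = None
    percent_identity: float = float("nan")
    aln_length: int = 0
    query_coverage: float = float("nan")


class AlignmentError(ValueError):
    pass


def _check_protein(seq: str, label: str) -> str:
    if not seq:
        raise AlignmentError(f"{label} sequence is empty")
    seq = seq.upper().rstrip("*")
    bad = set(seq) - _VALID
    if bad:
        raise AlignmentError(f"{label} sequence has non-amino-acid characters: {sorted(bad)}")
    return seq


def align_local(query: str, subject: str, scheme: ScoringScheme | None = None) -> Hit | None:
    """Best local alignment of two proteins; ``None`` if no positive score.

    Returns a :class:`Hit` with raw score, bitscore, percent identity over
    the alignment (gaps count toward its length) and query coverage.
    """
    scheme = scheme or ScoringScheme()
    query = _check_protein(query, "query")
    subject = _check_protein(subject, "subject")
    aligner = scheme.aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(query, subject)))
    q_aln, s_aln = str(aln[0]), str(aln[1])
    matches = sum(a == b and a != "-" for a, b in zip(q_aln, s_aln))
    q_span = aln.aligned[0]
    covered = int(sum(end - start for start, end in q_span))
    return Hit(
        query_gene_id="",
        mag_id="",
        reference_id="",
        raw_score=int(round(score)),
        bitscore=scheme.bitscore(score),
        percent_identity=100.0 * matches / len(q_aln),
        aln_length=len(q_aln),
        query_coverage=covered / len(query),
    )


def _parse_mag_id(gene_id: str, pattern: str) -> str:
    m = re.match(pattern, gene_id)
    if not m:
        raise AlignmentError(
            f"gene id {gene_id!r} does not match the MAG-id pattern {pattern!r}"
        )
    return m.group("mag")


def screen_proteome(
    proteome,
    catalog,
    scheme: ScoringScheme | None = None,
    min_bitscore: float = 60.0,
    mag_id_pattern: str = DEFAULT_ID_PATTERN,
    mag_id: str | None = None,
) -> list[Hit]:
    """Screen a MAG proteome against the reference catalog.

    ``proteome`` is a FASTA path or an iterable of ``(gene_id, sequence)``
    pairs.  Every (gene, reference) pair with bitscore strictly above
    ``min_bitscore`` is returned — all passing references per gene, not just
    the best, since identity refinement happens downstream.  ``mag_id``
    overrides per-gene MAG-id parsing for single-MAG files.

    Scoring is done score-only first; the (expensive) traceback for
    identity and coverage runs only for passing pairs.
    """
    if min_bitscore < 0:
        raise ValueError("min_bitscore must be non-negative")
    scheme = scheme or ScoringScheme()
    if isinstance(proteome, (str, bytes)) or hasattr(proteome, "__fspath__"):
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(proteome), "fasta")]
    else:
        records = list(proteome)
    if not records:
        log.warning("empty proteome: no sequences to screen")
        return []

    aligner = scheme.aligner()
    hits: list[Hit] = []
    for gene_id, seq in records:
        seq = _check_protein(seq, gene_id)
        mag = mag_id if mag_id is not None else _parse_mag_id(gene_id, mag_id_pattern)
        for ref in catalog:
            score = aligner.score(seq, ref.protein_seq)
            if scheme.bitscore(score) > min_bitscore:
                hit = align_local(seq, ref.protein_seq, scheme)
                assert hit is not None
                hit.query_gene_id = gene_id
                hit.mag_id = mag
                hit.reference_id = ref.id
                hits.append(hit)
    hits.sort(key=lambda h: (h.mag_id, h.query_gene_id, h.reference_id))
    return hits


def filter_archaeal_hits(hits: Sequence[Hit], catalog) -> list[Hit]:
    """Keep hits only for MAGs that encode an mtxB-family homolog.

    A MAG qualifies when at least one of its (already bitscore-filtered)
    hits is to a reference with role MtxB or MtsFused; all hits from other
    MAGs are dropped entirely.
    """
    from .catalog import SystemRole

    b_roles = {SystemRole.MTXB, SystemRole.MTS_FUSED}
    qualified = {
        h.mag_id for h in hits if catalog[h.reference_id].role in b_roles
    }
    return [h for h in hits if h.mag_id in qualified]


# ---------------------------------------------------------------------------
# tabular search interchange (BLAST outfmt-6 dialect)


def ingest_tabular(search_file, mag_id_pattern: str = DEFAULT_ID_PATTERN) -> list[Hit]:
    """Read 12-column tabular protein-search output into hits.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  Raw scores are unavailable in
    this format and are left unset.
    """
    hits: list[Hit] = []
    with open(search_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AlignmentError(
                    f"{search_file}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise AlignmentError(
                    f"{search_file}: line {lineno}: malformed numeric field ({exc})"
                ) from None
            hits.append(
                Hit(
                    query_gene_id=fields[0],
                    mag_id=_parse_mag_id(fields[0], mag_id_pattern),
                    reference_id=fields[1],
                    bitscore=bitscore,
                    raw_score=None,
                    percent_identity=pident,
                    aln_length=length,
                    query_coverage=float("nan"),
                )
            )
    return hits


def write_tabular(hits: Iterable[Hit], path) -> None:
    """Write hits back in the 12-column tabular dialect (no header).

    Inverse of :func:`ingest_tabular` for files it produced: fields the
    Hit model does not carry (mismatch, gapopen, coordinates, evalue) are
    written as zero/placeholder values, so ingest -> write round-trips the
    fields the pipeline consumes, not arbitrary third-party files.
    """
    with open(path, "w") as fh:
        for h in hits:
            qend = h.aln_length if h.aln_length else 0
            fh.write(
                "\t".join(
                    [
                        h.query_gene_id, h.reference_id,
                        f"{h.percent_identity:g}", str(h.aln_length),
                        "0", "0", "1", str(qend), "1", str(qend),
                        "0", f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def write_hits(hits: Iterable[Hit], path) -> None:
    """Write hits to a header-ed TSV."""
    rows = [
        {
            "query_gene_id": h.query_gene_id,
            "mag_id": h.mag_id,
            "reference_id": h.reference_id,
            "raw_score": h.raw_score,
            "bitscore": h.bitscore,
            "percent_identity": h.percent_identity,
            "aln_length": h.aln_length,
            "query_coverage": h.query_coverage,
        }
        for h in hits
    ]
    pd.DataFrame(
        rows,
        columns=[
            "query_gene_id", "mag_id", "reference_id", "raw_score", "bitscore",
            "percent_identity", "aln_length", "query_coverage",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_hits(path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    return [
        Hit(
            query_gene_id=r.query_gene_id,
            mag_id=r.mag_id,
            reference_id=r.reference_id,
            bitscore=float(r.bitscore),
            raw_score=None if pd.isna(r.raw_score) else int(r.raw_score),
            percent_identity=float(r.percent_identity),
            aln_length=int(r.aln_length),
            query_coverage=float(r.query_coverage),
        )
        for r in df.itertuples(index=False)
    ]
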