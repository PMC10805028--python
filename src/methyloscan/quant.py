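"""Expression normalization, abundance rollups and activity calls.

Metatranscriptome counts are floor-filtered (cells < 5 set to zero) and
converted to geTMM: counts per kilobase (RPK) scaled by trimmed-mean-of-
M-values (TMM) normalization factors and expressed per million,

    geTMM[g, s] = RPK[g, s] / (sum_g RPK[g, s] * f_s) * 1e6,

so each sample column sums to 1e6 / f_s.  The TMM factors follow the
canonical recipe: the reference sample is the one whose 75th-percentile
count fraction is closest to the mean of those; per sample, log-ratios (M)
and average log-intensities (A) are computed over genes positive in both
sample and reference; the top and bottom 30% of M and 5% of A are trimmed;
the factor is 2 to the precision-weighted mean M, and the factors are
rescaled to geometric mean 1.

MAG abundance comes from trimmed-mean per-base coverage (default: mean of
the depths between the 10th and 90th coverage percentiles), normalized to
relative abundance against a configurable denominator set (all MAGs, all
archaea, or all methanogens).

Activity calls mirror the genotype rules: a MAG is an active methylotroph
only when, for at least one identified methyltransferase system, the
majority of member genes are expressed (group-mean geTMM > 0) including
the mtxB member.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assign import GeneAssignment, OperonEvidence
from .catalog import SystemRole

log = logging.getLogger(__name__)


@dataclass
class NormalizationParams:
    trim_M: float = 0.30
    trim_A: float = 0.05
    count_floor: int = 5
    coverage_trim_min: float = 0.1
    coverage_trim_max: float = 0.9
    #: precision-weight the trimmed mean of M-values (the canonical
    #: default).  Unweighted factors are exactly invariant to scaling a
    #: sample's counts; weighted ones only approximately, because the
    #: delta-method weights depend on absolute counts.
    tmm_weighted: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.trim_M < 0.5 and 0 <= self.trim_A < 0.5):
            raise ValueError("trim fractions must be in [0, 0.5)")
        if not self.coverage_trim_min < self.coverage_trim_max:
            raise ValueError("coverage_trim_min must be below coverage_trim_max")


class QuantError(ValueError):
    pass


# ---------------------------------------------------------------------------
# count filtering and geTMM


def filter_counts(matrix: pd.DataFrame, count_floor: int = 5) -> pd.DataFrame:
    """Zero out cells with count < ``count_floor`` (strict); shape unchanged."""
    if (matrix.to_numpy() < 0).any():
        raise QuantError("count matrix contains negative values")
    return matrix.where(matrix >= count_floor, 0)


def _quantile_factor(x: np.ndarray, lib: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.array([np.quantile(x[:, j], p) for j in range(x.shape[1])]) / lib


def tmm_factors(
    matrix: pd.DataFrame,
    params: NormalizationParams | None = None,
    ref_column: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    Factors are rescaled so that their geometric mean is 1.  Raises when a
    sample has a zero library sum (naming it).
    """
    params = params or NormalizationParams()
    x = matrix.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise QuantError("TMM needs at least two samples")
    lib = x.sum(axis=0)
    for name, total in zip(matrix.columns, lib):
        if total <= 0:
            raise QuantError(f"sample {name!r} has a zero library sum")

    f75 = _quantile_factor(x, lib)
    if ref_column is None:
        ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_j = list(matrix.columns).index(ref_column)
    ref, ref_lib = x[:, ref_j], lib[ref_j]

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref_j:
            continue
        obs, obs_lib = x[:, j], lib[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            continue
        o, r = obs[keep], ref[keep]
        M = np.log2((o / obs_lib) / (r / ref_lib))
        A = 0.5 * np.log2((o / obs_lib) * (r / ref_lib))
        # asymptotic (delta-method) variance of M; precision weights
        w = 1.0 / ((obs_lib - o) / (obs_lib * o) + (ref_lib - r) / (ref_lib * r))

        n = len(M)
        lo_M = np.floor(n * params.trim_M) + 1
        hi_M = n + 1 - lo_M
        lo_A = np.floor(n * params.trim_A) + 1
        hi_A = n + 1 - lo_A
        rank_M = stats.rankdata(M)
        rank_A = stats.rankdata(A)
        sel = (rank_M >= lo_M) & (rank_M <= hi_M) & (rank_A >= lo_A) & (rank_A <= hi_A)
        if sel.any() and np.isfinite(w[sel]).all():
            if params.tmm_weighted:
                factors[j] = 2 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
            else:
                factors[j] = 2 ** np.mean(M[sel])

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.columns, name="tmm_factor")


def getmm(
    matrix: pd.DataFrame,
    lengths: pd.Series,
    params: NormalizationParams | None = None,
    apply_count_floor: bool = True,
) -> pd.DataFrame:
    """Gene-length-corrected TMM normalization (geTMM).

    ``lengths`` are gene lengths in bp, indexed like the matrix rows.
    Contract: geTMM[g, s] = RPK[g, s] / (colsum_RPK[s] * factor_s) * 1e6,
    i.e. column s sums to 1e6 / factor_s.
    """
    params = params or NormalizationParams()
    lengths = lengths.reindex(matrix.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise QuantError(f"genes without lengths: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])[:5]
        raise QuantError(f"non-positive gene lengths: {bad}")
    counts = filter_counts(matrix, params.count_floor) if apply_count_floor else matrix
    rpk = counts.div(lengths / 1000.0, axis=0)
    if rpk.shape[1] == 1:  # nothing to normalize against
        factors = pd.Series(1.0, index=rpk.columns)
    else:
        factors = tmm_factors(rpk, params)
    eff_lib = rpk.sum(axis=0) * factors
    return rpk.div(eff_lib, axis=1) * 1e6


# ---------------------------------------------------------------------------
# replicate groups and expression rollups


def group_means(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates per habitat x depth group.

    ``design`` columns: sample, group (or habitat + depth, concatenated).
    Missing replicates are mean-of-available with a logged warning.
    """
    d = design.copy()
    if "group" not in d.columns:
        d["group"] = d["habitat"].astype(str) + "_" + d["depth"].astype(str)
    absent = set(d["sample"]) - set(matrix.columns)
    if absent:
        log.warning("samples in design but not in matrix: %s", sorted(absent))
        d = d[~d["sample"].isin(absent)]
    sizes = d.groupby("group")["sample"].count()
    if sizes.nunique() > 1:
        log.warning("unbalanced replicate groups; using mean of available replicates")
    out = {}
    for group, sub in d.groupby("group"):
        out[group] = matrix[list(sub["sample"])].mean(axis=1)
    return pd.DataFrame(out)


def classify_active_methylotroph(
    getmm_matrix: pd.DataFrame,
    assignments: Sequence[GeneAssignment],
    design: pd.DataFrame,
    operons: Sequence[OperonEvidence] = (),
) -> pd.DataFrame:
    """Active-methylotroph call per MAG and replicate group.

    A MAG is active in a group when, for at least one identified system —
    an operon cluster containing an mtxB-family member, or failing any
    operon evidence the MAG's full set of assigned methylotrophy genes —
    more than half of the member genes have group-mean geTMM > 0 and the
    mtxB (or fused MtsDFH) member is among the expressed genes.

    Returns a boolean DataFrame (MAG x group) plus an ``active_any``
    column.
    """
    means = group_means(getmm_matrix, design)
    by_mag: dict[str, list[GeneAssignment]] = {}
    for a in assignments:
        by_mag.setdefault(a.mag_id, []).append(a)

    b_roles = (SystemRole.MTXB, SystemRole.MTS_FUSED)
    systems: dict[str, list[list[GeneAssignment]]] = {}
    covered: dict[str, set[str]] = {}
    for op in operons:
        mag_members = [a for a in by_mag.get(op.mag_id, []) if a.gene_id in op.member_gene_ids]
        if any(a.role in b_roles for a in mag_members):
            systems.setdefault(op.mag_id, []).append(mag_members)
            covered.setdefault(op.mag_id, set()).update(a.gene_id for a in mag_members)
    for mag_id, genes in by_mag.items():
        if mag_id not in systems:
            systems[mag_id] = [genes]

    rows = {}
    for mag_id, mag_systems in sorted(systems.items()):
        row = {}
        for group in means.columns:
            active = False
            for system in mag_systems:
                ids = [a.gene_id for a in system]
                expressed = {
                    g for g in ids if g in means.index and means.loc[g, group] > 0
                }
                majority = len(expressed) > 0.5 * len(ids)
                b_expressed = any(
                    a.gene_id in expressed for a in system if a.role in b_roles
                )
                if majority and b_expressed:
                    active = True
                    break
            row[group] = active
        rows[mag_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=means.columns)
    out.index.name = "mag_id"
    out["active_any"] = out.any(axis=1)
    return out


def order_activity_fractions(
    getmm_matrix: pd.DataFrame,
    gene_to_mag: Mapping[str, str],
    mag_to_order: Mapping[str, str],
    design: pd.DataFrame,
    methanogen_mags: set[str] | None = None,
) -> pd.DataFrame:
    """Order-level share of methanogen transcription per replicate group.

    fraction(order, group) = sum of group-mean geTMM over the order's genes
    / sum over all methanogen genes.  Columns sum to 1 where the group has
    any methanogen expression; groups with none are reported as missing.
    """
    means = group_means(getmm_matrix, design)
    mags = pd.Series({g: gene_to_mag.get(g) for g in means.index})
    keep = mags.dropna()
    if methanogen_mags is not None:
        keep = keep[keep.isin(methanogen_mags)]
    means = means.loc[keep.index]
    orders = keep.map(lambda m: mag_to_order.get(m, "unclassified"))
    summed = means.groupby(orders.to_numpy()).sum()
    totals = summed.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fractions = summed.div(totals, axis=1)
    fractions.loc[:, totals == 0] = np.nan
    if (totals == 0).any():
        log.warning(
            "groups without methanogen expression: %s",
            list(totals.index[totals == 0]),
        )
    fractions.index.name = "order"
    return fractions


def abundance_normalized_expression(
    getmm_means: pd.DataFrame,
    gene_to_mag: Mapping[str, str],
    abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Group-mean geTMM divided by the gene's MAG relative abundance.

    ``abundance`` is MAG x group relative abundance from the matched
    metagenomes.  Zero abundance with nonzero expression is reported as
    missing (not infinity) with a logged warning; zero expression stays 0.
    """
    out = pd.DataFrame(index=getmm_means.index, columns=getmm_means.columns, dtype=float)
    flagged = []
    for gene in getmm_means.index:
        mag = gene_to_mag.get(gene)
        for group in getmm_means.columns:
            expr = getmm_means.loc[gene, group]
            ab = (
                abundance.loc[mag, group]
                if mag in abundance.index and group in abundance.columns
                else 0.0
            )
            if expr == 0:
                out.loc[gene, group] = 0.0
            elif ab > 0:
                out.loc[gene, group] = expr / ab
            else:
                out.loc[gene, group] = np.nan
                flagged.append((gene, group))
    if flagged:
        log.warning("expression with zero matched abundance: %s", flagged[:5])
    return out


# ---------------------------------------------------------------------------
# coverage-based abundance


def trimmed_mean_coverage(
    depth_values: Sequence[float], params: NormalizationParams | None = None
) -> float:
    """Mean per-base depth between the trim percentiles of coverage.

    Depths are sorted; positions with sorted index i in
    [floor(trim_min * n), ceil(trim_max * n)) are averaged (an
    inclusive-exclusive convention).  For a length-1 vector this degenerates
    to the value itself.
    """
    params = params or NormalizationParams()
    arr = np.sort(np.asarray(depth_values, dtype=float))
    if arr.size == 0:
        raise QuantError("empty depth vector")
    lo = int(np.floor(params.coverage_trim_min * arr.size))
    hi = int(np.ceil(params.coverage_trim_max * arr.size))
    return float(arr[lo:hi].mean())


def relative_abundance(
    coverages: pd.DataFrame, denominator_set: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample relative abundance over a denominator MAG set.

    ``coverages`` is MAG x sample trimmed-mean coverage.  Fractions are
    coverage / summed coverage of the denominator set, restricted to that
    set; a sample whose denominator sums to zero (e.g. a habitat where the
    group is below detection) is reported as missing with a warning.
    """
    if denominator_set is None:
        sub = coverages
    else:
        missing = set(denominator_set) - set(coverages.index)
        if missing:
            raise QuantError(f"denominator MAGs missing from coverage table: {sorted(missing)}")
        sub = coverages.loc[list(denominator_set)]
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        log.warning(
            "samples with zero denominator coverage (below detection): %s",
            list(totals.index[totals == 0]),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = sub.div(totals.replace(0, np.nan), axis=1)
    return out


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise QuantError("need two equal-length vectors with at least 3 points")
    if np.var(x) == 0 or np.var(y) == 0:
        raise QuantError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)
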