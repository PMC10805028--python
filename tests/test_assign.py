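import math

import numpy as np
import pytest

from methyloscan.assign import (
    AssignmentError,
    GeneAssignment,
    PylStatus,
    assign_identity,
    detect_operons,
    detect_pyl,
    read_assignments,
    refine_mttb_substrate,
    write_assignments,
)
from methyloscan.catalog import (
    ReferenceCatalog,
    ReferenceGene,
    SubstrateCategory,
    SystemRole,
)
from methyloscan.screen import Hit
from methyloscan.simulate import back_translate


@pytest.fixture(scope="module")
def toy_catalog():
    cat = ReferenceCatalog()
    entries = [
        ("mtaB_t", SystemRole.MTXB, SubstrateCategory.METHYL_O, "mtaB methanol"),
        ("mttB_t", SystemRole.MTXB, SubstrateCategory.METHYL_N, "mttB Pyl trimethylamine"),
        ("mtbB_t", SystemRole.MTXB, SubstrateCategory.METHYL_N, "mtbB dimethylamine"),
        ("mtaC_t", SystemRole.MTXC, SubstrateCategory.METHYL_O, "mtaC"),
        ("mtaA_t", SystemRole.MTXA, SubstrateCategory.METHYL_O, "mtaA"),
        ("ramA_t", SystemRole.RAMX, SubstrateCategory.AMBIGUOUS, ""),
    ]
    for gid, role, cat_, sub in entries:
        cat.add(ReferenceGene(gid, role, cat_, sub, "MKTAYIAKQR"))
    return cat


def _hit(gene, ref, bits, mag="MAG1"):
    return Hit(gene, mag, ref, bitscore=bits)


class TestAssignIdentity:
    def test_unopposed_single_hit(self, toy_catalog):
        a = assign_identity([_hit("g1", "mtaB_t", 150.0)], toy_catalog, 10.0)
        assert a.role is SystemRole.MTXB
        assert a.substrate is SubstrateCategory.METHYL_O
        assert a.subtype == "mtaB methanol"
        assert a.margin_bits == math.inf

    def test_wide_margin_keeps_best_category(self, toy_catalog):
        hits = [_hit("g1", "mtaB_t", 250.0), _hit("g1", "mttB_t", 100.0)]
        a = assign_identity(hits, toy_catalog, 10.0)
        assert a.substrate is SubstrateCategory.METHYL_O
        assert a.margin_bits == pytest.approx(150.0)

    def test_narrow_cross_category_margin_goes_ambiguous(self, toy_catalog):
        hits = [_hit("g1", "mtaB_t", 105.0), _hit("g1", "mtbB_t", 101.0)]
        a = assign_identity(hits, toy_catalog, 10.0)
        assert a.substrate is SubstrateCategory.AMBIGUOUS
        assert a.subtype == ""
        assert a.margin_bits == pytest.approx(4.0)

    def test_same_category_competitors_stay_specific(self, toy_catalog):
        # mttB vs mtbB are both methyl-N: a close call within one category
        # still resolves the category
        hits = [_hit("g1", "mttB_t", 105.0), _hit("g1", "mtbB_t", 104.0)]
        a = assign_identity(hits, toy_catalog, 10.0)
        assert a.substrate is SubstrateCategory.METHYL_N

    def test_ramx_never_resolves_substrate(self, toy_catalog):
        a = assign_identity([_hit("g1", "ramA_t", 300.0)], toy_catalog, 10.0)
        assert a.role is SystemRole.RAMX
        assert a.substrate is SubstrateCategory.AMBIGUOUS

    def test_order_invariance_with_lexicographic_ties(self, toy_catalog):
        hits = [_hit("g1", "mttB_t", 100.0), _hit("g1", "mtbB_t", 100.0)]
        a1 = assign_identity(hits, toy_catalog, 10.0)
        a2 = assign_identity(hits[::-1], toy_catalog, 10.0)
        assert a1 == a2
        assert a1.best_reference_id == "mtbB_t"  # lexicographic tie-break

    def test_empty_hits_error(self, toy_catalog):
        with pytest.raises(AssignmentError):
            assign_identity([], toy_catalog, 10.0)


def _gff(genes_by_contig):
    """genes_by_contig: {contig: [gene ids in order]} -> GFF3 text."""
    lines = ["##gff-version 3"]
    for contig, genes in genes_by_contig.items():
        pos = 1
        for gid in genes:
            lines.append(
                f"{contig}\tsim\tCDS\t{pos}\t{pos + 299}\t.\t+\t0\tID={gid}"
            )
            pos += 350
    return "\n".join(lines) + "\n"


def _assignment(gene, role, mag="MAG1"):
    return GeneAssignment(
        gene_id=gene, mag_id=mag, role=role,
        substrate=SubstrateCategory.METHYL_O, subtype="x",
        best_reference_id="r", best_bitscore=100.0, margin_bits=50.0,
    )


class TestDetectOperons:
    def test_adjacent_system_forms_one_cluster(self):
        gff = _gff({"c1": ["d1", "b", "c", "a", "r", "d2"]})
        assigns = [
            _assignment("b", SystemRole.MTXB),
            _assignment("c", SystemRole.MTXC),
            _assignment("a", SystemRole.MTXA),
            _assignment("r", SystemRole.RAMX),
        ]
        operons, flagged = detect_operons(assigns, gff, max_intergenic=2)
        assert len(operons) == 1
        assert operons[0].roles_present == {
            SystemRole.MTXB, SystemRole.MTXC, SystemRole.MTXA, SystemRole.RAMX
        }
        assert operons[0].member_gene_ids == ["b", "c", "a", "r"]
        assert all(a.syntenic for a in flagged)

    def test_genes_on_different_contigs_never_cluster(self):
        gff = _gff({"c1": ["b"], "c2": ["c"]})
        assigns = [_assignment("b", SystemRole.MTXB), _assignment("c", SystemRole.MTXC)]
        operons, flagged = detect_operons(assigns, gff, max_intergenic=2)
        assert operons == []
        assert not any(a.syntenic for a in flagged)

    def test_three_intervening_genes_break_the_cluster(self):
        gff = _gff({"c1": ["b", "x1", "x2", "x3", "c"]})
        assigns = [_assignment("b", SystemRole.MTXB), _assignment("c", SystemRole.MTXC)]
        operons, _ = detect_operons(assigns, gff, max_intergenic=2)
        assert operons == []

    def test_two_intervening_genes_still_cluster(self):
        gff = _gff({"c1": ["b", "x1", "x2", "c"]})
        assigns = [_assignment("b", SystemRole.MTXB), _assignment("c", SystemRole.MTXC)]
        operons, _ = detect_operons(assigns, gff, max_intergenic=2)
        assert len(operons) == 1
        assert operons[0].max_intergenic_genes == 2

    def test_coordinate_direction_invariance(self):
        fwd = _gff({"c1": ["d1", "b", "c", "a", "d2"]})
        rev = _gff({"c1": ["d2", "a", "c", "b", "d1"]})
        assigns = [
            _assignment("b", SystemRole.MTXB),
            _assignment("c", SystemRole.MTXC),
            _assignment("a", SystemRole.MTXA),
        ]
        op_f, _ = detect_operons(assigns, fwd, max_intergenic=2)
        op_r, _ = detect_operons(assigns, rev, max_intergenic=2)
        assert len(op_f) == len(op_r) == 1
        assert set(op_f[0].member_gene_ids) == set(op_r[0].member_gene_ids)
        assert op_f[0].roles_present == op_r[0].roles_present

    def test_missing_gene_is_named(self):
        gff = _gff({"c1": ["b"]})
        with pytest.raises(AssignmentError, match="ghost"):
            detect_operons([_assignment("ghost", SystemRole.MTXB)], gff, 2)


def _mttb_cds(n_codons=500, stop_at=None, stop="TAG", rng_seed=0):
    """Construct an mttB-like CDS of n_codons with an internal stop."""
    rng = np.random.default_rng(rng_seed)
    aas = "".join(np.random.default_rng(rng_seed).choice(list("ACDEFGHIKLMNPQRSTVWY"), n_codons))
    nt = back_translate(aas, rng)
    if stop_at is not None:
        nt = nt[: stop_at * 3] + stop + nt[(stop_at + 1) * 3 :]
    return nt + "TAA"


class TestDetectPyl:
    def test_truncating_amber_with_readthrough_is_pyl(self):
        cds = _mttb_cds(500, stop_at=150, stop="TAG")
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.status is PylStatus.PYL
        assert result.called_length_aa == 150
        assert result.stop_codon == "TAG"
        assert not result.low_confidence

    def test_truncating_ochre_is_non_pyl(self):
        cds = _mttb_cds(500, stop_at=150, stop="TAA")
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.status is PylStatus.NON_PYL

    def test_full_length_gene_is_non_pyl(self):
        cds = _mttb_cds(500)  # ends with TAA after 500 codons
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.status is PylStatus.NON_PYL
        assert result.called_length_aa == 500

    def test_amber_followed_by_quick_stop_is_non_pyl(self):
        # TAG at 150 but another stop 5 codons later: no real readthrough
        cds = _mttb_cds(500, stop_at=150, stop="TAG")
        cds = cds[: 155 * 3] + "TGA" + cds[156 * 3 :]
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.status is PylStatus.NON_PYL

    def test_short_context_flags_low_confidence(self):
        # sequence cut 10 codons after the amber: readthrough cannot resolve
        cds = _mttb_cds(500, stop_at=150, stop="TAG")[: 161 * 3]
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.low_confidence

    def test_ambiguous_nucleotide_flags_not_errors(self):
        cds = _mttb_cds(500, stop_at=150, stop="TAG")
        cds = cds[:30] + "NNN" + cds[33:]
        result = detect_pyl(cds, reference_length_aa=500)
        assert result.low_confidence

    def test_pure_function_of_inputs(self):
        cds = _mttb_cds(500, stop_at=150, stop="TAG")
        assert detect_pyl(cds, 500) == detect_pyl(cds, 500)


class TestRefineMttb:
    def _mttb_assignment(self):
        return GeneAssignment(
            gene_id="g1", mag_id="M1", role=SystemRole.MTXB,
            substrate=SubstrateCategory.METHYL_N,
            subtype="mttB Pyl trimethylamine",
            best_reference_id="mttB_t", best_bitscore=200.0, margin_bits=100.0,
        )

    def test_pyl_subtype(self):
        a = refine_mttb_substrate(self._mttb_assignment(), PylStatus.PYL)
        assert a.substrate is SubstrateCategory.METHYL_N
        assert "Pyl-MttB" in a.subtype
        assert a.pyl_status is PylStatus.PYL

    def test_non_pyl_subtype(self):
        a = refine_mttb_substrate(self._mttb_assignment(), PylStatus.NON_PYL)
        assert a.substrate is SubstrateCategory.METHYL_N
        assert "quaternary amine" in a.subtype

    def test_non_mttb_assignment_rejected(self):
        a = self._mttb_assignment()
        a.subtype = "mtaB methanol"
        with pytest.raises(AssignmentError):
            refine_mttb_substrate(a, PylStatus.PYL)


def test_assignment_tsv_round_trip(tmp_path):
    a = GeneAssignment(
        gene_id="g1", mag_id="M1", role=SystemRole.MTXB,
        substrate=SubstrateCategory.METHYL_O, subtype="mtaB methanol",
        best_reference_id="mtaB_t", best_bitscore=123.4, margin_bits=math.inf,
        syntenic=True, pyl_status=PylStatus.NOT_APPLICABLE,
    )
    path = tmp_path / "assignments.tsv"
    write_assignments([a], path)
    assert read_assignments(path) == [a]
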