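"""Regenerate the packaged synthetic reference catalog.

The curated catalog used in field studies of corrinoid-dependent
methylotrophy is a set of 53 well-characterized gene types: 20 substrate:
corrinoid methyltransferases (mtxB family, including the methyl-sulfide
mtsA/mtsB pair and the tri-functional fused mtsD/mtsF/mtsH), 16 corrinoid-
binding proteins (mtxC), 10 methylcorrinoid:carrier methyltransferases
(mtxA) and 7 reductive activases (ramX).  This repository cannot ship the
original curated protein sequences, so it packages a SYNTHETIC stand-in
catalog with the same family composition, substrate annotations and
realistic sequence lengths: each gene family descends from a random
ancestor protein, with family members mutated to 75-90% identity using
BLOSUM62 exchangeabilities.  Cross-family identity is at random-sequence
background, so homology screening behaves qualitatively like a screen
against the real catalog (strong within-family hits, negligible
cross-family hits).

Run from the repository root:

    python scripts/build_reference_catalog.py

Outputs (overwritten in place):
    src/methyloscan/data/reference_catalog_synthetic.faa
    src/methyloscan/data/reference_catalog_synthetic.tsv
    src/methyloscan/data/substrate_chemistry.tsv
"""

from __future__ import annotations

import pathlib

import numpy as np
from Bio.Align import substitution_matrices

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "methyloscan" / "data"

AA = "ACDEFGHIKLMNPQRSTVWY"

# family name -> (n members, role, category, subtype, length)
FAMILIES = [
    ("mtaB", 3, "MtxB", "methyl_O", "mtaB methanol", 460),
    ("mttB", 3, "MtxB", "methyl_N", "mttB Pyl trimethylamine", 500),
    ("mttB-nonPyl", 2, "MtxB", "methyl_N", "non-Pyl mttB quaternary amine", 490),
    ("mtbB", 2, "MtxB", "methyl_N", "mtbB dimethylamine", 470),
    ("mtmB", 2, "MtxB", "methyl_N", "mtmB monomethylamine", 460),
    ("mtoB", 3, "MtxB", "methyl_O", "methoxy", 450),
    ("mtsA", 1, "MtxB", "methyl_S", "mtsA", 340),
    ("mtsB", 1, "MtxB", "methyl_S", "mtsB", 220),
    ("mtsD", 1, "MtsFused", "methyl_S", "mtsD/F/H", 700),
    ("mtsF", 1, "MtsFused", "methyl_S", "mtsD/F/H", 700),
    ("mtsH", 1, "MtsFused", "methyl_S", "mtsD/F/H", 700),
    ("mtaC", 4, "MtxC", "methyl_O", "mtaC", 230),
    ("mttC", 4, "MtxC", "methyl_N", "mttC", 230),
    ("mtbC", 3, "MtxC", "methyl_N", "mtbC", 220),
    ("mtmC", 2, "MtxC", "methyl_N", "mtmC", 220),
    ("mtoC", 3, "MtxC", "methyl_O", "methoxy mtxC", 230),
    ("mtaA", 4, "MtxA", "methyl_O", "mtaA", 330),
    ("mtbA", 3, "MtxA", "methyl_N", "mtbA", 330),
    ("mtoA", 3, "MtxA", "methyl_O", "methoxy mtxA", 320),
    ("ramA", 4, "RamX", "ambiguous", "", 600),
    ("ramM", 3, "RamX", "ambiguous", "", 590),
]

CHEM_ROWS = [
    ("methanol", "methyl_O", 1),
    ("syringate", "methyl_O", 2),
    ("trimethoxybenzoate", "methyl_O", 3),
    ("apocynin", "methyl_O", 1),
    ("monomethylamine", "methyl_N", 1),
    ("dimethylamine", "methyl_N", 2),
    ("trimethylamine", "methyl_N", 3),
    ("glycine betaine", "methyl_N", 3),
    ("choline", "methyl_N", 3),
    ("trigonelline", "methyl_N", 1),
    ("methanethiol", "methyl_S", 1),
    ("dimethyl sulfide", "methyl_S", 2),
]


def exchange_probs() -> np.ndarray:
    """P(a -> b) proportional to exp(BLOSUM62[a, b]) over b != a."""
    b62 = substitution_matrices.load("BLOSUM62")
    n = len(AA)
    probs = np.zeros((n, n))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                probs[i, j] = np.exp(float(b62[a, b]))
        probs[i] /= probs[i].sum()
    return probs


def mutate(seq: str, identity: float, rng: np.random.Generator, probs: np.ndarray) -> str:
    idx = {a: i for i, a in enumerate(AA)}
    n_mut = int(round(len(seq) * (1.0 - identity)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = AA[rng.choice(len(AA), p=probs[idx[out[p]]])]
    return "".join(out)


def main() -> None:
    rng = np.random.default_rng(53)
    probs = exchange_probs()
    fasta_lines: list[str] = []
    meta_lines = ["id\trole\tsubstrate_category\tsubstrate_subtype\tsource_note"]
    for family, n, role, category, subtype, length in FAMILIES:
        ancestor = "".join(rng.choice(list(AA), size=length))
        for k in range(1, n + 1):
            ident = rng.uniform(0.75, 0.90)
            seq = mutate(ancestor, ident, rng, probs)
            gene_id = f"{family}_{k}"
            fasta_lines.append(f">{gene_id}")
            fasta_lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
            meta_lines.append(
                f"{gene_id}\t{role}\t{category}\t{subtype}\t"
                f"synthetic stand-in, {family} family"
            )
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "reference_catalog_synthetic.faa").write_text("\n".join(fasta_lines) + "\n")
    (OUT / "reference_catalog_synthetic.tsv").write_text("\n".join(meta_lines) + "\n")
    chem = ["name\tcategory\tmethyl_equivalents"]
    chem += [f"{n}\t{c}\t{m}" for n, c, m in CHEM_ROWS]
    (OUT / "substrate_chemistry.tsv").write_text("\n".join(chem) + "\n")
    print(f"wrote catalog ({sum(f[1] for f in FAMILIES)} entries) to {OUT}")


if __name__ == "__main__":
    main()
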