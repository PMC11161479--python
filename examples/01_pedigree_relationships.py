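"""Pedigree relationship matrices: A, its inverse, and the genotyped block.

Builds the classic full-sib mating example and prints the coefficients a
breeder would expect: parent-offspring 0.5, full sibs 0.5, and an inbred
offspring with diagonal 1.25 (F = 0.25).
"""

import numpy as np

from wssgwas import Pedigree, build_A, build_A_inverse, extract_A22, sort_pedigree

ped = sort_pedigree(
    Pedigree.from_records(
        [
            ("sire", None, None),
            ("dam", None, None),
            ("sib1", "sire", "dam"),
            ("sib2", "sire", "dam"),
            ("inbred", "sib1", "sib2"),
        ]
    )
)

A = build_A(ped)
print("Numerator relationship matrix A (order:", ", ".join(A.ids) + "):")
print(np.round(A.values, 3))
print()
print(f"full sibs:            a(sib1, sib2) = {A.loc('sib1', 'sib2'):.3f}")
print(f"inbred diagonal:      a(inbred, inbred) = {A.loc('inbred', 'inbred'):.3f}  (1 + F, F = 0.25)")

Ainv = build_A_inverse(ped)
print()
print("A^-1 (Henderson's rules with inbreeding) times A is the identity:")
print("max |A A^-1 - I| =", f"{np.abs(A.values @ Ainv.values - np.eye(len(ped))).max():.2e}")

A22 = extract_A22(A, ["sib1", "inbred"])
print()
print("A22 for the 'genotyped' pair (sib1, inbred):")
print(np.round(A22.values, 3))
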