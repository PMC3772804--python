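"""Parse a pedigree and compute additive genetic relationships.

Builds a three-generation family as PED text, runs the tabular recursion,
and prints selected coefficients plus the relative-pair census. The
coefficients are the expected fractions of shared additive genetic effects
(twice the kinship coefficient): 0.5 for parent-offspring and siblings,
0.25 for grandparent-grandchild and avuncular pairs.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from pedimeth import additive_relationship, pair_degree_census, read_pedigree

PED = """\
F1 GF 0 0 1
F1 GM 0 0 2
F1 SP 0 0 2
F1 C1 GF GM 1
F1 C2 GF GM 2
F1 K1 C1 SP 2
F1 K2 C1 SP 1
"""

with TemporaryDirectory() as tmp:
    path = Path(tmp) / "family.ped"
    path.write_text(PED)
    ped = read_pedigree(path)

rel = additive_relationship(ped)
print(f"{len(ped)} individuals, founders: {sorted(ped.founders)}")
for a, b in [("GF", "C1"), ("C1", "K1"), ("K1", "K2"), ("GF", "K1"),
             ("C2", "K1"), ("GF", "SP")]:
    print(f"  A[{a},{b}] = {rel.coefficient(a, b):.4g}")
print("\nRelative-pair census (degree -> pair count):")
print(pair_degree_census(rel).to_string(index=False))
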