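"""Small sequence helpers shared across the pipeline.

Internal convention everywhere: DNA coordinates are 0-based, half-open,
on the forward strand of the scaffold; writers convert to 1-based closed.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Standard genetic code; stops kept as '*', codons containing N give 'X'.
CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a DNA string frame 0; partial trailing codon dropped.

    Stop codons become '*', codons with N (or any non-ACGT symbol) 'X'.
    """
    dna = dna.upper()
    n = len(dna) // 3
    out = []
    for i in range(n):
        out.append(CODON_TABLE.get(dna[3 * i : 3 * i + 3], "X"))
    return "".join(out)


AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
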