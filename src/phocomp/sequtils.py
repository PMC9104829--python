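"""Small shared sequence helpers used across the pipeline modules."""

from __future__ import annotations

import math

import numpy as np
from Bio.Data import CodonTable

DNA = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid ('*' for stop)
CODON_TO_AA = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> sorted list of codons (deterministic order)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a complete CDS; trailing stop is dropped, internal stops kept as '*'."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    aa = "".join(CODON_TO_AA[cds[i:i + 3]] for i in range(0, len(cds), 3))
    return aa[:-1] if aa.endswith("*") else aa


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate a protein to a CDS with a seeded uniform codon choice.

    A stop codon (TAA/TAG/TGA, chosen at random) is appended.
    """
    codons = []
    for aa in protein:
        choices = AA_TO_CODONS[aa]
        codons.append(choices[rng.integers(len(choices))])
    stops = AA_TO_CODONS["*"]
    codons.append(stops[rng.integers(len(stops))])
    return "".join(codons)


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, size=n)])


def random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, size=n)])


def truncate2(x: float) -> float:
    """Two-decimal truncation (floor), the rendering used for percent shares."""
    return math.floor(x * 100.0) / 100.0
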