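"""Low-level DNA utilities: genetic code, translation, reverse complement.

Translation is vectorised with numpy (the search stage translates whole
assemblies in six frames). Codons containing any non-ACGT base translate
to 'X'; stop codons render as '*'.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_standard = CodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"

#: synonymous codons per amino acid (stops excluded), sorted for determinism
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, []).append(_codon)

_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

# 5x5x5 codon index space; index 4 in any slot = ambiguous base -> 'X'
_CODON_AA = np.full(125, ord("X"), dtype=np.uint8)
for _codon, _aa in GENETIC_CODE.items():
    _i0, _i1, _i2 = (int(_BASE_INDEX[ord(c)]) for c in _codon)
    _CODON_AA[_i0 * 25 + _i1 * 5 + _i2] = ord(_aa)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANTGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0) -> str:
    """Translate one forward reading frame (0, 1 or 2) of ``dna``."""
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    arr = _BASE_INDEX[np.frombuffer(dna.encode("ascii"), dtype=np.uint8)]
    usable = 3 * ((len(arr) - frame) // 3)
    if usable <= 0:
        return ""
    codons = arr[frame : frame + usable].reshape(-1, 3).astype(np.int32)
    idx = codons[:, 0] * 25 + codons[:, 1] * 5 + codons[:, 2]
    return _CODON_AA[idx].tobytes().decode("ascii")
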