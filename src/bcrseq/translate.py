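"""Codon translation under the standard genetic code.

The reading frame throughout the package is fixed by the V-segment anchor
codon (IMGT convention), so translation is always frame 0 of the supplied
fragment; stops are reported as ``*``.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


def translate(nt: str) -> str:
    """Translate complete codons of ``nt``; trailing partial codons ignored."""
    return "".join(CODON_TABLE.get(nt[i:i + 3], "X")
                   for i in range(0, len(nt) - len(nt) % 3, 3))


def has_stop(nt: str) -> bool:
    """True if any complete in-frame codon of ``nt`` is a stop."""
    return "*" in translate(nt)
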