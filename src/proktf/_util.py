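"""Shared helpers: errors, codon tables, reverse complement."""

from __future__ import annotations

from Bio.Data import CodonTable

__all__ = [
    "ProktfError",
    "BACTERIAL_TABLE",
    "STOP_CODONS",
    "revcomp",
    "translate_bacterial",
]


class ProktfError(Exception):
    """Base error for invalid inputs or configuration."""


_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
BACTERIAL_TABLE = dict(_TABLE11.forward_table)
STOP_CODONS = frozenset(_TABLE11.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_bacterial(nt: str, *, start_is_met: bool = True) -> str:
    """Translate an in-frame CDS (stop codon optional) with table 11.

    Any codon containing N becomes X; the initiator codon is rendered M
    whatever its identity (fMet initiation), unless ``start_is_met`` is off.
    """
    aa = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in STOP_CODONS:
            if i == len(nt) - 3:
                break
            aa.append("*")
        else:
            aa.append(BACTERIAL_TABLE[codon])
    if aa and start_is_met:
        aa[0] = "M"
    return "".join(aa)
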