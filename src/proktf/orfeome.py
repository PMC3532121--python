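"""ORFeome reconstitution: exhaustive valid-ORF enumeration on both strands.

A *valid ORF* is a maximal stretch that begins at a start codon and runs to
the first in-frame stop codon, on either strand, in any of the six reading
frames.  Translating every valid ORF of a replicon yields its ORFeome, which
is screened alongside the deposited proteome so that regulator genes missed
by the original annotation ("mispredicted" genes) can be recovered.

Coordinates in all records are 1-based inclusive and always refer to the
forward strand of the replicon, GenBank style.  The scan itself runs on a
base-5 numeric encoding of the sequence so that whole-genome scans stay
cheap; codons containing N never act as start or stop and translate as X.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._util import ProktfError, revcomp, translate_bacterial

__all__ = [
    "DEFAULT_START_CODONS",
    "ALLOWED_START_CODONS",
    "GeneFeature",
    "Replicon",
    "OrfRecord",
    "make_orf_id",
    "scan_orfs",
    "build_orfeome",
    "find_mispredicted",
]

logger = logging.getLogger(__name__)

#: Standard prokaryotic initiators under the bacterial code.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG", "TTG"})
#: Initiators accepted by the bacterial code at all (superset of the default).
ALLOWED_START_CODONS = frozenset({"ATG", "GTG", "TTG", "CTG", "ATT"})

_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a replicon (1-based inclusive coordinates)."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"  # CDS | pseudogene | other
    product_id: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ProktfError(
                f"feature {self.locus_tag}: bad interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ProktfError(f"feature {self.locus_tag}: strand must be + or -")
        if self.kind not in ("CDS", "pseudogene", "other"):
            raise ProktfError(f"feature {self.locus_tag}: unknown kind {self.kind!r}")


@dataclass
class Replicon:
    """A named DNA sequence with topology and its annotated features."""

    id: str
    sequence: str
    topology: str = "linear"  # linear | circular
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ProktfError(f"replicon {self.id}: empty sequence")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ProktfError(
                f"replicon {self.id}: non-alphabet characters {sorted(bad)!r}"
            )
        if self.topology not in ("linear", "circular"):
            raise ProktfError(f"replicon {self.id}: topology {self.topology!r}")
        self.sequence = seq
        tags = [f.locus_tag for f in self.features]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ProktfError(f"replicon {self.id}: duplicate locus tags {dup}")
        limit = len(seq) if self.topology == "linear" else 2 * len(seq)
        for f in self.features:
            if f.end > limit:
                raise ProktfError(
                    f"replicon {self.id}: feature {f.locus_tag} exceeds length"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]

    def pseudogene_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "pseudogene"]


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame, stop codon included in the interval.

    ``start``/``end`` are forward-strand, 1-based inclusive.  For an ORF
    crossing the origin of a circular replicon ``wraps_origin`` is set and
    ``end`` < ``start`` after normalisation; otherwise
    ``nt_length == end - start + 1``.
    """

    orf_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    frame: int  # 1-3 forward, 4-6 reverse
    nt_length: int
    translation: str
    provenance: str = "orfeome"  # annotated | orfeome
    wraps_origin: bool = False
    mispredicted: bool = False

    @property
    def aa_length(self) -> int:
        return len(self.translation)


def make_orf_id(replicon_id: str, start: int, end: int, strand: str) -> str:
    """Deterministic ORF identifier used across hit tables and exports."""
    return f"{replicon_id}_{start}_{end}_{'f' if strand == '+' else 'r'}"


# -- numeric six-frame scan ---------------------------------------------------

_ENC = np.full(256, 64, dtype=np.int32)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
# N (and any other IUPAC letter) keeps the poison value 64, so any codon
# containing it encodes to >= 64*25 and can never match a start or stop.


def _codon_values(codons: Iterable[str]) -> np.ndarray:
    return np.array(
        sorted(_ENC[ord(c[0])] * 25 + _ENC[ord(c[1])] * 5 + _ENC[ord(c[2])] for c in codons),
        dtype=np.int32,
    )


_STOP_VALUES = _codon_values(("TAA", "TAG", "TGA"))


def _scan_frame(
    enc: np.ndarray,
    offset: int,
    start_values: np.ndarray,
    min_aa: int,
    all_starts: bool,
) -> list[tuple[int, int]]:
    """Return 0-based (start_nt, stop_last_nt) pairs for one frame.

    One ORF per stop codon: the earliest start after the previous in-frame
    stop (i.e. the longest compatible ORF).  With ``all_starts`` every nested
    start long enough is reported.
    """
    usable = (enc.size - offset) // 3
    if usable == 0:
        return []
    tri = enc[offset : offset + usable * 3].reshape(-1, 3)
    vals = tri[:, 0] * 25 + tri[:, 1] * 5 + tri[:, 2]
    stop_idx = np.flatnonzero(np.isin(vals, _STOP_VALUES))
    if stop_idx.size == 0:
        return []
    start_idx = np.flatnonzero(np.isin(vals, start_values))
    if start_idx.size == 0:
        return []
    out: list[tuple[int, int]] = []
    prev = np.concatenate(([-1], stop_idx[:-1]))
    # first start index strictly after the previous stop, for each stop
    first = np.searchsorted(start_idx, prev + 1)
    for k in range(stop_idx.size):
        j = first[k]
        stop = stop_idx[k]
        if all_starts:
            while j < start_idx.size and start_idx[j] < stop:
                if stop - start_idx[j] >= min_aa:
                    out.append((int(offset + 3 * start_idx[j]), int(offset + 3 * stop + 2)))
                j += 1
        else:
            if j < start_idx.size and start_idx[j] < stop:
                if stop - start_idx[j] >= min_aa:
                    out.append((int(offset + 3 * start_idx[j]), int(offset + 3 * stop + 2)))
    return out


def scan_orfs(
    replicon: Replicon,
    min_aa_length: int = 60,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    *,
    all_starts: bool = False,
    provenance: str = "orfeome",
) -> list[OrfRecord]:
    """Enumerate valid ORFs of a replicon on both strands, all six frames.

    Parameters
    ----------
    min_aa_length
        Minimum translated length, stop codon excluded.
    start_codons
        Accepted initiators; must be a non-empty subset of
        :data:`ALLOWED_START_CODONS`.
    all_starts
        Also emit nested ORFs sharing a stop with a longer one.

    For a circular replicon the scan runs on the doubled sequence and each
    origin-spanning ORF is reported once with ``wraps_origin`` set; ORFs as
    long as the replicon or longer are dropped.
    """
    starts = frozenset(c.upper() for c in start_codons)
    if not starts or not starts <= ALLOWED_START_CODONS:
        raise ProktfError(
            f"start codons must be a non-empty subset of {sorted(ALLOWED_START_CODONS)}"
        )
    if min_aa_length < 1:
        raise ProktfError("min_aa_length must be >= 1")
    start_values = _codon_values(starts)

    L = len(replicon)
    circular = replicon.topology == "circular"
    seq = replicon.sequence + replicon.sequence if circular else replicon.sequence

    records: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        enc = _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        for off in range(3):
            for a, b in _scan_frame(enc, off, start_values, min_aa_length, all_starts):
                nt_len = b - a + 1
                # leftmost forward coordinate on the scanned string
                f_start = a if strand == "+" else len(s) - 1 - b
                if circular:
                    # the doubled sequence shows every ORF twice; keep the
                    # copy starting (in scan coordinates) in the first period
                    if a >= L or nt_len >= L:
                        continue
                    p_start = f_start % L
                    p_end = p_start + nt_len - 1
                    wraps = p_end >= L
                    start1 = p_start + 1
                    end1 = p_end % L + 1
                else:
                    wraps = False
                    start1, end1 = f_start + 1, f_start + nt_len
                nt = s[a : b + 1]
                records.append(
                    OrfRecord(
                        orf_id=make_orf_id(replicon.id, start1, end1, strand),
                        replicon_id=replicon.id,
                        start=start1,
                        end=end1,
                        strand=strand,
                        frame=(off + 1) if strand == "+" else (off + 4),
                        nt_length=nt_len,
                        translation=translate_bacterial(nt),
                        provenance=provenance,
                        wraps_origin=wraps,
                    )
                )
    return records


def build_orfeome(
    replicon: Replicon,
    min_aa_length: int = 60,
    start_codons: Iterable[str] = DEFAULT_START_CODONS,
    *,
    all_starts: bool = False,
) -> list[OrfRecord]:
    """Deduplicated ORFeome in deterministic (start, end, strand) order."""
    seen: dict[tuple[int, int, str], OrfRecord] = {}
    for rec in scan_orfs(
        replicon, min_aa_length, start_codons, all_starts=all_starts
    ):
        seen.setdefault((rec.start, rec.end, rec.strand), rec)
    return [seen[k] for k in sorted(seen)]


def _intervals(start: int, end: int, length: int | None, wraps: bool) -> list[tuple[int, int]]:
    if wraps and length is not None:
        return [(start, length), (1, end)]
    return [(start, end)]


def _overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def find_mispredicted(
    orfeome_tf_candidates: Sequence[OrfRecord],
    features: Sequence[GeneFeature],
    overlap_threshold: float = 0.1,
    *,
    replicon_length: int | None = None,
) -> list[OrfRecord]:
    """Select ORFs absent from the deposited annotation.

    A candidate is retained when no annotated CDS on the same strand covers
    more than ``overlap_threshold`` of the ORF length, and it does not touch
    a pseudogene feature at all (either strand): gene remnants annotated as
    pseudogenes are deliberately not resurrected.  Retained records come back
    with ``mispredicted`` set.
    """
    if not 0 <= overlap_threshold <= 1:
        raise ProktfError("overlap_threshold must be in [0, 1]")
    if not features:
        warnings.warn(
            "no annotated features supplied: every candidate is 'mispredicted'",
            stacklevel=2,
        )
    cds = [f for f in features if f.kind == "CDS"]
    pseudo = [f for f in features if f.kind == "pseudogene"]
    kept: list[OrfRecord] = []
    for orf in orfeome_tf_candidates:
        ivs = _intervals(orf.start, orf.end, replicon_length, orf.wraps_origin)
        if any(
            _overlap_bp(iv, (p.start, p.end)) > 0 for p in pseudo for iv in ivs
        ):
            continue
        worst = 0.0
        for f in cds:
            if f.strand != orf.strand:
                continue
            ov = sum(_overlap_bp(iv, (f.start, f.end)) for iv in ivs)
            worst = max(worst, ov / orf.nt_length)
        if worst <= overlap_threshold:
            kept.append(replace(orf, mispredicted=True))
    return kept
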