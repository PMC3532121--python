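"""Domain-hit parsing, significance filtering and per-protein architectures.

Candidate regulators are recognised from profile matches (RPS-BLAST against
CDD-formatted Pfam/SMART profiles, or hmmscan) rather than from sequence
similarity.  A match counts only when its E-value is at most 0.01 and the
alignment covers at least 50% of the profile length; both boundaries are
inclusive.  Surviving hits are reduced to a non-redundant *architecture* —
the ordered list of domains along the protein — which is the sole input to
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._util import ProktfError
from .registry import DomainRoleRegistry

__all__ = [
    "DEFAULT_EVALUE_CUTOFF",
    "DEFAULT_MIN_COVERAGE",
    "RawHit",
    "DomainHit",
    "Architecture",
    "parse_hits",
    "filter_hits",
    "resolve_overlaps",
    "build_architecture",
    "architectures_from_hits",
]

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_CUTOFF = 0.01
DEFAULT_MIN_COVERAGE = 0.5

DIALECTS = ("rpsblast_tab", "hmmscan_domtbl")


@dataclass(frozen=True)
class RawHit:
    """One unfiltered profile match on one protein."""

    protein_id: str
    profile_accession: str
    evalue: float
    query_start: int  # 1-based aa
    query_end: int
    profile_aligned_length: int
    profile_total_length: int
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ProktfError(f"{self.protein_id}: negative E-value")
        if self.query_end < self.query_start or self.query_start < 1:
            raise ProktfError(f"{self.protein_id}: bad query interval")
        if not 0 < self.profile_aligned_length <= self.profile_total_length:
            raise ProktfError(f"{self.protein_id}: bad profile alignment length")

    @property
    def coverage(self) -> float:
        return self.profile_aligned_length / self.profile_total_length


@dataclass(frozen=True)
class DomainHit:
    """A significance-filtered hit annotated with its functional role."""

    protein_id: str
    accession: str  # canonical (alias-resolved) accession
    evalue: float
    query_start: int
    query_end: int
    coverage: float
    role: str
    bitscore: float = 0.0

    @property
    def span(self) -> int:
        return self.query_end - self.query_start + 1


@dataclass(frozen=True)
class Architecture:
    """Ordered domain complement of one protein."""

    protein_id: str
    hits: tuple[DomainHit, ...]
    signature: str
    dbd_count: int
    distinct_dbd_count: int

    def roles(self) -> set[str]:
        return {h.role for h in self.hits}


# -- parsing ------------------------------------------------------------------

def _parse_rpsblast_row(parts: list[str]) -> RawHit:
    # outfmt "6 std qlen slen": 12 standard columns then qlen, slen
    if len(parts) < 14:
        raise ValueError("expected 14 columns (outfmt 6 std qlen slen)")
    sstart, send = int(parts[8]), int(parts[9])
    return RawHit(
        protein_id=parts[0],
        profile_accession=parts[1],
        evalue=float(parts[10]),
        query_start=int(parts[6]),
        query_end=int(parts[7]),
        profile_aligned_length=abs(send - sstart) + 1,
        profile_total_length=int(parts[13]),
        bitscore=float(parts[11]),
    )


def _parse_domtbl_row(parts: list[str]) -> RawHit:
    # HMMER3 --domtblout: target name/acc/tlen, query name/acc/qlen, then
    # per-domain columns; we use the independent E-value and domain score
    if len(parts) < 22:
        raise ValueError("expected >= 22 whitespace-separated columns")
    acc = parts[1] if parts[1] != "-" else parts[0]
    hmm_from, hmm_to = int(parts[15]), int(parts[16])
    return RawHit(
        protein_id=parts[3],
        profile_accession=acc,
        evalue=float(parts[12]),
        query_start=int(parts[17]),
        query_end=int(parts[18]),
        profile_aligned_length=hmm_to - hmm_from + 1,
        profile_total_length=int(parts[2]),
        bitscore=float(parts[13]),
    )


def parse_hits(
    path: str | Path,
    dialect: str,
    *,
    errors: list[str] | None = None,
) -> list[RawHit]:
    """Read a domain-hit table.

    Supported dialects: ``rpsblast_tab`` (BLAST ``-outfmt "6 std qlen slen"``,
    tab-separated) and ``hmmscan_domtbl`` (HMMER3 ``--domtblout``).  Rows with
    unparseable or invalid numerics are rejected individually and recorded
    (with their row number) in ``errors`` and the log; an empty file yields an
    empty list with a warning.
    """
    if dialect not in DIALECTS:
        raise ProktfError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    row_parser = _parse_rpsblast_row if dialect == "rpsblast_tab" else _parse_domtbl_row
    hits: list[RawHit] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            n_rows += 1
            parts = line.split("\t") if dialect == "rpsblast_tab" else line.split()
            try:
                hits.append(row_parser(parts))
            except (ValueError, ProktfError) as exc:
                msg = f"{path}:{lineno}: rejected row ({exc})"
                logger.warning(msg)
                if errors is not None:
                    errors.append(msg)
    if n_rows == 0:
        logger.warning("%s: empty hit table", path)
    return hits


# -- filtering ----------------------------------------------------------------

def filter_hits(
    hits: Iterable[RawHit],
    registry: DomainRoleRegistry,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[DomainHit]:
    """Apply the significance filter and annotate roles.

    Retains exactly the hits with ``evalue <= evalue_cutoff`` and
    ``coverage >= min_coverage`` (inclusive boundaries); coverage is measured
    over the profile length.  Accessions unknown to the registry survive with
    role ``other``.
    """
    if evalue_cutoff <= 0 or min_coverage <= 0:
        raise ProktfError("cutoffs must be positive")
    out: list[DomainHit] = []
    for h in hits:
        if h.evalue <= evalue_cutoff and h.coverage >= min_coverage:
            acc = registry.canonical(h.profile_accession)
            out.append(
                DomainHit(
                    protein_id=h.protein_id,
                    accession=acc,
                    evalue=h.evalue,
                    query_start=h.query_start,
                    query_end=h.query_end,
                    coverage=h.coverage,
                    role=registry.role(acc),
                    bitscore=h.bitscore,
                )
            )
    return out


def _conflicts(a: DomainHit, b: DomainHit, min_frac: float) -> bool:
    ov = min(a.query_end, b.query_end) - max(a.query_start, b.query_start) + 1
    return ov > min_frac * min(a.span, b.span)


def resolve_overlaps(
    hits: Sequence[DomainHit],
    *,
    min_frac: float = 0.5,
    keep_overlaps: bool = False,
) -> list[DomainHit]:
    """Reduce one protein's hits to a non-redundant set.

    Where two hits overlap by more than ``min_frac`` of the shorter interval
    only the better one survives: lowest E-value, then highest bitscore, then
    lexicographically smallest accession.  ``keep_overlaps`` disables the
    reduction entirely (positional sort only).
    """
    if len({h.protein_id for h in hits}) > 1:
        raise ProktfError("resolve_overlaps expects hits from a single protein")
    if keep_overlaps:
        return sorted(hits, key=lambda h: (h.query_start, h.query_end, h.accession))
    ranked = sorted(hits, key=lambda h: (h.evalue, -h.bitscore, h.accession))
    kept: list[DomainHit] = []
    for h in ranked:
        if not any(_conflicts(h, k, min_frac) for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: (h.query_start, h.query_end, h.accession))


def build_architecture(
    protein_id: str, hits: Sequence[DomainHit]
) -> Architecture:
    """Assemble the ordered, deterministic architecture of one protein.

    The signature is the '+'-joined canonical accession list in query order;
    proteins with two or more DNA-binding-domain hits are multi-DBD (the
    distinct count separates repeated identical DBDs from mixed ones).
    """
    ordered = tuple(
        sorted(hits, key=lambda h: (h.query_start, h.query_end, h.accession))
    )
    dbd_hits = [h for h in ordered if h.role == "DBD"]
    return Architecture(
        protein_id=protein_id,
        hits=ordered,
        signature="+".join(h.accession for h in ordered),
        dbd_count=len(dbd_hits),
        distinct_dbd_count=len({h.accession for h in dbd_hits}),
    )


def architectures_from_hits(
    raw_hits: Iterable[RawHit],
    registry: DomainRoleRegistry,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    *,
    keep_overlaps: bool = False,
) -> list[Architecture]:
    """filter → resolve → architecture for a whole hit table, sorted by id."""
    per_protein: dict[str, list[DomainHit]] = {}
    for h in filter_hits(raw_hits, registry, evalue_cutoff, min_coverage):
        per_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for pid in sorted(per_protein):
        resolved = resolve_overlaps(per_protein[pid], keep_overlaps=keep_overlaps)
        if resolved:
            out.append(build_architecture(pid, resolved))
    return out
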