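"""Gene-neighbourhood analysis around classified regulator genes.

Regulator genes tend to sit next to the genes they control, and next to the
partners that control them (histidine kinases beside response regulators,
anti-sigma factors beside sigma factors).  The neighbourhood of a TF gene is
built by walking outward in both directions, chaining consecutive genes while
each intergenic gap stays within a distance window (500 bp by default) — an
operon-like block that approximates the putative regulation region.
Neighbours are tagged with their COG functional category when provided,
their pseudogene status, and whether they are themselves classified TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._util import ProktfError
from .orfeome import GeneFeature, Replicon

__all__ = ["NeighbourGene", "NeighbourhoodContext", "neighbourhood", "context_table"]

DEFAULT_WINDOW = 500
DEFAULT_MAX_NEIGHBOURS = 10


@dataclass(frozen=True)
class NeighbourGene:
    locus_tag: str
    strand: str
    gap_bp: int  # distance to the previous gene in the chain, floored at 0
    cog_category: str | None = None
    is_pseudogene: bool = False
    is_tf: bool = False


@dataclass(frozen=True)
class NeighbourhoodContext:
    tf_locus: str
    upstream: tuple[NeighbourGene, ...]  # increasing distance, lower coords
    downstream: tuple[NeighbourGene, ...]  # increasing distance, higher coords
    block_span: tuple[int, int]


def _gap(left: GeneFeature, right: GeneFeature) -> int:
    """Intergenic distance on forward coordinates; overlaps floor at 0."""
    return max(0, right.start - left.end - 1)


def _as_neighbour(
    f: GeneFeature,
    gap: int,
    cogs: Mapping[str, str] | None,
    tf_loci: frozenset[str],
) -> NeighbourGene:
    cog = None
    if cogs:
        cog = cogs.get(f.locus_tag) or (cogs.get(f.product_id) if f.product_id else None)
    return NeighbourGene(
        locus_tag=f.locus_tag,
        strand=f.strand,
        gap_bp=gap,
        cog_category=cog,
        is_pseudogene=f.kind == "pseudogene",
        is_tf=f.locus_tag in tf_loci,
    )


def neighbourhood(
    tf: GeneFeature | str,
    features: Sequence[GeneFeature],
    cogs: Mapping[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
    *,
    tf_loci: frozenset[str] | set[str] = frozenset(),
    max_neighbours: int = DEFAULT_MAX_NEIGHBOURS,
    same_strand: bool = False,
    replicon_length: int | None = None,
    circular: bool = False,
) -> NeighbourhoodContext:
    """Chain the genes around one TF while each gap stays within ``window``.

    The walk is transitive: each next gene is admitted while its gap to the
    previous gene in the chain is at most ``window`` (inclusive), up to
    ``max_neighbours`` per side.  With ``same_strand`` a strand switch also
    breaks the chain.  On a circular replicon the walk wraps across the
    origin (requires ``replicon_length``).
    """
    if window < 0:
        raise ProktfError("window must be >= 0")
    ordered = sorted(features, key=lambda f: (f.start, f.end, f.locus_tag))
    tag = tf.locus_tag if isinstance(tf, GeneFeature) else tf
    idx = next((i for i, f in enumerate(ordered) if f.locus_tag == tag), None)
    if idx is None:
        raise ProktfError(f"TF locus {tag!r} not found among features")
    focus = ordered[idx]
    tf_loci = frozenset(tf_loci)
    n = len(ordered)

    def walk(direction: int) -> list[NeighbourGene]:
        chain: list[NeighbourGene] = []
        prev = focus
        i = idx
        steps = 0
        while steps < max_neighbours:
            j = i + direction
            if circular and replicon_length is not None:
                j %= n
                if j == idx:
                    break
            elif not 0 <= j < n:
                break
            nxt = ordered[j]
            if direction > 0:
                gap = _gap(prev, nxt)
                if circular and replicon_length is not None and j < i:
                    gap = max(0, (replicon_length - prev.end) + nxt.start - 1)
            else:
                gap = _gap(nxt, prev)
                if circular and replicon_length is not None and j > i:
                    gap = max(0, (replicon_length - nxt.end) + prev.start - 1)
            if gap > window:
                break
            if same_strand and nxt.strand != prev.strand:
                break
            chain.append(_as_neighbour(nxt, gap, cogs, tf_loci))
            prev, i = nxt, j
            steps += 1
        return chain

    down = walk(+1)
    up = walk(-1)
    span_start = min([focus.start] + [f.start for f in ordered if f.locus_tag in {g.locus_tag for g in up + down}])
    span_end = max([focus.end] + [f.end for f in ordered if f.locus_tag in {g.locus_tag for g in up + down}])
    return NeighbourhoodContext(
        tf_locus=focus.locus_tag,
        upstream=tuple(up),
        downstream=tuple(down),
        block_span=(span_start, span_end),
    )


def _serialise(chain: Sequence[NeighbourGene]) -> str:
    return ";".join(
        f"{g.locus_tag}({g.strand},gap={g.gap_bp},cog={g.cog_category or '-'}"
        f"{',pseudo' if g.is_pseudogene else ''}{',tf' if g.is_tf else ''})"
        for g in chain
    )


def context_table(
    tf_records: Sequence,
    replicon: Replicon,
    cogs: Mapping[str, str] | None = None,
    window: int = DEFAULT_WINDOW,
    **kwargs,
) -> pd.DataFrame:
    """One row of serialised neighbourhood per annotated TF record.

    Records without a locus tag on this replicon (e.g. ORFeome recoveries)
    are skipped — they have no annotated neighbours to report.
    """
    feats = list(replicon.features)
    known = {f.locus_tag for f in feats}
    tf_loci = frozenset(
        r.locus_tag for r in tf_records if r.locus_tag and r.locus_tag in known
    )
    rows = []
    for rec in tf_records:
        if not rec.locus_tag or rec.locus_tag not in known:
            continue
        ctx = neighbourhood(
            rec.locus_tag,
            feats,
            cogs=cogs,
            window=window,
            tf_loci=tf_loci,
            replicon_length=len(replicon),
            circular=replicon.topology == "circular",
            **kwargs,
        )
        neighbours = ctx.upstream + ctx.downstream
        rows.append(
            {
                "tf_locus": ctx.tf_locus,
                "category": rec.category,
                "family": rec.family if rec.family is not None else "",
                "n_upstream": len(ctx.upstream),
                "n_downstream": len(ctx.downstream),
                "upstream": _serialise(ctx.upstream),
                "downstream": _serialise(ctx.downstream),
                "has_pseudogene_neighbour": any(g.is_pseudogene for g in neighbours),
                "has_tf_neighbour": any(g.is_tf for g in neighbours),
                "block_start": ctx.block_span[0],
                "block_end": ctx.block_span[1],
            }
        )
    cols = [
        "tf_locus",
        "category",
        "family",
        "n_upstream",
        "n_downstream",
        "upstream",
        "downstream",
        "has_pseudogene_neighbour",
        "has_tf_neighbour",
        "block_start",
        "block_end",
    ]
    return pd.DataFrame(rows, columns=cols)
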