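"""Hierarchical classification of DNA-binding proteins.

The scheme is architecture-driven and proceeds in three steps:

1. *Gate*: a protein enters the analysis only if it carries a domain the
   registry knows as DNA-binding — a transcription-factor DBD, a sigma-factor
   region, or a non-regulatory DNA-binding marker.
2. *TF vs ODP*: proteins whose only DNA-binding evidence is a non-regulatory
   marker (transposase, integrase, histone-like) are Other DNA-binding
   Proteins; any TF-qualifying DBD wins over such markers.
3. *Category*, in configurable precedence (default RR > SF > OCS > TR):
   a receiver (phosphoacceptor) domain makes a response regulator; the sigma
   rules type sigma factors as RpoN (sigma-54 DNA-binding + core-binding),
   RpoD (sigma-70 regions 2+3+4) or ECF (regions 2+4 without 3); a sensory
   input domain alongside a DBD, with no phosphotransfer domain, makes a
   one-component system; everything else is a transcriptional regulator,
   the residual category.

Families are then assigned from the DBD with the lowest E-value, with two
data-driven refinements: any DBD accompanied by a Peptidase_S24 autoprotease
domain is a LexA-family repressor whatever the DBD, and the near-identical
HTH_XRE and HTH_3 domains share the single family Xre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._util import ProktfError
from .domain_scan import Architecture
from .registry import DNA_BINDING_ROLES, DomainRoleRegistry

__all__ = [
    "TFRecord",
    "is_dbd_protein",
    "split_tf_odp",
    "classify_category",
    "assign_family",
    "classify_all",
]

CATEGORIES = ("TR", "OCS", "RR", "SF")
SF_SUBFAMILIES = ("RpoN", "RpoD", "ECF")


@dataclass
class TFRecord:
    """One classified DNA-binding protein."""

    protein_id: str
    architecture: Architecture
    dbd_or_odp: str  # TF | ODP
    category: str = "none"  # TR | OCS | RR | SF | none
    sf_subfamily: str = "none"  # RpoN | RpoD | ECF | none
    family: str | None = None
    mispredicted: bool = False
    provenance: str = "annotated"  # annotated | orfeome
    locus_tag: str | None = None
    aa_sequence: str | None = None
    nt_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.dbd_or_odp == "ODP" and self.category != "none":
            raise ProktfError(f"{self.protein_id}: ODP cannot carry a TF category")
        if (self.category == "SF") != (self.sf_subfamily != "none"):
            raise ProktfError(
                f"{self.protein_id}: sf_subfamily set iff category is SF"
            )


def is_dbd_protein(arch: Architecture, registry: DomainRoleRegistry) -> bool:
    """Does any hit qualify the protein as a DNA binder?"""
    return any(h.role in DNA_BINDING_ROLES for h in arch.hits)


def split_tf_odp(arch: Architecture, registry: DomainRoleRegistry) -> str:
    """ODP when the DNA-binding evidence is exclusively non-regulatory markers."""
    roles = arch.roles()
    if roles & {"DBD", "sigma_region"}:
        return "TF"
    if "odp_marker" in roles:
        return "ODP"
    raise ProktfError(f"{arch.protein_id}: not a DNA-binding protein")


def _rule_rr(arch: Architecture, registry: DomainRoleRegistry):
    if "receiver" in arch.roles():
        return "RR", "none"
    return None


def _rule_sf(arch: Architecture, registry: DomainRoleRegistry):
    tags = {registry.sigma_tag(h.accession) for h in arch.hits} - {None}
    if {"s54_dbd", "s54_core"} <= tags:
        return "SF", "RpoN"
    if {"r2", "r4"} <= tags:
        return "SF", ("RpoD" if "r3" in tags else "ECF")
    return None


def _rule_ocs(arch: Architecture, registry: DomainRoleRegistry):
    roles = arch.roles()
    if "input" in roles and "DBD" in roles and "phosphotransfer" not in roles:
        return "OCS", "none"
    return None


_CATEGORY_RULES = {"RR": _rule_rr, "SF": _rule_sf, "OCS": _rule_ocs}


def classify_category(
    arch: Architecture, registry: DomainRoleRegistry
) -> tuple[str, str]:
    """Assign (category, sf_subfamily) to a TF.

    Rules fire in the registry's precedence order; TR is the total residual,
    so every TF receives exactly one category.  A phosphotransfer domain next
    to input+DBD denies the one-component call (that architecture is the
    kinase side of a two-component system) and the protein falls through
    to TR.
    """
    for cat in registry.precedence:
        rule = _CATEGORY_RULES.get(cat)
        if rule is None:
            continue
        res = rule(arch, registry)
        if res is not None:
            return res
    return "TR", "none"


def assign_family(
    arch: Architecture, category: str, registry: DomainRoleRegistry
) -> str:
    """Family of a TR/OCS/RR protein (sigma factors are their subfamily).

    Override rules run first: a protein with any DBD plus all partner domains
    of an override takes that family regardless of E-values (LexA).  Otherwise
    the DBD hit with the lowest E-value (ties: bitscore, then accession)
    selects the family whose rule lists its subtype; proteins whose best DBD
    matches no rule are counted as ``unclassified`` rather than rejected.
    """
    present = {h.accession for h in arch.hits}
    dbd_hits = [h for h in arch.hits if h.role == "DBD"]
    if dbd_hits:
        for rule in registry.override_rules():
            if rule.required_partners <= present:
                return rule.family_name
    if not dbd_hits:
        return "unclassified"
    best = min(dbd_hits, key=lambda h: (h.evalue, -h.bitscore, h.accession))
    subtype = registry.dbd_subtype(best.accession)
    if subtype is None:
        return "unclassified"
    for rule in registry.family_rules_for_subtype(subtype):
        if rule.required_partners <= present:
            return rule.family_name
    return "unclassified"


def classify_all(
    architectures: Iterable[Architecture],
    registry: DomainRoleRegistry,
    *,
    provenance: str = "annotated",
    mispredicted: bool = False,
) -> list[TFRecord]:
    """Classify every DNA-binding protein; non-DBD architectures are dropped.

    Output is deterministic: one record per qualifying protein, sorted by
    protein id.
    """
    registry.validate()
    records: list[TFRecord] = []
    for arch in sorted(architectures, key=lambda a: a.protein_id):
        if not is_dbd_protein(arch, registry):
            continue
        kind = split_tf_odp(arch, registry)
        if kind == "ODP":
            records.append(
                TFRecord(
                    protein_id=arch.protein_id,
                    architecture=arch,
                    dbd_or_odp="ODP",
                    family=None,
                    mispredicted=mispredicted,
                    provenance=provenance,
                )
            )
            continue
        category, sf_sub = classify_category(arch, registry)
        if category == "SF":
            family = sf_sub
        else:
            family = assign_family(arch, category, registry)
        records.append(
            TFRecord(
                protein_id=arch.protein_id,
                architecture=arch,
                dbd_or_odp="TF",
                category=category,
                sf_subfamily=sf_sub,
                family=family,
                mispredicted=mispredicted,
                provenance=provenance,
            )
        )
    return records
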