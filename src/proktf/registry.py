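"""Domain role registry: which profile accessions mean what.

The classification scheme is entirely data-driven.  A registry file maps
profile accessions (Pfam/SMART style names) to functional roles — DNA-binding
domain, sensory input, receiver, phosphotransfer, sigma-factor region,
non-regulatory DNA-binding marker — and carries the family-definition rules
plus an accession alias table (CDD PSSM ids, versioned Pfam accessions, …).
Editing the YAML file extends the scheme without touching code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from ._util import ProktfError

__all__ = ["ROLES", "FamilyRule", "DomainRoleRegistry", "load_default_registry"]

ROLES = frozenset(
    {
        "DBD",
        "input",
        "output",
        "receiver",
        "phosphotransfer",
        "sigma_region",
        "odp_marker",
        "other",
    }
)

#: Roles whose presence admits a protein into the DNA-binding pool.
DNA_BINDING_ROLES = frozenset({"DBD", "sigma_region", "odp_marker"})

_VERSION_RE = re.compile(r"\.\d+$")


@dataclass(frozen=True)
class FamilyRule:
    """One architecture-defined family.

    ``required_dbd`` is an any-of set of DBD subtypes; ``required_partners``
    an all-of set of accessions.  A rule with no DBD requirement but with
    partners is an override: any DBD plus the partners places the protein in
    the family (the LexA / Peptidase_S24 case).
    """

    family_name: str
    required_dbd: frozenset[str] = frozenset()
    required_partners: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.required_dbd and not self.required_partners:
            raise ProktfError(f"family {self.family_name}: empty rule")


@dataclass
class DomainRoleRegistry:
    """Validated role/family rule set driving classification."""

    roles: dict[str, str]  # canonical accession -> role
    dbd_subtypes: dict[str, str] = field(default_factory=dict)  # accession -> subtype
    sigma_tags: dict[str, str] = field(default_factory=dict)  # accession -> region tag
    families: list[FamilyRule] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)
    precedence: tuple[str, ...] = ("RR", "SF", "OCS", "TR")

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -------------------------------------------------------------

    def canonical(self, accession: str) -> str:
        """Resolve an accession through the alias table (case/version lax)."""
        for cand in (accession, _VERSION_RE.sub("", accession)):
            if cand in self.aliases:
                return self.aliases[cand]
            if cand in self.roles:
                return cand
            low = cand.lower()
            if low in self._aliases_low:
                return self._aliases_low[low]
            if low in self._roles_low:
                return self._roles_low[low]
        return accession

    def role(self, accession: str) -> str:
        return self.roles.get(self.canonical(accession), "other")

    def dbd_subtype(self, accession: str) -> str | None:
        return self.dbd_subtypes.get(self.canonical(accession))

    def sigma_tag(self, accession: str) -> str | None:
        return self.sigma_tags.get(self.canonical(accession))

    def family_rules_for_subtype(self, subtype: str) -> list[FamilyRule]:
        return sorted(
            (r for r in self.families if subtype in r.required_dbd),
            key=lambda r: (-r.priority, r.family_name),
        )

    def override_rules(self) -> list[FamilyRule]:
        return sorted(
            (r for r in self.families if not r.required_dbd and r.required_partners),
            key=lambda r: (-r.priority, r.family_name),
        )

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        bad = {a: r for a, r in self.roles.items() if r not in ROLES}
        if bad:
            raise ProktfError(f"unknown roles: {bad}")
        for acc in self.dbd_subtypes:
            if acc not in self.roles:
                raise ProktfError(f"dbd_subtype for unregistered accession {acc}")
        known_subtypes = set(self.dbd_subtypes.values())
        for rule in self.families:
            missing = rule.required_dbd - known_subtypes
            if missing:
                raise ProktfError(
                    f"family {rule.family_name}: unknown DBD subtypes {sorted(missing)}"
                )
            for acc in rule.required_partners:
                if acc not in self.roles:
                    raise ProktfError(
                        f"family {rule.family_name}: unregistered partner {acc}"
                    )
        # family names are unique among subtype rules; an override rule (no
        # DBD requirement) may share its name with the subtype rule it extends
        names = [r.family_name for r in self.families if r.required_dbd]
        if len(names) != len(set(names)):
            raise ProktfError("duplicate family names in registry")
        onames = [r.family_name for r in self.families if not r.required_dbd]
        if len(onames) != len(set(onames)):
            raise ProktfError("duplicate override rules in registry")
        if set(self.precedence) != {"RR", "SF", "OCS", "TR"}:
            raise ProktfError("precedence must order RR, SF, OCS, TR")
        self._aliases_low = {a.lower(): t for a, t in self.aliases.items()}
        self._roles_low = {a.lower(): a for a in self.roles}

    # -- (de)serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "DomainRoleRegistry":
        roles: dict[str, str] = {}
        subtypes: dict[str, str] = {}
        sigma: dict[str, str] = {}
        for acc, spec in (data.get("roles") or {}).items():
            if isinstance(spec, str):
                spec = {"role": spec}
            roles[acc] = spec["role"]
            if "dbd_subtype" in spec:
                subtypes[acc] = spec["dbd_subtype"]
            if "sigma" in spec:
                sigma[acc] = spec["sigma"]
        families = [
            FamilyRule(
                family_name=f["name"],
                required_dbd=frozenset(f.get("dbd") or ()),
                required_partners=frozenset(f.get("partners") or ()),
                priority=int(f.get("priority", 0)),
            )
            for f in data.get("families") or []
        ]
        return cls(
            roles=roles,
            dbd_subtypes=subtypes,
            sigma_tags=sigma,
            families=families,
            aliases=dict(data.get("aliases") or {}),
            precedence=tuple(data.get("precedence") or ("RR", "SF", "OCS", "TR")),
        )

    def to_dict(self) -> dict:
        roles: dict[str, dict] = {}
        for acc, role in self.roles.items():
            spec: dict = {"role": role}
            if acc in self.dbd_subtypes:
                spec["dbd_subtype"] = self.dbd_subtypes[acc]
            if acc in self.sigma_tags:
                spec["sigma"] = self.sigma_tags[acc]
            roles[acc] = spec
        return {
            "precedence": list(self.precedence),
            "roles": roles,
            "aliases": dict(self.aliases),
            "families": [
                {
                    "name": r.family_name,
                    "dbd": sorted(r.required_dbd),
                    "partners": sorted(r.required_partners),
                    "priority": r.priority,
                }
                for r in self.families
            ],
        }

    @classmethod
    def load(cls, path: str | Path) -> "DomainRoleRegistry":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ProktfError(f"registry file {path} is not a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_default_registry() -> DomainRoleRegistry:
    """The registry shipped with the package."""
    ref = resources.files("proktf").joinpath("data/registry.yaml")
    data = yaml.safe_load(ref.read_text())
    return DomainRoleRegistry.from_dict(data)
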