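"""TF/ODP split, category precedence and family assignment rules."""

from __future__ import annotations

import csv

import pytest

from proktf import (
    DomainRoleRegistry,
    assign_family,
    build_architecture,
    classify_all,
    classify_category,
    is_dbd_protein,
    split_tf_odp,
)

from conftest import DATA, make_domain_hit


def arch_of(registry, *specs):
    """Build an architecture from (accession, evalue) or accession specs."""
    hits = []
    pos = 1
    for spec in specs:
        acc, evalue = spec if isinstance(spec, tuple) else (spec, 1e-10)
        canon = registry.canonical(acc)
        hits.append(
            make_domain_hit(
                accession=canon,
                evalue=evalue,
                start=pos,
                end=pos + 50,
                role=registry.role(canon),
            )
        )
        pos += 70
    return build_architecture("P1", hits)


class TestDbdGate:
    def test_single_dbd_qualifies(self, registry):
        assert is_dbd_protein(arch_of(registry, "HTH_TetR"), registry)

    def test_enzymatic_domains_do_not_qualify(self, registry):
        assert not is_dbd_protein(arch_of(registry, "GGDEF", "EAL"), registry)

    def test_sigma_regions_qualify(self, registry):
        assert is_dbd_protein(arch_of(registry, "Sigma70_r2", "Sigma70_r4"), registry)

    def test_odp_marker_qualifies_for_inclusion(self, registry):
        assert is_dbd_protein(arch_of(registry, "Transposase_mut"), registry)


class TestTfOdpSplit:
    def test_transposase_is_odp(self, registry):
        assert split_tf_odp(arch_of(registry, "Transposase_mut"), registry) == "ODP"

    def test_canonical_regulator_is_tf(self, registry):
        arch = arch_of(registry, "HTH_LacI", "Periplasmic_binding")
        assert split_tf_odp(arch, registry) == "TF"

    def test_tf_qualifying_dbd_outranks_odp_marker(self, registry):
        arch = arch_of(registry, "Integrase_core", "HTH_Xre")
        assert split_tf_odp(arch, registry) == "TF"

    @pytest.mark.parametrize("marker", ["Transposase_mut", "Integrase_core", "HNS"])
    @pytest.mark.parametrize("dbd", ["HTH_TetR", "HTH_XRE", "Sigma70_r2"])
    def test_precedence_over_all_marker_dbd_pairs(self, registry, marker, dbd):
        assert split_tf_odp(arch_of(registry, marker, dbd), registry) == "TF"
        assert split_tf_odp(arch_of(registry, marker), registry) == "ODP"


class TestCategoryRules:
    def test_receiver_makes_response_regulator(self, registry):
        arch = arch_of(registry, "REC", "HTH_LuxR")
        assert classify_category(arch, registry) == ("RR", "none")

    def test_sigma70_region_rules(self, registry):
        ecf = arch_of(registry, "pfam4542", "pfam4545")
        assert classify_category(ecf, registry) == ("SF", "ECF")
        rpod = arch_of(registry, "pfam4542", "pfam4545", "pfam4539")
        assert classify_category(rpod, registry) == ("SF", "RpoD")

    def test_sigma54_rule(self, registry):
        arch = arch_of(registry, "pfam4552", "pfam4963")
        assert classify_category(arch, registry) == ("SF", "RpoN")

    def test_ocs_requires_absent_phosphotransfer(self, registry):
        ocs = arch_of(registry, "PAS", "HTH_AraC")
        assert classify_category(ocs, registry) == ("OCS", "none")
        kinase_like = arch_of(registry, "PAS", "HTH_AraC", "HisKA")
        assert classify_category(kinase_like, registry) == ("TR", "none")

    def test_lone_dbd_is_residual_tr(self, registry):
        assert classify_category(arch_of(registry, "HTH_TetR"), registry) == ("TR", "none")

    def test_receiver_outranks_sigma(self, registry):
        arch = arch_of(registry, "REC", "pfam4542", "pfam4545")
        assert classify_category(arch, registry) == ("RR", "none")

    def test_full_truth_table(self, registry):
        """The category call over the whole role-presence lattice matches the
        committed hand-derived table."""
        with open(DATA / "category_truth_table.tsv") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
        assert len(rows) == 64
        for row in rows:
            specs = ["HTH_TetR"]  # a TF-qualifying DBD is always present
            if int(row["receiver"]):
                specs.append("Response_reg")
            if int(row["s54_pair"]):
                specs += ["Sigma54_DBD", "Sigma54_CBD"]
            if int(row["r2r4"]):
                specs += ["Sigma70_r2", "Sigma70_r4"]
            if int(row["r3"]):
                specs.append("Sigma70_r3")
            if int(row["input"]):
                specs.append("PAS")
            if int(row["phosphotransfer"]):
                specs.append("HisKA")
            got = classify_category(arch_of(registry, *specs), registry)
            assert got == (row["category"], row["sf_subfamily"]), row


class TestFamilyAssignment:
    def test_merr_family_from_dbd(self, registry):
        arch = arch_of(registry, ("HTH_MerR", 1e-12), "B12-binding")
        assert assign_family(arch, "OCS", registry) == "MerR"

    def test_peptidase_s24_overrides_any_dbd(self, registry):
        xre = arch_of(registry, ("HTH_Xre", 1e-4), "Peptidase_S24")
        assert assign_family(xre, "OCS", registry) == "LexA"
        lexa = arch_of(registry, "LexA_DNA_bin", "Peptidase_S24")
        assert assign_family(lexa, "OCS", registry) == "LexA"

    def test_lexa_dbd_alone_still_lexa(self, registry):
        arch = arch_of(registry, "LexA_DNA_bin")
        assert assign_family(arch, "TR", registry) == "LexA"

    def test_lowest_evalue_dbd_chooses_family(self, registry):
        arch = arch_of(registry, ("HTH_AraC", 1e-20), ("HTH_IclR", 1e-6))
        assert assign_family(arch, "TR", registry) == "AraC"
        flipped = arch_of(registry, ("HTH_AraC", 1e-6), ("HTH_IclR", 1e-20))
        assert assign_family(flipped, "TR", registry) == "IclR"

    def test_hth3_and_hthxre_merge_into_xre(self, registry):
        assert assign_family(arch_of(registry, ("HTH_3", 1e-8)), "TR", registry) == "Xre"
        assert assign_family(arch_of(registry, "HTH_XRE"), "TR", registry) == "Xre"

    def test_unknown_dbd_degrades_to_unclassified(self, registry):
        reg2 = DomainRoleRegistry.from_dict(
            {
                "roles": {"NovelHTH": {"role": "DBD", "dbd_subtype": "NovelHTH"}},
                "families": [],
            }
        )
        arch = arch_of(reg2, "NovelHTH")
        assert assign_family(arch, "TR", reg2) == "unclassified"

    def test_peptidase_override_applies_to_every_registered_dbd(self, registry):
        for acc, role in registry.roles.items():
            if role != "DBD":
                continue
            arch = arch_of(registry, (acc, 1e-15), "Peptidase_S24")
            assert assign_family(arch, "TR", registry) == "LexA", acc


class TestClassifyAll:
    def test_mixed_fixture_proteome(self, registry):
        archs = {
            "p01": ["Transposase_mut"],
            "p02": ["REC", "HTH_LuxR"],
            "p03": ["Sigma70_r2", "Sigma70_r4"],
            "p04": ["HTH_MerR", "B12-binding"],
            "p05": ["HTH_TetR"],
            "p06": ["HTH_XRE"],
            "p07": ["GGDEF", "EAL"],  # no DBD: absent from output
            "p08": [],
        }
        built = []
        for pid, accs in archs.items():
            a = arch_of(registry, *accs)
            built.append(
                build_architecture(pid, [h for h in a.hits])
            )
        records = classify_all(built, registry)
        got = {
            r.protein_id: (r.dbd_or_odp, r.category, r.family) for r in records
        }
        assert got == {
            "p01": ("ODP", "none", None),
            "p02": ("TF", "RR", "LuxR"),
            "p03": ("TF", "SF", "ECF"),
            "p04": ("TF", "OCS", "MerR"),
            "p05": ("TF", "TR", "TetR"),
            "p06": ("TF", "TR", "Xre"),
        }

    def test_empty_and_order_independent(self, registry):
        assert classify_all([], registry) == []
        archs = [
            arch_of(registry, "HTH_TetR"),
            arch_of(registry, "Transposase_mut"),
        ]
        a = classify_all(archs, registry)
        b = classify_all(list(reversed(archs)), registry)
        assert [r.protein_id for r in a] == [r.protein_id for r in b]

    def test_sf_records_have_subfamily_as_family(self, registry):
        arch = arch_of(registry, "Sigma70_r2", "Sigma70_r3", "Sigma70_r4")
        (rec,) = classify_all([arch], registry)
        assert rec.category == "SF" and rec.sf_subfamily == "RpoD" and rec.family == "RpoD"

    def test_registry_round_trip_preserves_classification(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.save(path)
        reloaded = DomainRoleRegistry.load(path)
        fixtures = [
            ["HTH_MerR", "B12-binding"],
            ["REC", "Trans_reg_C"],
            ["Sigma54_DBD", "Sigma54_CBD"],
            ["HTH_Xre", "Peptidase_S24"],
            ["Transposase_mut"],
        ]
        for accs in fixtures:
            a1 = arch_of(registry, *accs)
            a2 = arch_of(reloaded, *accs)
            r1 = classify_all([a1], registry)
            r2 = classify_all([a2], reloaded)
            assert [(r.dbd_or_odp, r.category, r.sf_subfamily, r.family) for r in r1] == [
                (r.dbd_or_odp, r.category, r.sf_subfamily, r.family) for r in r2
            ]
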