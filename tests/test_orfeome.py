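"""Six-frame ORF enumeration, ORFeome assembly and mispredicted-gene calls."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proktf import (
    GeneFeature,
    ProktfError,
    Replicon,
    build_orfeome,
    find_mispredicted,
    scan_orfs,
)
from proktf._util import revcomp, translate_bacterial
from proktf.orfeome import OrfRecord, make_orf_id

from conftest import random_dna
from oracles import brute_force_orfs, orf_key


class TestScanOrfs:
    def test_minimal_forward_orf(self):
        rep = Replicon(id="r", sequence="ATGAAATAA")
        (orf,) = scan_orfs(rep, min_aa_length=2, start_codons={"ATG"})
        assert (orf.start, orf.end, orf.strand) == (1, 9, "+")
        assert orf.translation == "MK"
        assert orf.nt_length == 9

    def test_reverse_strand_orf_has_forward_coordinates(self):
        rep = Replicon(id="r", sequence=revcomp("ATGAAATAA"))
        (orf,) = scan_orfs(rep, min_aa_length=2, start_codons={"ATG"})
        assert (orf.start, orf.end, orf.strand) == (1, 9, "-")
        assert orf.translation == "MK"

    def test_no_start_codon_yields_nothing(self):
        rep = Replicon(id="r", sequence="AAATTTCCC")
        assert scan_orfs(rep, min_aa_length=1) == []

    def test_alternative_start_translates_as_methionine(self):
        rep = Replicon(id="r", sequence="GTGAAATAA")
        (orf,) = scan_orfs(rep, min_aa_length=2)
        assert orf.translation == "MK"

    def test_longest_orf_per_stop_by_default(self):
        # two in-frame starts share one stop: only the earlier start reported
        rep = Replicon(id="r", sequence="ATGCCCATGAAATAA")
        orfs = scan_orfs(rep, min_aa_length=2, start_codons={"ATG"})
        forward = [o for o in orfs if o.strand == "+"]
        assert len(forward) == 1 and forward[0].start == 1
        nested = scan_orfs(rep, min_aa_length=2, start_codons={"ATG"}, all_starts=True)
        assert {o.start for o in nested if o.strand == "+"} == {1, 7}

    def test_n_codons_never_start_or_stop_and_translate_as_x(self):
        rep = Replicon(id="r", sequence="ATGAANTTTTAA")
        (orf,) = scan_orfs(rep, min_aa_length=2, start_codons={"ATG"})
        assert orf.translation == "MXF"

    def test_invalid_characters_rejected(self):
        with pytest.raises(ProktfError, match="non-alphabet"):
            Replicon(id="r", sequence="ATGRAATAA")

    def test_invalid_start_codon_set_rejected(self):
        rep = Replicon(id="r", sequence="ATGAAATAA")
        with pytest.raises(ProktfError):
            scan_orfs(rep, 2, start_codons={"AAA"})
        with pytest.raises(ProktfError):
            scan_orfs(rep, 2, start_codons=set())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_random_sequence(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 10_000, gc=float(rng.uniform(0.25, 0.75)))
        rep = Replicon(id="r", sequence=seq)
        got = orf_key(scan_orfs(rep, min_aa_length=20))
        want = brute_force_orfs(seq, 20, {"ATG", "GTG", "TTG"})
        assert got == want

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(300, 3000))
    def test_strand_symmetry(self, seed, length):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, length)
        fwd = scan_orfs(Replicon(id="r", sequence=seq), min_aa_length=15)
        rev = scan_orfs(Replicon(id="r", sequence=revcomp(seq)), min_aa_length=15)
        L = len(seq)
        mirrored = {
            (L - o.end + 1, L - o.start + 1, "-" if o.strand == "+" else "+", o.translation)
            for o in fwd
        }
        assert orf_key(rev) == mirrored

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_translations_rederivable_from_slice(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 2000)
        rep = Replicon(id="r", sequence=seq)
        for o in scan_orfs(rep, min_aa_length=10):
            nt = seq[o.start - 1 : o.end]
            if o.strand == "-":
                nt = revcomp(nt)
            assert translate_bacterial(nt) == o.translation


class TestCircular:
    def test_origin_spanning_orf_recovered_once_with_wrap_flag(self):
        core = "ATG" + "GAA" * 30 + "TAA"  # 96 nt ORF
        # place so that the ORF crosses the origin: last 40 nt at the end
        seq = core[40:] + ("C" * 61) + core[:40]
        rep = Replicon(id="c", sequence=seq, topology="circular")
        orfs = [o for o in build_orfeome(rep, min_aa_length=20) if o.wraps_origin]
        assert len(orfs) == 1
        (o,) = orfs
        assert o.start == len(seq) - 40 + 1 and o.end == len(core) - 40
        assert o.nt_length == len(core)
        assert o.translation == "M" + "E" * 30

    def test_linear_topology_does_not_wrap(self):
        core = "ATG" + "GAA" * 30 + "TAA"
        seq = core[40:] + ("C" * 61) + core[:40]
        rep = Replicon(id="c", sequence=seq, topology="linear")
        assert all(not o.wraps_origin for o in build_orfeome(rep, min_aa_length=20))

    def test_circular_scan_agrees_with_linear_away_from_origin(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 5000)
        lin = orf_key(scan_orfs(Replicon(id="r", sequence=seq), min_aa_length=20))
        circ = scan_orfs(
            Replicon(id="r", sequence=seq, topology="circular"), min_aa_length=20
        )
        assert lin <= orf_key(circ)


class TestBuildOrfeome:
    def test_two_planted_orfs_in_coordinate_order(self):
        gene = "ATG" + "GCT" * 25 + "TAA"
        seq = "TAATTT" + gene + "TCTCTACTATTCTAA" + gene + "CCCTTT"
        rep = Replicon(id="r", sequence=seq)
        orfs = build_orfeome(rep, min_aa_length=20)
        planted = [o for o in orfs if o.translation == "M" + "A" * 25]
        assert len(planted) == 2
        assert planted[0].start < planted[1].start
        starts = [(o.start, o.end, o.strand) for o in orfs]
        assert starts == sorted(starts)

    def test_deterministic_and_provenance(self):
        rng = np.random.default_rng(11)
        seq = random_dna(rng, 4000)
        rep = Replicon(id="r", sequence=seq)
        a = build_orfeome(rep, min_aa_length=30)
        b = build_orfeome(rep, min_aa_length=30)
        assert a == b
        assert all(o.provenance == "orfeome" for o in a)


class TestFindMispredicted:
    def _orf(self, start, end, strand="+"):
        return OrfRecord(
            orf_id=make_orf_id("r", start, end, strand),
            replicon_id="r",
            start=start,
            end=end,
            strand=strand,
            frame=1,
            nt_length=end - start + 1,
            translation="M" * ((end - start + 1) // 3 - 1),
        )

    def test_identical_annotated_cds_excluded(self):
        orf = self._orf(1000, 1600)
        feats = [GeneFeature("g1", 1000, 1600, "+", "CDS")]
        assert find_mispredicted([orf], feats) == []

    def test_distant_orf_retained_and_flagged(self):
        orf = self._orf(5000, 5600)
        feats = [GeneFeature("g1", 3000, 4000, "+", "CDS")]
        (kept,) = find_mispredicted([orf], feats)
        assert kept.mispredicted is True

    def test_pseudogene_overlap_excluded_any_strand(self):
        orf = self._orf(1000, 1600, strand="+")
        feats = [GeneFeature("ps", 1500, 2200, "-", "pseudogene")]
        assert find_mispredicted([orf], feats) == []

    def test_opposite_strand_cds_does_not_exclude(self):
        orf = self._orf(1000, 1600, strand="+")
        feats = [GeneFeature("g1", 1000, 1600, "-", "CDS")]
        (kept,) = find_mispredicted([orf], feats)
        assert kept.mispredicted

    def test_overlap_threshold_is_fraction_of_orf_length(self):
        orf = self._orf(1000, 1599)  # 600 nt
        # 59 bp overlap < 10%: retained; 61 bp > 10%: excluded
        assert find_mispredicted([orf], [GeneFeature("a", 1541, 2000, "+", "CDS")])
        assert not find_mispredicted([orf], [GeneFeature("a", 1539, 2000, "+", "CDS")])

    def test_empty_feature_list_warns_and_returns_all(self):
        orf = self._orf(10, 300)
        with pytest.warns(UserWarning):
            kept = find_mispredicted([orf], [])
        assert len(kept) == 1

    def test_retained_records_overlap_no_same_strand_cds(self):
        rng = np.random.default_rng(3)
        orfs = [
            self._orf(int(s), int(s) + 299, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(1, 20_000, size=40)
        ]
        feats = [
            GeneFeature(f"g{i}", int(s), int(s) + 499, "+" if rng.random() < 0.5 else "-")
            for i, s in enumerate(rng.integers(1, 20_000, size=30))
        ]
        for kept in find_mispredicted(orfs, feats, 0.1):
            for f in feats:
                if f.strand != kept.strand:
                    continue
                ov = max(0, min(kept.end, f.end) - max(kept.start, f.start) + 1)
                assert ov <= 0.1 * kept.nt_length
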