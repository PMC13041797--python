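"""Preset catalog, Aβ42 threading, facing parity, pleat and mass accounting."""

import collections

import pytest

from conbarrel.geometry import derive_geometry
from conbarrel.topology import (AB42_SEQUENCE, SegmentScheme, catalog,
                                get_preset, glycine_pleat_check,
                                monomer_mass, peptides_for_mass, thread)


class TestSegmentScheme:
    def test_default_partition(self):
        s = SegmentScheme()
        assert (s.s1a, s.s1b, s.s2, s.s3) == (
            (1, 7), (8, 14), (15, 27), (28, 42))
        assert len(s.sequence) == 42
        assert s.sequence[0] == "D" and s.sequence[-1] == "A"  # Asp1, Ala42

    def test_non_contiguous_ranges_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SegmentScheme(s1a=(1, 7), s1b=(9, 14))

    def test_non_canonical_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-canonical"):
            SegmentScheme(sequence="DAEFRHDX" + "G" * 34)


class TestCatalog:
    def test_unknown_preset_lists_valid_names(self):
        with pytest.raises(KeyError, match="soluble_hexamer_small"):
            get_preset("does_not_exist")

    def test_small_hexamer_barrels(self):
        p = get_preset("soluble_hexamer_small")
        inner, outer = p.barrel("inner_S3").spec, p.barrel("outer_S1S2").spec
        assert (inner.n_strands, inner.shear) == (6, 6)
        assert (outer.n_strands, outer.shear) == (12, 18)  # S/N = 1.5

    def test_large_hexamer_outer_s_over_n_is_two(self):
        p = get_preset("soluble_hexamer_large")
        outer = p.barrel("outer_S1S2").spec
        assert outer.shear / outer.n_strands == 2.0
        assert p.barrel("inner_S3").spec.shear == 12

    def test_small_24mer_channel_s3_tilt(self):
        spec = get_preset("channel_24_1con1").barrel("inner_S3").spec
        assert round(derive_geometry(spec).tilt) == 36

    def test_plugged_48_composition(self):
        p = get_preset("plugged_48")
        assert p.subunit_count == 48
        assert p.barrel("inner_S3").spec.n_strands == 36   # channel wall
        assert p.barrel("plug_inner_S3").spec.n_strands == 12  # dodecamer plug

    def test_subunit_counts_multiple_of_six_except_octamer_family(self):
        for p in catalog():
            if p.name in ("soluble_octamer", "soluble_hexadecamer"):
                assert p.subunit_count in (8, 16)
            else:
                assert p.subunit_count % 6 == 0

    def test_channel_sizes_present_in_both_families(self):
        names = {p.name for p in catalog()}
        for n in (12, 18, 24, 36):
            assert f"channel_{n}_1con1" in names
            assert f"channel_{n}_1con2" in names


class TestThreading:
    def test_small_24mer_secondary_structure_fractions(self):
        asg = thread(get_preset("channel_24_1con1"))
        fr = asg.fractions()
        assert fr["beta"] == 55
        assert fr["helix"] == 19
        assert sum(fr.values()) == 100

    def test_fractions_sum_to_100_everywhere(self, all_presets):
        for p in all_presets:
            assert sum(thread(p).fractions().values()) == 100

    def test_assignment_total_and_exclusive(self, all_presets):
        for p in all_presets:
            asg = thread(p)
            assert len(asg.records) == p.subunit_count * 42
            slots = collections.Counter(
                (r.component, r.strand, r.position)
                for r in asg.records
                if r.component and r.component != "helix_ring")
            assert all(v == 1 for v in slots.values()), p.name

    @pytest.mark.parametrize("name", [
        "channel_12_1con2", "channel_24_1con1", "channel_36_1con2"])
    def test_odd_s3_residues_face_inward(self, name):
        asg = thread(get_preset(name))
        for rec in asg.records:
            if rec.component == "inner_S3" and rec.residue % 2 == 1:
                assert rec.facing == "inward"

    def test_channel_pore_uses_s1_only_and_s3_transmembrane(self):
        for name in ("channel_12_1con2", "channel_24_1con1",
                     "channel_36_1con2"):
            asg = thread(get_preset(name))
            for rec in asg.records:
                if rec.component and rec.component.startswith("pore_"):
                    assert rec.residue <= 14, name       # S1 residues only
                if rec.component == "inner_S3":
                    assert rec.residue >= 28, name       # S3 residues only

    def test_strand_facing_alternates_with_residue_parity(self):
        asg = thread(get_preset("soluble_hexamer_small"))
        by_strand = collections.defaultdict(list)
        for rec in asg.records:
            if rec.component and rec.component != "helix_ring":
                by_strand[(rec.subunit, rec.component, rec.strand)].append(rec)
        for recs in by_strand.values():
            recs.sort(key=lambda r: r.residue)
            for a, b in zip(recs, recs[1:]):
                assert a.facing != b.facing


class TestGlycinePleat:
    def test_large_hexamer_glycines_share_a_pleat(self):
        ok, info = glycine_pleat_check(get_preset("soluble_hexamer_large"))
        assert ok
        assert max(info["axial_offsets_nm"].values()) <= info["threshold_nm"]

    def test_small_hexamer_glycines_do_not(self):
        ok, info = glycine_pleat_check(get_preset("soluble_hexamer_small"))
        assert not ok
        assert min(info["axial_offsets_nm"].values()) > info["threshold_nm"]

    def test_sn2_true_sn1_false_across_channels(self):
        assert glycine_pleat_check(get_preset("channel_12_1con2"))[0]
        assert not glycine_pleat_check(get_preset("channel_24_1con1"))[0]

    def test_preset_without_s3_reports_note(self):
        import dataclasses
        p = get_preset("soluble_hexamer_small")
        stripped = dataclasses.replace(
            p, barrels=tuple(b for b in p.barrels if b.role != "inner_S3"))
        ok, info = glycine_pleat_check(stripped)
        assert ok is False
        assert "no S3 barrel" in info["note"]


class TestMass:
    def test_ab42_average_mass(self):
        # sum of standard average residue masses - 41 waters: ~4514 Da
        assert monomer_mass() == pytest.approx(4514.0, abs=1.0)

    def test_single_glycine_is_free_amino_acid(self):
        scheme = SegmentScheme.__new__(SegmentScheme)  # bypass partition check
        object.__setattr__(scheme, "sequence", "G")
        assert monomer_mass(scheme) == pytest.approx(75.07, abs=0.01)

    def test_empty_sequence_rejected(self):
        scheme = SegmentScheme.__new__(SegmentScheme)
        object.__setattr__(scheme, "sequence", "")
        with pytest.raises(ValueError, match="empty"):
            monomer_mass(scheme)

    @pytest.mark.parametrize("kda,count", [(100, 22), (45, 10)])
    def test_trypsin_fragment_peptide_counts(self, kda, count):
        assert peptides_for_mass(kda) == count

    def test_one_monomer_mass_gives_one_peptide(self):
        assert peptides_for_mass(monomer_mass() / 1000.0) == 1

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            peptides_for_mass(0)
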