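"""Intergenic senseness, PBS context typing, densities, candidate selection."""

import numpy as np
import pytest

from afebox.context import (
    GeneAnnotation,
    classify_pbs,
    compute_intergenic,
    density_by_type,
    read_gff3,
    select_candidates,
    total_intergenic_bp,
    total_start_zone_bp,
    write_gff3,
)
from afebox.pbs import group_hits
from afebox.profiles import Hit


def G(gid, start, end, strand, contig="c"):
    return GeneAnnotation(gene_id=gid, contig=contig, start=start, end=end, strand=strand)


def P(start, end, contig="c", pid="PBS_0001"):
    (p,) = group_hits([Hit(contig, start, end, "C", "+", 10.0)])
    return p


class TestSenseness:
    def test_diverging_pair_is_sense(self):
        igs = compute_intergenic([G("g1", 100, 400, "-"), G("g2", 600, 900, "+")], 1000)
        mid = [r for r in igs if r.start == 400][0]
        assert mid.is_sense

    def test_converging_pair_is_not_sense(self):
        igs = compute_intergenic([G("g1", 100, 400, "+"), G("g2", 600, 900, "-")], 1000)
        mid = [r for r in igs if r.start == 400][0]
        assert not mid.is_sense

    def test_tandem_pair_is_sense(self):
        igs = compute_intergenic([G("g1", 100, 400, "+"), G("g2", 600, 900, "+")], 1000)
        mid = [r for r in igs if r.start == 400][0]
        assert mid.is_sense  # g2's start codon abuts the gap

    def test_contig_end_regions_follow_single_flank_rule(self):
        igs = compute_intergenic([G("g1", 100, 400, "+")], 1000)
        first = [r for r in igs if r.start == 0][0]
        last = [r for r in igs if r.end == 1000][0]
        assert first.is_sense  # g1 reads away from the leading gap
        assert not last.is_sense

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlapping CDS"):
            compute_intergenic([G("g1", 0, 400, "+"), G("g2", 399, 800, "+")], 1000)

    def test_cds_outside_contig_rejected(self):
        with pytest.raises(ValueError, match="outside contig"):
            compute_intergenic([G("g1", 0, 1400, "+")], 1000)

    def test_ig_regions_are_complement_of_cds(self):
        anns = [G("g1", 100, 400, "+"), G("g2", 600, 900, "-")]
        igs = compute_intergenic(anns, 1000)
        assert [(r.start, r.end) for r in igs] == [(0, 100), (400, 600), (900, 1000)]
        assert total_intergenic_bp(igs) == 1000 - 600


class TestClassification:
    ANNS = [G("g1", 300, 1200, "-"), G("g2", 1400, 2780, "+"), G("g3", 2800, 4000, "+")]

    def igs(self):
        return compute_intergenic(self.ANNS, 4500)

    def test_pbs_in_diverging_sense_ig_is_type_I(self):
        call = classify_pbs(P(1250, 1280), self.igs(), self.ANNS)
        assert call.context_type == "I"
        # both diverging genes associate with the shared PBS
        assert set(call.associated_genes) == {"g1", "g2"}

    def test_pbs_in_cds_near_start_is_type_II(self):
        # center 150 bp upstream of g3's start but inside g2's CDS
        call = classify_pbs(P(2635, 2665), self.igs(), self.ANNS)
        assert call.context_type == "II"
        assert call.nearest_start_gene == "g3"
        assert call.distance_center_to_start == 2650 - 2800

    def test_pbs_deep_in_cds_is_type_III(self):
        call = classify_pbs(P(3390, 3420), self.igs(), self.ANNS)
        assert call.context_type == "III"

    def test_downstream_window_is_strand_aware(self):
        # 40 bp downstream of g2's start codon, inside its CDS: Type II
        call = classify_pbs(P(1430, 1450), self.igs(), self.ANNS)
        assert call.context_type in ("I", "II")  # overlaps IG? no: starts at 1430
        assert call.context_type == "II"
        assert call.distance_center_to_start == 1440 - 1400

    def test_types_partition_all_pbss(self):
        rng = np.random.default_rng(0)
        igs = self.igs()
        for _ in range(100):
            s = int(rng.integers(0, 4470))
            call = classify_pbs(P(s, s + 30), igs, self.ANNS)
            assert call.context_type in ("I", "II", "III")

    def test_classification_mirror_invariance(self):
        """Mirroring genome and annotation preserves context types."""
        L = 4500
        mirrored = [
            GeneAnnotation(a.gene_id, a.contig, L - a.end, L - a.start,
                           "-" if a.strand == "+" else "+")
            for a in self.ANNS
        ]
        migs = compute_intergenic(mirrored, L)
        rng = np.random.default_rng(1)
        for _ in range(60):
            s = int(rng.integers(0, L - 31))
            fwd = classify_pbs(P(s, s + 31), self.igs(), self.ANNS)  # odd width: exact mirror center
            rev = classify_pbs(P(L - s - 31, L - s), migs, mirrored)
            assert fwd.context_type == rev.context_type


class TestDensity:
    def test_hand_arithmetic(self):
        d = density_by_type({"I": 2}, 10_000, 1000, 3000)
        assert d["I"] == pytest.approx(2000.0)
        assert d["II"] == pytest.approx(0.0)

    def test_zero_denominator_undefined_not_infinite(self):
        d = density_by_type({"I": 5}, 10_000, 0, 3000)
        assert d["I"] is None

    def test_denominators_sum_to_genome_length_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(5_000, 20_000))
            anns, pos, i = [], int(rng.integers(50, 300)), 0
            while pos + 900 < L:
                glen = int(rng.integers(300, 800))
                anns.append(G(f"g{i}", pos, pos + glen, "+-"[int(rng.integers(2))]))
                pos += glen + int(rng.integers(30, 300))
                i += 1
            igs = compute_intergenic(anns, L)
            tIG = total_intergenic_bp(igs)
            t250 = total_start_zone_bp(anns, {"c": L})
            denoms = [tIG, t250 - tIG, L - t250]
            assert sum(denoms) == L


class TestSelection:
    def test_selection_rules(self):
        from afebox.context import ContextCall

        calls = [
            ContextCall("p1", "I", None, None, None),
            ContextCall("p2", "II", "g", -100, None),
            ContextCall("p3", "II", "g", -100, None),
            ContextCall("p4", "III", "g", 900, None),
        ]
        promos = {"p3": ["pred"], "p4": ["pred"]}  # p2 has none, p4 is Type III
        assert select_candidates(calls, promos) == ["p1", "p3"]


def test_gff3_roundtrip(tmp_path):
    anns = [
        GeneAnnotation("geneA", "chr1", 10, 400, "+", product="widget synthase"),
        GeneAnnotation("geneB", "chr1", 500, 900, "-", product="hypothetical"),
    ]
    text = write_gff3(anns, {"chr1": 1000})
    back = read_gff3(text, from_string=True)
    assert [(a.gene_id, a.start, a.end, a.strand, a.product) for a in back] == [
        (a.gene_id, a.start, a.end, a.strand, a.product) for a in anns
    ]
    assert back[0].start_codon_pos == 10
    assert back[1].start_codon_pos == 899
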