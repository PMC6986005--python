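"""Intron, editing and operon calling against planted truth and hand oracles."""

import math

import numpy as np
import pytest

from plastokit.align import AlignmentBlock, TranscriptAlignment, spliced_map
from plastokit.features import (EditingSite, annotate_editing, call_editing,
                                call_introns, call_operons,
                                combine_site_sets, compare_intron_lengths,
                                editing_summary,
                                intron_length_from_annotation)
from plastokit.models import Annotation, CircularGenome, GeneModel
from plastokit.synthetic import (EditingPlan, GenomeSpec, generate_genome,
                                 scaled_spec, simulate_isoseq)


def _fake_alignment(rid, blocks, strand="+", mismatches=()):
    return TranscriptAlignment(
        read_id=rid, strand=strand,
        blocks=[AlignmentBlock(*b) for b in blocks],
        mismatches=list(mismatches), cigar=[], score=100,
        query_length=sum(b[1] - b[0] for b in blocks))


class TestCallIntrons:
    def test_planted_introns_recovered_exactly(self, scaled_world,
                                               mapped_scaled):
        genome, annotation, truth = scaled_world
        alns, _ = mapped_scaled
        calls = call_introns(alns, annotation, genome=genome)
        got = {(c.gene, c.donor, c.acceptor) for c in calls}
        expected = {(i.gene, i.donor, i.acceptor) for i in truth.introns}
        assert got == expected
        assert all(c.motif_match for c in calls)

    def test_intron_free_data_yields_no_calls(self, scaled_world):
        genome, annotation, truth = scaled_world
        # single-block alignments only
        alns = [_fake_alignment(f"r{i}", [(100 + i, 600 + i, 0, 500)])
                for i in range(10)]
        assert call_introns(alns, annotation) == []

    def test_support_threshold_suppresses_thin_calls(self, scaled_world):
        genome, annotation, truth = scaled_world
        intr = truth.introns[0]
        blocks = [(intr.donor - 50, intr.donor, 0, 50),
                  (intr.acceptor, intr.acceptor + 50, 50, 100)]
        alns = [_fake_alignment(f"r{i}", blocks) for i in range(2)]
        assert call_introns(alns, annotation, min_support=3) == []
        assert len(call_introns(alns, annotation, min_support=2)) == 1

    def test_short_exon_overhang_not_counted_as_support(self, scaled_world):
        genome, annotation, truth = scaled_world
        intr = truth.introns[0]
        blocks = [(intr.donor - 5, intr.donor, 0, 5),   # 5 bp < 10 bp flank
                  (intr.acceptor, intr.acceptor + 50, 5, 55)]
        alns = [_fake_alignment(f"r{i}", blocks) for i in range(5)]
        assert call_introns(alns, annotation, min_support=3) == []


class TestCompareIntronLengths:
    def test_shared_genes_across_two_synthetic_species(self):
        ann = {}
        for name, seed in (("speciesA", 61), ("speciesB", 62)):
            _, a, _ = generate_genome(scaled_spec(20, seed=seed))
            ann[name] = a
        df = compare_intron_lengths(ann)
        assert set(df["species"]) == {"speciesA", "speciesB"}
        present = df[df["status"] == "present"]
        assert set(present["gene"]) == {"ycf3", "clpP"}

    def test_species_lacking_an_intron_marked_absent(self):
        g1 = GeneModel("clpP", "+", ((0, 100), (300, 400)))
        g2 = GeneModel("clpP", "+", ((0, 200),))
        ann = {"withintron": Annotation("a", 1000, [g1]),
               "grasslike": Annotation("b", 1000, [g2])}
        df = compare_intron_lengths(ann)
        grass = df[(df.species == "grasslike") & (df.intron_index == 1)]
        assert list(grass["status"]) == ["absent"]
        assert grass["intron_length"].isna().all()

    def test_intron_length_equals_exon_gap_from_genbank(self, tmp_path):
        from plastokit.io import parse_genbank, write_genbank
        genome, annotation, _ = generate_genome(scaled_spec(20, seed=63))
        path = tmp_path / "x.gb"
        write_genbank(genome, annotation, path)
        _, back = parse_genbank(path)
        g = back.by_name("ycf3")
        expected = g.exons[1][0] - g.exons[0][1]
        assert intron_length_from_annotation(back, "ycf3") == expected


class TestCallEditing:
    def test_full_recovery_on_scaled_world(self, scaled_world, mapped_scaled):
        genome, annotation, truth = scaled_world
        alns, _ = mapped_scaled
        ics = call_introns(alns, annotation, genome=genome)
        sites = call_editing(alns, genome, annotation, intron_calls=ics)
        got = {s.position for s in sites}
        expected = {s.position for s in truth.editing_sites}
        assert got == expected
        by_pos = {s.position: s for s in sites}
        for ts in truth.editing_sites:
            s = by_pos[ts.position]
            assert s.strand == ts.strand
            assert s.category == ts.category
            assert abs(s.efficiency - ts.efficiency) <= 0.15

    def test_binomial_filter_matches_exact_tail(self, scaled_world):
        """30 covering / 6 edited: p-value equals the closed-form tail."""
        genome, annotation, _ = scaled_world
        pos = next(p for p in range(200, 2000) if genome.sequence[p] == "C")
        blocks = [(pos - 100, pos + 100, 0, 200)]
        alns = [_fake_alignment(f"e{i}", blocks,
                                mismatches=[(pos, "C", "T")]) for i in range(6)]
        alns += [_fake_alignment(f"c{i}", blocks) for i in range(24)]
        sites = call_editing(alns, genome, annotation, min_cov=10,
                             min_eff=0.10, err=0.02)
        mine = [s for s in sites if s.position == pos]
        assert len(mine) == 1
        s = mine[0]
        assert s.edited == 6 and s.covering == 30
        assert s.efficiency == pytest.approx(0.2)
        exact_tail = sum(math.comb(30, k) * 0.02 ** k * 0.98 ** (30 - k)
                         for k in range(6, 31))
        assert s.p_value == pytest.approx(exact_tail, rel=1e-9)
        # with min_eff above the observed fraction the site is suppressed
        sites_hi = call_editing(alns, genome, annotation, min_cov=10,
                                min_eff=0.25, err=0.02)
        assert all(x.position != pos for x in sites_hi)

    def test_specificity_on_editing_free_simulations(self):
        """No editing planted, 2% error: zero false calls across 20 seeds."""
        from plastokit.align import TargetIndex
        false_calls = 0
        for seed in range(20):
            spec = scaled_spec(20, seed=400 + seed)
            spec = GenomeSpec(**{**spec.__dict__,
                                 "editing_plan": EditingPlan(
                                     efficiencies=(), n_cds=0, n_intron=0,
                                     n_intergenic=0)})
            genome, annotation, truth = generate_genome(spec)
            index = TargetIndex.build(genome, k=13)
            reads = simulate_isoseq(genome, truth, depth=30, error_rate=0.02,
                                    seed=500 + seed, intron_retention=0.2)
            alns = [a for a in (spliced_map(r, index) for r in reads) if a]
            false_calls += len(call_editing(alns, genome, annotation))
        assert false_calls == 0

    def test_bit_for_bit_reproducibility(self, scaled_world, mapped_scaled):
        genome, annotation, _ = scaled_world
        alns, _ = mapped_scaled
        a = call_editing(alns, genome, annotation)
        b = call_editing(alns, genome, annotation)
        assert [(s.position, s.edited, s.covering, s.q_value) for s in a] == \
               [(s.position, s.edited, s.covering, s.q_value) for s in b]


class TestAnnotateEditing:
    def _mini_world(self, codons, strand="+"):
        # gene of given codons planted at position 30 of a 200 bp genome
        cds = "ATG" + codons + "TAA"
        if strand == "+":
            seq = "A" * 30 + cds + "A" * (170 - len(cds))
        else:
            from plastokit._seq import revcomp
            seq = "A" * 30 + revcomp(cds) + "A" * (170 - len(cds))
        genome = CircularGenome(id="mini", sequence=seq, circular=False)
        gene = GeneModel("testgene", strand, ((30, 30 + len(cds)),))
        return genome, Annotation("mini", 200, [gene])

    def test_tca_to_tta_is_serine_to_leucine(self):
        genome, ann = self._mini_world("TCA")
        site = EditingSite(position=34, strand="+", ref_base="C", edited=10,
                           covering=10, efficiency=1.0, p_value=0.0,
                           q_value=0.0)
        annotate_editing(site, ann, genome)
        assert site.category == "CDS"
        assert site.codon_position == 2
        assert site.aa_change == "S>L"

    def test_third_position_ctc_to_ctt_synonymous(self):
        genome, ann = self._mini_world("CTC")
        site = EditingSite(position=35, strand="+", ref_base="C", edited=10,
                           covering=10, efficiency=1.0, p_value=0.0,
                           q_value=0.0)
        annotate_editing(site, ann, genome)
        assert site.codon_position == 3
        assert "synonymous" in site.aa_change

    def test_minus_strand_codon_mapping(self):
        genome, ann = self._mini_world("TCA", strand="-")
        gene = ann.genes[0]
        # coding position of the C in TCA: codon index 1, offset 1 -> 4
        gpos = gene.end - 1 - 4
        assert genome.sequence[gpos] == "G"
        site = EditingSite(position=gpos, strand="-", ref_base="C", edited=5,
                           covering=5, efficiency=1.0, p_value=0.0,
                           q_value=0.0)
        annotate_editing(site, ann, genome)
        assert site.aa_change == "S>L"

    def test_non_c_reference_is_invariant_violation(self, scaled_world):
        genome, annotation, _ = scaled_world
        pos = next(p for p in range(100) if genome.sequence[p] != "C")
        site = EditingSite(position=pos, strand="+", ref_base="C", edited=1,
                           covering=1, efficiency=1.0, p_value=0.0,
                           q_value=0.0)
        with pytest.raises(ValueError, match="not C"):
            annotate_editing(site, annotation, genome)

    def test_intergenic_site_category(self, scaled_world, mapped_scaled):
        genome, annotation, truth = scaled_world
        alns, _ = mapped_scaled
        ts = next(s for s in truth.editing_sites if s.category == "intergenic")
        sites = call_editing(alns, genome, annotation)
        mine = [s for s in sites if s.position == ts.position]
        assert mine and mine[0].category == "intergenic"


class TestEditingSummary:
    def test_category_totals_sum(self):
        sites = ([EditingSite(i, "+", "C", 5, 10, 0.5, 0.0, 0.0,
                              category="CDS") for i in range(30)]
                 + [EditingSite(100, "+", "C", 5, 10, 0.5, 0.0, 0.0,
                                category="intron")]
                 + [EditingSite(200 + i, "+", "C", 5, 10, 0.5, 0.0, 0.0,
                                category="intergenic") for i in range(6)])
        s = editing_summary(sites)
        assert s["by_category"] == {"CDS": 30, "intron": 1, "intergenic": 6}
        assert s["total"] == 37

    def test_empty_input_gives_zeros(self):
        s = editing_summary([])
        assert s["total"] == 0
        assert s["efficiency"]["median"] == 0.0

    def test_combine_site_sets_arithmetic(self):
        known = set(range(66))
        new = set(range(37, 74))  # 66..73 are new-only? overlap = 37..65 = 29
        out = combine_site_sets(known, new)
        assert out == {"known": 66, "new": 37, "overlap": 29, "combined": 74}


class TestCallOperons:
    def test_planted_units_recovered(self, scaled_world, mapped_scaled):
        _, annotation, truth = scaled_world
        alns, _ = mapped_scaled
        calls = call_operons(alns, annotation)
        expected = {u.gene_names for u in truth.units
                    if len(u.gene_names) >= 2}
        assert {c.genes for c in calls} == expected
        for c in calls:
            unit = next(u for u in truth.units if u.gene_names == c.genes)
            assert c.strand == unit.strand

    def test_monocistronic_only_data_yields_no_calls(self, scaled_world):
        _, annotation, _ = scaled_world
        g = annotation.sorted_by_position()[0]
        alns = [_fake_alignment(f"r{i}", [(g.start, g.end, 0, g.span)],
                                strand=g.strand) for i in range(10)]
        assert call_operons(alns, annotation) == []

    def test_subset_groups_not_merged(self):
        genes = [GeneModel("atpA", "+", ((100, 400),)),
                 GeneModel("atpF", "+", ((500, 800),)),
                 GeneModel("atpH", "+", ((900, 1200),))]
        ann = Annotation("t", 2000, genes)
        two = [_fake_alignment(f"a{i}", [(100, 800, 0, 700)])
               for i in range(5)]
        three = [_fake_alignment(f"b{i}", [(100, 1200, 0, 1100)])
                 for i in range(5)]
        calls = call_operons(two + three, ann)
        assert len(calls) == 2
        sub = next(c for c in calls if len(c.genes) == 2)
        sup = next(c for c in calls if len(c.genes) == 3)
        assert sub.subset_of == sup.name
        assert {sub.name, sup.name} == {"Atp_1", "Atp_2"}

    def test_gene_order_follows_transcription_direction(self):
        genes = [GeneModel("psbB", "-", ((100, 400),)),
                 GeneModel("psbT", "-", ((500, 800),))]
        ann = Annotation("t", 1000, genes)
        alns = [_fake_alignment(f"r{i}", [(100, 800, 0, 700)], strand="-")
                for i in range(4)]
        calls = call_operons(alns, ann)
        assert len(calls) == 1
        # minus strand: transcription runs right to left on the genome
        assert calls[0].genes == ("psbT", "psbB")
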