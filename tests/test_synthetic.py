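"""The generator must emit exactly the structure the analyses assume."""

import numpy as np
import pytest

from plastokit._seq import gc_percent, revcomp
from plastokit.synthetic import (EditingPlan, GenomeSpec, SpecSizingError,
                                 generate_genome, mix_decoy_reads,
                                 scaled_spec, simulate_genomic_reads,
                                 simulate_isoseq, study_spec)


class TestGenerateGenome:
    def test_region_reconstruction_byte_for_byte(self, scaled_world):
        genome, _, truth = scaled_world
        parts = [genome.sequence[s:e] for s, e in
                 (truth.region_coords[r] for r in ("lsc", "ira", "ssc", "irb"))]
        assert "".join(parts) == genome.sequence

    def test_ir_copies_are_exact_reverse_complements(self, scaled_world):
        genome, _, truth = scaled_world
        ira = genome.sequence[slice(*truth.region_coords["ira"])]
        irb = genome.sequence[slice(*truth.region_coords["irb"])]
        assert revcomp(ira) == irb

    def test_scaled_genome_length(self, scaled_world):
        genome, _, _ = scaled_world
        assert len(genome) == 91210 // 20 + 14058 // 20 + 2 * (31844 // 20)

    def test_full_scale_genome_length_matches_quadripartite_sum(self):
        genome, annotation, truth = generate_genome(study_spec(seed=3))
        assert len(genome) == 168956
        assert len(annotation) == 107

    def test_genes_do_not_overlap(self, scaled_world):
        _, annotation, _ = scaled_world
        spans = sorted((g.start, g.end) for g in annotation)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_introns_inside_their_genes_with_group_ii_motifs(self, scaled_world):
        genome, annotation, truth = scaled_world
        for intr in truth.introns:
            g = annotation.by_name(intr.gene)
            assert g.start < intr.donor < intr.acceptor < g.end
            iseq = genome.sequence[intr.donor:intr.acceptor]
            if g.strand == "-":
                iseq = revcomp(iseq)
            assert iseq[:3] == "GTG" and iseq[3] in "CT" and iseq[4] == "G"
            assert iseq[-2] == "A" and iseq[-1] in "CT"

    def test_region_gc_within_tolerance(self, scaled_world):
        genome, _, truth = scaled_world
        targets = {"lsc": 33.47, "ssc": 30.17, "ira": 40.06, "irb": 40.06}
        for region, (s, e) in truth.region_coords.items():
            gc = gc_percent(genome.sequence[s:e])
            assert abs(gc - targets[region]) <= 1.5

    def test_editing_sites_are_c_on_their_strand(self, scaled_world):
        genome, _, truth = scaled_world
        for site in truth.editing_sites:
            base = genome.sequence[site.position]
            assert base == ("C" if site.strand == "+" else "G")

    def test_operon_genes_contiguous_and_co_stranded(self, scaled_world):
        _, annotation, truth = scaled_world
        order = [g.name for g in annotation.sorted_by_position()]
        for unit in truth.units:
            models = [annotation.by_name(n) for n in unit.gene_names]
            assert len({m.strand for m in models}) == 1
            idx = sorted(order.index(n) for n in unit.gene_names)
            assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_intron_free_plan_plants_no_introns(self):
        spec = scaled_spec(20, seed=1)
        spec = GenomeSpec(**{**spec.__dict__, "intron_plan": {},
                             "editing_plan": EditingPlan(
                                 efficiencies=(0.5,), n_cds=1, n_intron=0,
                                 n_intergenic=0)})
        _, _, truth = generate_genome(spec)
        assert truth.introns == []

    def test_infeasible_spec_names_the_region(self):
        spec = scaled_spec(20, seed=1)
        spec = GenomeSpec(**{**spec.__dict__, "lsc_len": 900})
        with pytest.raises(SpecSizingError, match="LSC"):
            generate_genome(spec)

    def test_strand_closure_round_trip(self, scaled_world):
        """Reverse-complementing the genome mirrors every gene model."""
        genome, annotation, _ = scaled_world
        n = len(genome)
        rc = genome.reverse_complement()
        for g in annotation:
            mirrored = type(g)(
                name=g.name, strand="-" if g.strand == "+" else "+",
                exons=tuple(sorted((n - e, n - s) for s, e in g.exons)),
                gene_type=g.gene_type)
            assert mirrored.spliced_sequence(rc) == g.spliced_sequence(genome)


class TestGenomicReads:
    def test_zero_error_reads_are_exact_substrings(self, scaled_world):
        genome, _, _ = scaled_world
        doubled = genome.sequence * 3
        reads = simulate_genomic_reads(genome, 50, 800, 0.0, seed=5)
        for r in reads:
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            assert seq in doubled

    def test_truth_intervals_match_read_content(self, scaled_world):
        genome, _, _ = scaled_world
        reads = simulate_genomic_reads(genome, 30, 600, 0.0, seed=6)
        for r in reads:
            expected = genome.fetch(r.source_start, r.source_end)
            seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
            assert seq == expected

    def test_mean_length_concentrates(self, scaled_world):
        genome, _, _ = scaled_world
        reads = simulate_genomic_reads(genome, 1000, 1000, 0.0, seed=7)
        assert 950 <= reads.total_bases() / len(reads) <= 1050

    def test_origin_spanning_reads_exist_at_depth(self, scaled_world):
        genome, _, _ = scaled_world
        n = len(genome)
        reads = simulate_genomic_reads(genome, 500, 1500, 0.0, seed=8)
        assert any(r.source_end > n for r in reads)

    def test_n_zero_gives_empty_set(self, scaled_world):
        genome, _, _ = scaled_world
        assert len(simulate_genomic_reads(genome, 0, 1000, 0.1, seed=1)) == 0

    def test_error_rate_bounds(self, scaled_world):
        genome, _, _ = scaled_world
        with pytest.raises(ValueError):
            simulate_genomic_reads(genome, 10, 1000, 0.5, seed=1)


class TestDecoyMixing:
    def test_fraction_zero_is_identity(self, scaled_world):
        genome, _, _ = scaled_world
        reads = simulate_genomic_reads(genome, 100, 800, 0.05, seed=9)
        mixed = mix_decoy_reads(reads, genome, 0.0, seed=10)
        assert [r.id for r in mixed] == [r.id for r in reads]

    def test_fraction_one_is_all_decoy(self, scaled_world):
        genome, _, _ = scaled_world
        reads = simulate_genomic_reads(genome, 100, 800, 0.05, seed=9)
        decoy = generate_genome(scaled_spec(20, seed=99))[0]
        mixed = mix_decoy_reads(reads, decoy, 1.0, seed=10)
        assert all(r.origin == "decoy" for r in mixed)

    def test_binomial_mixing_fraction(self, scaled_world):
        genome, _, _ = scaled_world
        reads = simulate_genomic_reads(genome, 1000, 600, 0.0, seed=11)
        decoy = generate_genome(scaled_spec(20, seed=98))[0]
        mixed = mix_decoy_reads(reads, decoy, 0.5, seed=12)
        n_decoy = sum(r.origin == "decoy" for r in mixed)
        assert len(mixed) == 1000 and 440 <= n_decoy <= 560


class TestIsoSeq:
    def test_full_efficiency_site_always_edited(self, scaled_world):
        genome, _, truth = scaled_world
        site = next(s for s in truth.editing_sites if s.efficiency == 1.0
                    and s.category != "intron")
        unit = next(u for u in truth.units
                    if u.start <= site.position < u.end and u.strand == s_strand(site))
        reads = simulate_isoseq(genome, truth, depth=30, error_rate=0.0,
                                seed=13, intron_retention=0.0)
        checked = 0
        for r in reads:
            if r.unit_id != unit.id:
                continue
            base = _base_at(genome, truth, r, site.position)
            if base is None:
                continue
            assert base == ("T" if site.strand == "+" else "A")
            checked += 1
        assert checked == 30

    def test_depth_transcripts_per_unit_cover_all_genes(self, scaled_world):
        genome, annotation, truth = scaled_world
        unit = max(truth.units, key=lambda u: len(u.gene_names))
        reads = simulate_isoseq(genome, truth, depth=20, error_rate=0.0,
                                seed=14, intron_retention=0.0)
        mine = [r for r in reads if r.unit_id == unit.id]
        assert len(mine) == 20
        for r in mine:
            for name in unit.gene_names:
                g = annotation.by_name(name)
                assert r.span[0] <= g.start and g.end <= r.span[1]

    def test_editing_fraction_concentrates_at_depth_200(self, scaled_world):
        genome, _, truth = scaled_world
        site = next(s for s in truth.editing_sites
                    if abs(s.efficiency - 0.93) < 1e-9)
        reads = simulate_isoseq(genome, truth, depth=200, error_rate=0.0,
                                seed=15, intron_retention=0.0)
        edited = covered = 0
        for r in reads:
            base = _base_at(genome, truth, r, site.position)
            if base is None:
                continue
            covered += 1
            edited += base == ("T" if site.strand == "+" else "A")
        assert covered == 200
        assert abs(edited / covered - 0.93) <= 0.05

    def test_spliced_molecules_lack_intron_sequence(self, scaled_world):
        genome, annotation, truth = scaled_world
        intr = truth.introns[0]
        unit = next(u for u in truth.units if intr.gene in u.gene_names)
        reads = simulate_isoseq(genome, truth, depth=5, error_rate=0.0,
                                seed=16, intron_retention=0.0)
        expected_len = (unit.end - unit.start) - sum(
            i.length for i in truth.introns
            if any(i.gene in (g,) for g in unit.gene_names))
        for r in reads:
            if r.unit_id == unit.id:
                assert len(r.sequence) == expected_len


def s_strand(site):
    return site.strand


def _base_at(genome, truth, read, position):
    """Base a transcript carries at a genomic position (None if spliced out
    or outside the unit)."""
    unit = next(u for u in truth.units if u.id == read.unit_id)
    if not unit.start <= position < unit.end:
        return None
    seq = read.sequence if unit.strand == "+" else revcomp(read.sequence)
    # reconstruct segment offsets by aligning lengths: error-free, so the
    # molecule is the unit span minus any spliced introns
    introns = sorted((i.donor, i.acceptor) for i in truth.introns
                     if any(g == i.gene for g in unit.gene_names))
    removed_before = 0
    removed_total = (unit.end - unit.start) - len(seq)
    spliced = []
    # determine which introns were spliced in this molecule by length
    for d, a in introns:
        spliced.append((d, a))
    if removed_total != sum(a - d for d, a in spliced):
        # some introns retained; cannot resolve offsets without alignment
        return None
    for d, a in spliced:
        if d <= position < a:
            return None
        if a <= position:
            removed_before += a - d
    return seq[position - unit.start - removed_before]
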