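#!/usr/bin/env python
"""Call introns, C->U editing sites and operons from the mapped cDNAs.

Reads scratch/study/transcripts.sam (from 04_map_transcripts.py), calls the
three feature classes, compares each against the planted truth, and writes
results/05_introns.tsv, results/05_editing.tsv, results/05_operons.tsv and
a recovery scorecard results/05_recovery.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from plastokit.align import read_sam
from plastokit.features import (call_editing, call_introns, call_operons,
                                editing_summary)
from plastokit.io import parse_fasta, parse_gff3, write_editing_tsv
from plastokit.synthetic import generate_genome, study_spec

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7
STUDY = Path("scratch/study")
RESULTS = Path("results")


def main():
    genome = parse_fasta(STUDY / "genome.fasta")
    annotation = parse_gff3(STUDY / "annotation.gff3")
    _, _, truth = generate_genome(study_spec(seed=SEED))
    alns = read_sam(STUDY / "transcripts.sam")

    introns = call_introns(alns, annotation, genome=genome)
    pd.DataFrame([{"gene": c.gene, "donor": c.donor, "acceptor": c.acceptor,
                   "length_bp": c.length, "support": c.support,
                   "motif": c.motif_match} for c in introns]).to_csv(
        RESULTS / "05_introns.tsv", sep="\t", index=False)

    sites = call_editing(alns, genome, annotation, intron_calls=introns)
    write_editing_tsv(sites, RESULTS / "05_editing.tsv")

    operons = call_operons(alns, annotation)
    pd.DataFrame([{"operon": o.name, "genes": "+".join(o.genes),
                   "n_genes": len(o.genes), "strand": o.strand,
                   "span_bp": o.span, "support": o.support,
                   "subset_of": o.subset_of} for o in operons]).to_csv(
        RESULTS / "05_operons.tsv", sep="\t", index=False)

    ti = {(i.gene, i.donor, i.acceptor) for i in truth.introns}
    ci = {(c.gene, c.donor, c.acceptor) for c in introns}
    tp_sites = {s.position for s in truth.editing_sites}
    cp_sites = {s.position for s in sites}
    planted_eff = {s.position: s.efficiency for s in truth.editing_sites}
    eff_err = [abs(s.efficiency - planted_eff[s.position])
               for s in sites if s.position in planted_eff]
    tu = {u.gene_names for u in truth.units if len(u.gene_names) >= 2}
    es = editing_summary(sites)
    rows = [
        ("introns_called", len(introns)),
        ("introns_exact", len(ci & ti)),
        ("intron_genes", len({c.gene for c in introns})),
        ("editing_sites_called", len(sites)),
        ("editing_sites_exact", len(cp_sites & tp_sites)),
        ("editing_false_positives", len(cp_sites - tp_sites)),
        ("editing_max_efficiency_error",
         round(max(eff_err), 4) if eff_err else ""),
        ("editing_cds/intron/intergenic",
         "/".join(str(es["by_category"][k])
                  for k in ("CDS", "intron", "intergenic"))),
        ("operons_called", len(operons)),
        ("operons_exact", len({o.genes for o in operons} & tu)),
        ("largest_operon_genes",
         max((len(o.genes) for o in operons), default=0)),
    ]
    df = pd.DataFrame(rows, columns=["quantity", "value"])
    df.to_csv(RESULTS / "05_recovery.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
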