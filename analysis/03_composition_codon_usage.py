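#!/usr/bin/env python
"""Composition skews and codon usage over the synthetic dataset.

For each simulated taxon: whole-genome and per-category A+T content and
AT/GC skews, the codon-position partition over the 13 concatenated PCGs,
the start/stop codon audit, and the RSCU table. Requires
02_simulate_dataset.py to have been run.

Writes results/composition.tsv, results/codon_audit.tsv, results/rscu.tsv.
"""

from pathlib import Path

from mitocomp.codon_usage import CodonCountTable, extract_coding_record, rscu
from mitocomp.composition import partition_composition
from mitocomp.genome_model import read_genbank

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_dataset"
OUT = ROOT / "results"


def main() -> None:
    genomes = {p.stem: read_genbank(p) for p in sorted(DATA.glob("*.gb"))}
    if not genomes:
        raise SystemExit("run analysis/02_simulate_dataset.py first")

    with open(OUT / "composition.tsv", "w") as fh:
        fh.write("taxon\tscope\tlabel\tA\tC\tG\tT\tAT_pct\tAT_skew\tGC_skew\n")
        for taxon, g in genomes.items():
            for scope in ("whole", "category", "codon-position"):
                for label, s in partition_composition(g, scope):
                    fh.write(f"{taxon}\t{scope}\t{label}\t{s.a}\t{s.c}\t{s.g}"
                             f"\t{s.t}\t{s.at_content:.2f}\t{s.at_skew:.4f}"
                             f"\t{s.gc_skew:.4f}\n")

    with open(OUT / "codon_audit.tsv", "w") as fh:
        fh.write("taxon\tgene\tstart_codon\tstop_codon\taa_length\n")
        for taxon, g in genomes.items():
            for f in g.table.pcgs:
                r = extract_coding_record(g, f)
                fh.write(f"{taxon}\t{f.name}\t{r.start_codon}\t{r.stop_codon}"
                         f"\t{r.aa_length}\n")

    with open(OUT / "rscu.tsv", "w") as fh:
        fh.write("taxon\tcodon\tfamily\tcount\trscu\n")
        for taxon, g in genomes.items():
            table = CodonCountTable.from_genome(g)
            for codon, (fam, val, _u) in sorted(rscu(table).items()):
                fh.write(f"{taxon}\t{codon}\t{fam}\t{table.counts.get(codon, 0)}"
                         f"\t{val:.4f}\n")

    for taxon, g in genomes.items():
        (_, w), = partition_composition(g, "whole")
        total = CodonCountTable.from_genome(g).total_codons
        print(f"{taxon}: AT {w.at_content:.2f}%, ATskew {w.at_skew:+.3f}, "
              f"GCskew {w.gc_skew:+.3f}, sense codons {total}")
    print(f"wrote composition.tsv, codon_audit.tsv, rscu.tsv to {OUT}")


if __name__ == "__main__":
    main()
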