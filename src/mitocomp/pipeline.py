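"""End-to-end orchestration: run the analysis stages in dependency order over
a set of annotated mitogenomes and collect one JSON-serializable summary.

Stage order is model -> composition/codon -> divergence -> repeats -> tree;
stages whose preconditions are unmet (no sequence, <3 taxa, ...) are skipped
with a notice rather than failing the whole run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from . import __version__
from .composition import partition_composition
from .codon_usage import CodonCountTable, extract_coding_record, rscu
from .divergence import codon_partition_distances, nei_gojobori
from .genome_model import Mitogenome, validate_gene_complement
from .phylo import build_supermatrix, bootstrap_support, check_constraints
from .registry import PCG_NAMES
from .repeats import repeat_report

_SIG = 6  # significant digits for serialized floats


def _round(x):
    if isinstance(x, float):
        return float(f"{x:.{_SIG}g}")
    return x


def config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _tsv_header(cfg_hash: str) -> str:
    return f"# mitocomp {__version__} config={cfg_hash}\n"


def _write_tsv(path: Path, header_cols: list[str], rows: list[list],
               cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(_tsv_header(cfg_hash))
        fh.write("\t".join(header_cols) + "\n")
        for row in rows:
            fh.write("\t".join("" if v is None else str(_round(v)) for v in row) + "\n")


def run_pipeline(genomes: dict[str, Mitogenome], outdir: str | Path,
                 stages: list[str] | None = None, seed: int = 0,
                 bootstrap_reps: int = 100,
                 constraints: list[set[str]] | None = None,
                 repeat_params: dict | None = None) -> dict:
    """Run selected stages over ``genomes`` (taxon -> Mitogenome), write
    per-stage TSVs under ``outdir``, and return the combined summary."""
    if not genomes:
        raise ValueError("at least one genome is required")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_stages = ["model", "composition", "codon", "divergence", "repeats", "tree"]
    stages = stages or all_stages
    unknown = set(stages) - set(all_stages)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    params = {"stages": stages, "seed": seed, "bootstrap_reps": bootstrap_reps,
              "taxa": sorted(genomes)}
    chash = config_hash(params)
    summary: dict = {"version": __version__, "schema": 1, "config": params,
                     "config_hash": chash, "skipped": {}}
    have_seq = {t: bool(g.sequence) for t, g in genomes.items()}

    if "model" in stages:
        model = {}
        for taxon, g in genomes.items():
            report = validate_gene_complement(g.table)
            model[taxon] = {
                "genome_length": g.table.genome_length,
                "counts": report.counts, "n_genes": report.n_genes,
                "missing": report.missing, "duplicated": report.duplicated,
            }
        _write_tsv(outdir / "model.tsv",
                   ["taxon", "genome_length", "n_genes", "PCG", "tRNA", "rRNA"],
                   [[t, m["genome_length"], m["n_genes"], m["counts"]["PCG"],
                     m["counts"]["tRNA"], m["counts"]["rRNA"]]
                    for t, m in model.items()], chash)
        summary["model"] = model

    if "composition" in stages:
        comp, rows = {}, []
        for taxon, g in genomes.items():
            if not have_seq[taxon]:
                continue
            (_, whole), = partition_composition(g, "whole")
            comp[taxon] = {"at_content": _round(whole.at_content),
                           "at_skew": _round(whole.at_skew),
                           "gc_skew": _round(whole.gc_skew)}
            rows.append([taxon, whole.a, whole.c, whole.g, whole.t,
                         whole.at_content, whole.at_skew, whole.gc_skew])
        if comp:
            _write_tsv(outdir / "composition.tsv",
                       ["taxon", "A", "C", "G", "T", "AT%", "ATskew", "GCskew"],
                       rows, chash)
            summary["composition"] = comp
        else:
            summary["skipped"]["composition"] = "no genome has sequence"

    if "codon" in stages:
        codon, rows = {}, []
        for taxon, g in genomes.items():
            if not have_seq[taxon]:
                continue
            records = [extract_coding_record(g, f) for f in g.table.pcgs]
            codon[taxon] = {
                "total_sense_codons": sum(r.aa_length for r in records),
                "start_codons": {r.gene: r.start_codon for r in records},
                "stop_codons": {r.gene: r.stop_codon for r in records},
            }
            rows += [[taxon, r.gene, r.start_codon, r.stop_codon, r.aa_length]
                     for r in records]
            table = CodonCountTable.from_records(records)
            _write_tsv(outdir / f"rscu_{taxon}.tsv",
                       ["codon", "family", "count", "RSCU"],
                       [[c, fam, table.counts.get(c, 0), val]
                        for c, (fam, val, _undef) in sorted(rscu(table).items())],
                       chash)
        if codon:
            _write_tsv(outdir / "codons.tsv",
                       ["taxon", "gene", "start_codon", "stop_codon", "aa_length"],
                       rows, chash)
            summary["codon"] = codon
        else:
            summary["skipped"]["codon"] = "no genome has sequence"

    seq_taxa = sorted(t for t in genomes if have_seq[t])
    if "divergence" in stages:
        if len(seq_taxa) < 2:
            summary["skipped"]["divergence"] = ">=2 genomes with sequence required"
        else:
            kaks_rows, dist_rows = [], []
            gene_means: dict[str, list[float]] = {g: [] for g in PCG_NAMES}
            for i, t1 in enumerate(seq_taxa):
                for t2 in seq_taxa[i + 1:]:
                    for gene in PCG_NAMES:
                        r1 = extract_coding_record(genomes[t1], genomes[t1].table[gene])
                        r2 = extract_coding_record(genomes[t2], genomes[t2].table[gene])
                        a, b = "".join(r1.codons), "".join(r2.codons)
                        if len(a) != len(b):
                            raise ValueError(f"{gene}: unequal lengths "
                                             f"{len(a)} vs {len(b)} for {t1}/{t2}")
                        res = nei_gojobori(a, b, gene=gene, pair=(t1, t2))
                        kaks_rows.append([gene, t1, t2, res.S, res.N, res.Sd,
                                          res.Nd, res.Ka, res.Ks, res.ratio,
                                          res.selection_class])
                        if res.ratio is not None:
                            gene_means[gene].append(res.ratio)
                        pd_ = codon_partition_distances(gene, (t1, t2), a, b)
                        dist_rows.append([gene, t1, t2, pd_.p12, pd_.p3])
            _write_tsv(outdir / "kaks.tsv",
                       ["gene", "taxon1", "taxon2", "S", "N", "Sd", "Nd",
                        "Ka", "Ks", "ratio", "class"], kaks_rows, chash)
            _write_tsv(outdir / "distances.tsv",
                       ["gene", "taxon1", "taxon2", "p12", "p3"], dist_rows, chash)
            summary["divergence"] = {
                "kaks_mean_per_gene": {
                    g: _round(sum(v) / len(v)) for g, v in gene_means.items() if v}}

    if "repeats" in stages:
        reps, rows = {}, []
        for taxon in seq_taxa:
            try:
                report = repeat_report(genomes[taxon], **(repeat_params or {}))
            except ValueError as exc:
                summary["skipped"][f"repeats:{taxon}"] = str(exc)
                continue
            reps[taxon] = [{k: r[k] for k in
                            ("start", "period", "copies", "identity", "span")}
                           for r in report]
            rows += [[taxon, r["region"], r["start"], r["period"], r["copies"],
                      r["identity"], r["consensus"]] for r in report]
        if reps:
            _write_tsv(outdir / "repeats.tsv",
                       ["taxon", "region", "start", "period", "copies",
                        "identity", "consensus"], rows, chash)
            summary["repeats"] = reps

    if "tree" in stages:
        if len(seq_taxa) < 3:
            summary["skipped"]["tree"] = ">=3 taxa with sequence required"
        else:
            sm = build_supermatrix({t: genomes[t] for t in seq_taxa})
            tree = bootstrap_support(sm, reps=bootstrap_reps, seed=seed)
            newick = tree.to_newick(decimals=6)
            (outdir / "tree.nwk").write_text(newick + "\n")
            summary["tree"] = {"newick": newick, "n_sites": sm.n_sites}
            if constraints:
                summary["tree"]["constraints"] = [
                    {"clade": sorted(c), "satisfied": ok}
                    for c, ok in zip(constraints, check_constraints(tree, constraints))]

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True) + "\n")
    return summary
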