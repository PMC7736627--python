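"""Synthetic circular mitogenomes with a ground-truth ledger.

The generator emulates the structural features of a vertebrate (fish)
mitogenome so every analysis stage can be exercised without downloads:

* the canonical 39-element layout (13 PCGs, 22 tRNAs, 2 rRNAs, OL, D-loop)
  at configurable element sizes (default: the *S. tertius*-style profile of
  the bundled reference table), laid out contiguously;
* PCGs that are stop-free ORFs under the vertebrate mitochondrial code with
  the conventional start/stop idiosyncrasies planted (GTG initiation for COI,
  incomplete terminal T/TA where the gene length demands it);
* an OL carrying exactly one copy of the conserved 5'-GCCGG-3' stem motif;
* a control region carrying a planted tandem repeat with configurable unit
  length, copy number and per-base substitution noise;
* base composition drawn to hit a target A+T content, positive AT-skew and
  negative GC-skew in expectation (on the H-strand; L-strand elements are
  sampled through the complement so the genome-wide skew target still holds).

Sequences then evolve along a user tree by codon-level rejection sampling:
HKY-style proposals (transition:transversion weight kappa), nonsynonymous
proposals accepted with probability omega, proposals creating stops always
rejected; non-coding and RNA elements evolve neutrally. Every accepted event
is recorded in a ledger sufficient to recompute the downstream statistics
without re-simulation. A single seed makes all outputs byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from . import reference, registry
from .codon_usage import CODON_TO_AA, STOP_CODONS
from .genome_model import (GeneFeature, GeneTable, Mitogenome, reverse_complement,
                           write_feature_table, write_fasta)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: conventional terminal codons for clean-multiple-of-3 PCGs (ST-style)
_FULL_STOPS = {"ND1": "TAG", "COI": "TAA", "ATP8": "TAA", "ND4L": "TAA",
               "ND5": "TAA", "ND6": "TAG"}
_START_OF = {"COI": "GTG"}
_OL_MOTIF = "GCCGG"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study-like conditions."""

    seed: int = 0
    tree: str = "((ST:0.02,SA:0.02):0.03,SM:0.08,OUT:0.25);"
    omega: float = 0.05
    kappa: float = 2.0
    target_at_content: float = 55.0   # percent A+T, fish mitogenome-like
    target_at_skew: float = 0.05      # H-strand, slightly positive
    target_gc_skew: float = -0.28     # H-strand, clearly negative
    repeat_spec: tuple[int, float, float] | None = (22, 6.0, 0.02)  # period, copies, noise
    gene_length_profile: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not (0 < self.target_at_content < 100):
            raise ValueError("target_at_content must be in (0, 100)")
        if not (abs(self.target_at_skew) < 1 and abs(self.target_gc_skew) < 1):
            raise ValueError("skew targets must be in (-1, 1)")
        if not self.gene_length_profile:
            df = reference.load_dataframe()
            self.gene_length_profile = {
                row["name"]: int(row["st_end"]) - int(row["st_start"]) + 1
                for _, row in df.iterrows()}

    @property
    def base_freqs(self) -> dict[str, float]:
        at = self.target_at_content / 100.0
        gc = 1.0 - at
        return {
            "A": at * (1 + self.target_at_skew) / 2,
            "T": at * (1 - self.target_at_skew) / 2,
            "G": gc * (1 + self.target_gc_skew) / 2,
            "C": gc * (1 - self.target_gc_skew) / 2,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "repeat_spec" in raw and raw["repeat_spec"] is not None:
            raw["repeat_spec"] = tuple(raw["repeat_spec"])
        return cls(**raw)


@dataclass
class GroundTruthLedger:
    """Everything needed to recheck the simulation without re-running it."""

    tree: str
    base_freqs: dict[str, float]
    repeat: dict | None                 # planted repeat, D-loop-local coords
    branch_events: dict[str, dict]      # child label -> accepted event counts
    config: dict

    def to_json(self) -> str:
        return json.dumps({
            "tree": self.tree,
            "base_freqs": self.base_freqs,
            "repeat": self.repeat,
            "branch_events": self.branch_events,
            "config": self.config,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthLedger":
        d = json.loads(text)
        return cls(tree=d["tree"], base_freqs=d["base_freqs"],
                   repeat=d["repeat"], branch_events=d["branch_events"],
                   config=d["config"])


# ---------------------------------------------------------------------------
# Root genome construction


def _sample_bases(rng: np.random.Generator, n: int, freqs: dict[str, float]) -> str:
    probs = np.array([freqs[b] for b in _BASES])
    probs = probs / probs.sum()
    return "".join(np.asarray(list(_BASES))[rng.choice(4, size=n, p=probs)])


def _sample_sense_codon(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    while True:
        codon = _sample_bases(rng, 3, freqs)
        if codon not in STOP_CODONS:
            return codon


def _build_cds(rng: np.random.Generator, gene: str, size: int,
               freqs: dict[str, float]) -> str:
    """A stop-free coding-strand CDS of exactly ``size`` bp with the
    conventional start and (possibly incomplete) terminal codon."""
    rem = size % 3
    stop = {1: "T", 2: "TA"}.get(rem) or _FULL_STOPS.get(gene, "TAA")
    n_sense = (size - len(stop)) // 3
    if n_sense < 2:
        raise ValueError(f"{gene}: size {size} cannot hold an ORF")
    codons = [_START_OF.get(gene, "ATG")]
    codons += [_sample_sense_codon(rng, freqs) for _ in range(n_sense - 1)]
    cds = "".join(codons) + stop
    assert len(cds) == size
    return cds


def _complement_freqs(freqs: dict[str, float]) -> dict[str, float]:
    return {b: freqs[_COMPLEMENT[b]] for b in _BASES}


def _build_ol(rng: np.random.Generator, size: int, freqs: dict[str, float]) -> str:
    offset = (size - len(_OL_MOTIF)) // 2
    for _ in range(1000):
        seq = _sample_bases(rng, size, freqs)
        seq = seq[:offset] + _OL_MOTIF + seq[offset + len(_OL_MOTIF):]
        if seq.count(_OL_MOTIF) == 1:
            return seq
    raise RuntimeError("could not build OL with a unique motif")


def _build_dloop(rng: np.random.Generator, size: int, freqs: dict[str, float],
                 repeat_spec: tuple[int, float, float] | None
                 ) -> tuple[str, dict | None]:
    seq = list(_sample_bases(rng, size, freqs))
    if repeat_spec is None:
        return "".join(seq), None
    period, copies, noise = repeat_spec
    span = round(copies * period)
    if span + 40 > size:
        raise ValueError(
            f"repeat of {span} bp does not fit a {size} bp control region")
    unit = _sample_bases(rng, period, freqs)
    offset = min(100, (size - span) // 2)  # 0-based position inside the D-loop
    array = []
    while len("".join(array)) < span:
        copy = [(_sample_bases(rng, 1, freqs) if rng.random() < noise else b)
                for b in unit]
        array.append("".join(copy))
    arr = "".join(array)[:span]
    seq[offset:offset + span] = list(arr)
    planted = {"start": offset + 1, "period": int(period),
               "copies": round(span / period, 3), "unit": unit,
               "noise": noise, "span": span}
    return "".join(seq), planted


def generate_root_genome(cfg: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> tuple[Mitogenome, GroundTruthLedger]:
    """Build the ancestral mitogenome (and the start of its ledger)."""
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = cfg.base_freqs
    features: list[GeneFeature] = []
    chunks: list[str] = []
    pos = 1
    planted_repeat = None
    for name, category, strand, letter in registry.CANONICAL_ORDER:
        size = cfg.gene_length_profile[name]
        if category == "PCG":
            coding_freqs = freqs if strand == "H" else _complement_freqs(freqs)
            cds = _build_cds(rng, name, size, coding_freqs)
            chunk = cds if strand == "H" else reverse_complement(cds)
        elif category == "origin":
            chunk = _build_ol(rng, size, freqs)
        elif category == "control":
            chunk, planted_repeat = _build_dloop(rng, size, freqs, cfg.repeat_spec)
        else:
            chunk = _sample_bases(rng, size, freqs)
        chunks.append(chunk)
        features.append(GeneFeature(name=name, start=pos, end=pos + size - 1,
                                    strand=strand, category=category,
                                    letter_code=letter))
        pos += size
    table = GeneTable(features=features)
    genome = Mitogenome(sequence="".join(chunks), table=table,
                        species="synthetic root", accession="ROOT")
    ledger = GroundTruthLedger(
        tree=cfg.tree, base_freqs=freqs, repeat=planted_repeat,
        branch_events={},
        config={"seed": cfg.seed, "omega": cfg.omega, "kappa": cfg.kappa,
                "target_at_content": cfg.target_at_content,
                "target_at_skew": cfg.target_at_skew,
                "target_gc_skew": cfg.target_gc_skew})
    return genome, ledger


# ---------------------------------------------------------------------------
# Evolution along a tree


def _propose_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    others = [b for b in _BASES if b != base]
    weights = np.array([kappa if _TRANSITION[base] == b else 1.0 for b in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def _evolve_cds(rng: np.random.Generator, cds: str, branch_length: float,
                omega: float, kappa: float, counts: dict) -> str:
    """Codon-level rejection sampling; start codon and terminus held fixed."""
    rem = len(cds) % 3
    stop_len = rem if rem else 3
    body = list(cds[:len(cds) - stop_len])
    mutable_lo = 3  # keep the initiation codon
    n_sites = len(body) - mutable_lo
    n_events = rng.poisson(branch_length * n_sites)
    for _ in range(n_events):
        site = mutable_lo + int(rng.integers(n_sites))
        old = body[site]
        new = _propose_base(rng, old, kappa)
        codon_i = site // 3
        codon = body[codon_i * 3:codon_i * 3 + 3]
        new_codon = "".join(codon[:site % 3] + [new] + codon[site % 3 + 1:])
        if new_codon in STOP_CODONS:
            counts["rejected_stop"] += 1
            continue
        old_codon = "".join(codon)
        synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]
        if synonymous:
            body[site] = new
            counts["syn"] += 1
        elif rng.random() < omega:
            body[site] = new
            counts["nonsyn"] += 1
        else:
            counts["rejected_nonsyn"] += 1
    return "".join(body) + cds[len(cds) - stop_len:]


def _evolve_neutral(rng: np.random.Generator, seq: str, branch_length: float,
                    kappa: float, counts: dict) -> str:
    s = list(seq)
    n_events = rng.poisson(branch_length * len(s))
    for _ in range(n_events):
        site = int(rng.integers(len(s)))
        s[site] = _propose_base(rng, s[site], kappa)
        counts["noncoding"] += 1
    return "".join(s)


def _evolve_branch(rng: np.random.Generator, genome: Mitogenome,
                   branch_length: float, cfg: SimulationConfig) -> tuple[Mitogenome, dict]:
    counts = {"syn": 0, "nonsyn": 0, "noncoding": 0,
              "rejected_stop": 0, "rejected_nonsyn": 0}
    chunks = []
    for f in genome.table:
        sub = genome.sequence[f.start - 1:f.end]
        if f.category == "PCG":
            cds = sub if f.strand == "H" else reverse_complement(sub)
            cds = _evolve_cds(rng, cds, branch_length, cfg.omega, cfg.kappa, counts)
            chunks.append(cds if f.strand == "H" else reverse_complement(cds))
        else:
            chunks.append(_evolve_neutral(rng, sub, branch_length, cfg.kappa, counts))
    child = Mitogenome(sequence="".join(chunks), table=genome.table,
                       species=genome.species, accession=genome.accession)
    return child, counts


def evolve_on_tree(root: Mitogenome, cfg: SimulationConfig,
                   ledger: GroundTruthLedger | None = None,
                   rng: np.random.Generator | None = None
                   ) -> tuple[dict[str, Mitogenome], GroundTruthLedger]:
    """Evolve the root genome down the configured tree; returns leaf genomes
    keyed by taxon label plus the completed ledger."""
    import dendropy
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if ledger is None:
        _, ledger = generate_root_genome(cfg)  # fresh ledger scaffold (unused genome)
    dtree = dendropy.Tree.get(data=cfg.tree, schema="newick")
    leaves: dict[str, Mitogenome] = {}

    def walk(node, genome: Mitogenome, label: str) -> None:
        for idx, child in enumerate(node.child_nodes()):
            bl = child.edge.length or 0.0
            child_label = (child.taxon.label if child.is_leaf()
                           else f"{label}.{idx}")
            child_genome, counts = _evolve_branch(rng, genome, bl, cfg)
            ledger.branch_events[child_label] = {"branch_length": bl, **counts}
            if child.is_leaf():
                name = child.taxon.label
                leaves[name] = Mitogenome(sequence=child_genome.sequence,
                                          table=genome.table,
                                          species=f"synthetic {name}",
                                          accession=name)
            else:
                walk(child, child_genome, child_label)

    walk(dtree.seed_node, root, "root")
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    return leaves, ledger


def simulate(cfg: SimulationConfig) -> tuple[dict[str, Mitogenome], GroundTruthLedger]:
    """Root construction + evolution in one deterministic call."""
    rng = np.random.default_rng(cfg.seed)
    root, ledger = generate_root_genome(cfg, rng)
    return evolve_on_tree(root, cfg, ledger, rng)


# ---------------------------------------------------------------------------
# Emission


_GB_TYPE = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
            "origin": "rep_origin", "control": "D-loop"}


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.accession or "SYN",
                       name=(genome.accession or "SYN")[:16],
                       description=genome.species,
                       annotations={"molecule_type": "DNA",
                                    "topology": "circular"})
    for f in genome.table:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "L" else 1)
        qualifiers = {"gene": [f.name]}
        if f.category == "PCG":
            qualifiers["transl_table"] = ["2"]
        record.features.append(SeqFeature(loc, type=_GB_TYPE[f.category],
                                          qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


def emit(leaves: dict[str, Mitogenome], ledger: GroundTruthLedger,
         outdir: str | Path) -> dict[str, dict[str, Path]]:
    """Write per-taxon FASTA + feature TSV + GenBank plus the ledger JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, dict[str, Path]] = {}
    for taxon, genome in sorted(leaves.items()):
        paths = {
            "fasta": outdir / f"{taxon}.fasta",
            "tsv": outdir / f"{taxon}.features.tsv",
            "genbank": outdir / f"{taxon}.gb",
        }
        write_fasta(genome, paths["fasta"])
        write_feature_table(genome.table, paths["tsv"])
        write_genbank(genome, paths["genbank"])
        written[taxon] = paths
    ledger_path = outdir / "ledger.json"
    ledger_path.write_text(ledger.to_json() + "\n")
    written["_ledger"] = {"json": ledger_path}
    return written
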