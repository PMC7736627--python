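"""Codon extraction and usage statistics under the vertebrate mitochondrial
genetic code (NCBI translation table 2).

Mitochondrial CDSs frequently end on an incomplete stop codon — a terminal T
or TA completed to TAA by post-transcriptional polyadenylation — so codon
bookkeeping here is driven by feature length mod 3: remainder 1 means a
trailing ``T``, remainder 2 a trailing ``TA``, remainder 0 a complete
terminal codon (which is treated as the stop when it is one under table 2).
Sense-codon counts include the initiation codon and exclude the stop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .genome_model import GeneFeature, Mitogenome, extract_region

_TABLE2 = CodonTable.unambiguous_dna_by_id[2]
#: codon -> one-letter amino acid, stops mapped to '*' (vertebrate mito code)
CODON_TO_AA: dict[str, str] = dict(_TABLE2.forward_table)
for _stop in _TABLE2.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS: frozenset[str] = frozenset(_TABLE2.stop_codons)  # TAA TAG AGA AGG
START_CODONS: frozenset[str] = frozenset(_TABLE2.start_codons)

#: amino acid -> synonymous codon family, Leu and Ser split into the two-
#: versus four-fold sub-families conventional on RSCU plots (L1=Leu(UUR),
#: L2=Leu(CUN), S1=Ser(UCN), S2=Ser(AGY))
SPLIT_FAMILIES: dict[str, tuple[str, ...]] = {}
POOLED_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    if _aa == "*":
        continue
    POOLED_FAMILIES.setdefault(_aa, ())
    POOLED_FAMILIES[_aa] += (_codon,)
    if _aa == "L":
        key = "L1" if _codon.startswith("TT") else "L2"
    elif _aa == "S":
        key = "S2" if _codon.startswith("AG") else "S1"
    else:
        key = _aa
    SPLIT_FAMILIES.setdefault(key, ())
    SPLIT_FAMILIES[key] += (_codon,)


class InternalStopError(ValueError):
    """A PCG contains an in-frame stop codon before its terminus."""


@dataclass
class PcgCodingRecord:
    """Codon-level reading of one protein-coding gene on its coding strand."""

    gene: str
    codons: list[str]          # sense codons: initiation included, stop excluded
    start_codon: str
    stop_codon: str            # full triplet, or incomplete "TA" / "T"

    @property
    def aa_length(self) -> int:
        return len(self.codons)


def extract_coding_record(genome: Mitogenome, f: GeneFeature) -> PcgCodingRecord:
    """Read a PCG's codons from the genome, resolving incomplete stops.

    Raises :class:`InternalStopError` if a stop codon occurs before the
    terminus (a frame or annotation error)."""
    if f.category != "PCG":
        raise ValueError(f"{f.name} is not a protein-coding gene")
    seq = extract_region(genome, f, orient="as-annotated")
    return coding_record_from_sequence(f.name, seq)


def coding_record_from_sequence(gene: str, seq: str) -> PcgCodingRecord:
    """As :func:`extract_coding_record`, from an explicit coding-strand CDS."""
    n = len(seq)
    if n < 6:
        raise ValueError(f"{gene}: CDS of {n} bp is too short")
    rem = n % 3
    if rem == 0:
        body, stop = seq[:-3], seq[-3:]
        if stop not in STOP_CODONS:
            # no terminal stop at all: every codon is sense
            body, stop = seq, ""
    else:
        body, stop = seq[:n - rem], seq[n - rem:]
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    for idx, codon in enumerate(codons):
        if CODON_TO_AA.get(codon) == "*":
            raise InternalStopError(
                f"{gene}: internal stop codon {codon} at codon {idx + 1}")
    return PcgCodingRecord(gene=gene, codons=codons,
                           start_codon=codons[0], stop_codon=stop)


def translate(codons: list[str] | str, initiation: bool = True) -> str:
    """Translate codons under the vertebrate mitochondrial code.

    Non-ATG initiation codons recognized by table 2 (GTG, ATA, ...) are
    rendered as Met at position 1 when ``initiation`` is true; non-ACGT
    triplets become ``X``."""
    if isinstance(codons, str):
        if len(codons) % 3:
            raise ValueError("sequence length not a multiple of 3")
        codons = [codons[i:i + 3] for i in range(0, len(codons), 3)]
    out = []
    for i, codon in enumerate(codons):
        aa = CODON_TO_AA.get(codon, "X")
        if i == 0 and initiation and codon in START_CODONS:
            aa = "M"
        out.append(aa)
    return "".join(out)


@dataclass
class CodonCountTable:
    """Sense-codon counts pooled over a set of coding records."""

    counts: Counter = field(default_factory=Counter)
    stop_counts: Counter = field(default_factory=Counter)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def add_record(self, record: PcgCodingRecord) -> None:
        self.counts.update(record.codons)
        if record.stop_codon:
            self.stop_counts[record.stop_codon] += 1

    @classmethod
    def from_records(cls, records) -> "CodonCountTable":
        table = cls()
        for r in records:
            table.add_record(r)
        return table

    @classmethod
    def from_genome(cls, genome: Mitogenome) -> "CodonCountTable":
        return cls.from_records(extract_coding_record(genome, f)
                                for f in genome.table.pcgs)


def rscu(table: CodonCountTable, split_leu_ser: bool = True
         ) -> dict[str, tuple[str, float, bool]]:
    """Relative synonymous codon usage.

    RSCU of codon j in family i is X_ij / mean(X over family i), i.e.
    n_i·X_ij / ΣX; a family observed zero times gets RSCU 0 for each codon
    with the ``undefined`` flag set. Returns codon -> (family label, RSCU,
    undefined)."""
    families = SPLIT_FAMILIES if split_leu_ser else POOLED_FAMILIES
    out: dict[str, tuple[str, float, bool]] = {}
    for fam, codons in families.items():
        total = sum(table.counts.get(c, 0) for c in codons)
        for c in codons:
            if total == 0:
                out[c] = (fam, 0.0, True)
            else:
                out[c] = (fam, len(codons) * table.counts.get(c, 0) / total, False)
    return out


def aa_usage(table: CodonCountTable) -> dict[str, int]:
    """Amino-acid usage counts by one-letter residue; Leu and Ser are also
    reported split by sub-family (keys ``L1``/``L2``, ``S1``/``S2``) alongside
    the pooled ``L``/``S`` totals."""
    out: dict[str, int] = {}
    for fam, codons in SPLIT_FAMILIES.items():
        out[fam] = sum(table.counts.get(c, 0) for c in codons)
    out["L"] = out.get("L1", 0) + out.get("L2", 0)
    out["S"] = out.get("S1", 0) + out.get("S2", 0)
    return out


def expected_sense_codons(size_bp: int, has_complete_stop: bool) -> int:
    """Sense-codon count implied by a CDS length: floor((size − incomplete)/3)
    minus the full stop when the length is a clean multiple of 3."""
    rem = size_bp % 3
    if rem:
        return (size_bp - rem) // 3
    return size_bp // 3 - (1 if has_complete_stop else 0)
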