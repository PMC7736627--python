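"""Base composition, A+T content, and strand-asymmetry (AT/GC skew) summaries.

Skews follow the standard definitions AT-skew = (A − T)/(A + T) and
GC-skew = (G − C)/(G + C), computed on the strand the sequence is given on.
IUPAC ambiguity codes are excluded from the four base counts and from the
skew denominators and reported separately, so a partly ambiguous region never
silently shifts a skew.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from .genome_model import GeneTable, Mitogenome, extract_region
from .codon_usage import extract_coding_record

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class CompositionSummary:
    """Base counts plus derived content/skew statistics for one sequence.

    ``at_skew``/``gc_skew`` are ``None`` when the corresponding denominator is
    zero (undefined, not zero)."""

    a: int
    c: int
    g: int
    t: int
    n_ambiguous: int = 0

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t + self.n_ambiguous

    @property
    def at_content(self) -> float | None:
        """Percent A+T among unambiguous bases."""
        denom = self.a + self.c + self.g + self.t
        return 100.0 * (self.a + self.t) / denom if denom else None

    @property
    def at_skew(self) -> float | None:
        return (self.a - self.t) / (self.a + self.t) if (self.a + self.t) else None

    @property
    def gc_skew(self) -> float | None:
        return (self.g - self.c) / (self.g + self.c) if (self.g + self.c) else None

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(self.a + other.a, self.c + other.c,
                                  self.g + other.g, self.t + other.t,
                                  self.n_ambiguous + other.n_ambiguous)


def composition(seq: str) -> CompositionSummary:
    """Count bases and derive AT%, AT-skew and GC-skew for one sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    counts = {b: s.count(b) for b in "ACGT"}
    known = sum(counts.values())
    bad = set(s) - set(_IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC symbols in sequence: {sorted(bad)}")
    return CompositionSummary(counts["A"], counts["C"], counts["G"], counts["T"],
                              n_ambiguous=len(s) - known)


def partition_composition(genome: Mitogenome, scope: str = "whole",
                          ) -> list[tuple[str, CompositionSummary]]:
    """Labeled composition summaries over a genome partition.

    scope:
      * ``whole`` — one summary for the full H-strand sequence;
      * ``category`` — one pooled summary per element category (H-strand);
      * ``feature`` — one summary per annotated element (H-strand);
      * ``codon-position`` — the 13 PCGs concatenated on their *coding*
        strands in table order, incomplete terminal stop bases excluded,
        split into first/second/third codon positions.
    """
    if not genome.sequence:
        raise ValueError("mitogenome has no sequence")
    if scope == "whole":
        return [("whole", composition(genome.sequence))]
    if scope == "feature":
        return [(f.name, composition(extract_region(genome, f, "h-strand")))
                for f in genome.table]
    if scope == "category":
        out: dict[str, CompositionSummary] = {}
        for f in genome.table:
            summary = composition(extract_region(genome, f, "h-strand"))
            out[f.category] = out[f.category] + summary if f.category in out else summary
        return list(out.items())
    if scope == "codon-position":
        pos_seqs = {1: [], 2: [], 3: []}
        for f in genome.table.pcgs:
            record = extract_coding_record(genome, f)
            codons = list(record.codons)
            if len(record.stop_codon) == 3:  # complete stops in, partial T/TA out
                codons.append(record.stop_codon)
            for codon in codons:
                for i in (1, 2, 3):
                    pos_seqs[i].append(codon[i - 1])
        return [(f"position_{i}", composition("".join(pos_seqs[i]))) for i in (1, 2, 3)]
    raise ValueError(f"unknown scope {scope!r}")


def _iupac_regex(motif: str) -> re.Pattern[str]:
    parts = []
    for sym in motif.upper():
        if sym not in _IUPAC:
            raise ValueError(f"invalid IUPAC symbol {sym!r} in motif")
        opts = _IUPAC[sym]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


def motif_scan(seq: str, motif: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) exact matches of
    an IUPAC motif on the given strand."""
    if not motif:
        raise ValueError("empty motif")
    pattern = _iupac_regex(motif)
    s = seq.upper()
    hits, pos = [], 0
    while True:
        m = pattern.search(s, pos)
        if m is None:
            return hits
        hits.append(m.start() + 1)
        pos = m.start() + 1
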