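"""Mitogenome data model: gene features, feature tables, coordinate arithmetic.

Coordinates are 1-based inclusive throughout, matching how mitogenome
annotation tables are published; conversion to 0-based half-open happens only
inside sequence-slicing code. Features never wrap around the circular origin
in this model (the canonical vertebrate layout starts at tRNA-Phe and ends
with the D-loop at the genome's last base); a wrap-around feature is rejected
with a clear error rather than silently mis-sliced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

from . import registry
from .registry import CATEGORIES, CANONICAL_NAMES, UnknownElementError

TSV_COLUMNS = ("name", "start", "end", "strand", "category", "letter_code")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element: a PCG, tRNA, rRNA, the OL, or the control region.

    ``start``/``end`` are 1-based inclusive positions on the heavy strand;
    ``strand`` is ``"H"`` or ``"L"`` (the element's coding strand).
    """

    name: str
    start: int
    end: int
    strand: str
    category: str
    letter_code: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"{self.name}: end {self.end} < start {self.start} "
                "(wrap-around features are not supported)")
        if self.strand not in ("H", "L"):
            raise ValueError(f"{self.name}: strand must be 'H' or 'L', got {self.strand!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


def feature_size(f: GeneFeature) -> int:
    """Length of the feature in bp (end − start + 1, both ends inclusive)."""
    return f.end - f.start + 1


def intervening_spacer(f1: GeneFeature, f2: GeneFeature) -> int:
    """Signed gap between two features in table order.

    Positive: intervening sequence between adjacent elements; negative: the
    elements overlap by that many bp; zero: exactly contiguous.
    """
    if f2.start < f1.start:
        raise ValueError(f"{f1.name} does not precede {f2.name} in table order")
    return f2.start - f1.end - 1


@dataclass
class GeneTable:
    """Ordered annotation table of one mitogenome (the in-memory gene table)."""

    features: list[GeneFeature] = field(default_factory=list)
    genome_length: int = 0

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        if self.features:
            inferred = max(f.end for f in self.features)
            if self.genome_length == 0:
                self.genome_length = inferred
            elif self.genome_length < inferred:
                raise ValueError(
                    f"genome_length {self.genome_length} < max feature end {inferred}")

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> GeneFeature:
        canon = registry.canonical_name(name)
        for f in self.features:
            if f.name == canon:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
            return True
        except (KeyError, UnknownElementError):
            return False

    def by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    @property
    def pcgs(self) -> list[GeneFeature]:
        """The 13 protein-coding genes in canonical order."""
        order = {n: i for i, n in enumerate(CANONICAL_NAMES)}
        return sorted(self.by_category("PCG"), key=lambda f: order.get(f.name, 99))

    def spacers(self) -> list[tuple[str, str, int]]:
        """(name_i, name_{i+1}, spacer) for every adjacent pair in table order."""
        out = []
        for f1, f2 in zip(self.features, self.features[1:]):
            out.append((f1.name, f2.name, intervening_spacer(f1, f2)))
        return out


@dataclass
class ComplementReport:
    """Result of checking a table against the canonical 39-element complement."""

    counts: dict[str, int]
    missing: list[str]
    duplicated: list[str]
    unexpected: list[str]

    @property
    def is_complete(self) -> bool:
        return not self.missing and not self.duplicated

    @property
    def n_genes(self) -> int:
        """Gene count in the conventional sense: PCGs + tRNAs + rRNAs (37 when
        complete; OL and the control region are elements, not genes)."""
        return self.counts["PCG"] + self.counts["tRNA"] + self.counts["rRNA"]


def validate_gene_complement(table: GeneTable) -> ComplementReport:
    """Count elements per category and flag deviations from the canonical
    vertebrate complement (13 PCGs, 22 tRNAs incl. two Leu and two Ser, 2
    rRNAs, one OL, one control region). Reports, never raises."""
    counts = {c: 0 for c in CATEGORIES}
    seen: dict[str, int] = {}
    unexpected: list[str] = []
    for f in table:
        counts[f.category] = counts.get(f.category, 0) + 1
        if f.name in CANONICAL_NAMES:
            seen[f.name] = seen.get(f.name, 0) + 1
        else:
            unexpected.append(f.name)
    missing = [n for n in CANONICAL_NAMES if n not in seen]
    duplicated = [n for n, k in seen.items() if k > 1]
    return ComplementReport(counts=counts, missing=missing,
                            duplicated=duplicated, unexpected=unexpected)


@dataclass
class Mitogenome:
    """A circular mitochondrial genome: H-strand sequence plus annotation."""

    sequence: str
    table: GeneTable
    species: str = ""
    accession: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.sequence and self.table.genome_length and \
                len(self.sequence) != self.table.genome_length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != table genome_length "
                f"{self.table.genome_length}")

    def __len__(self) -> int:
        return len(self.sequence)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_region(genome: Mitogenome, f: GeneFeature,
                   orient: str = "as-annotated") -> str:
    """Slice a feature's sequence.

    orient="h-strand" returns the H-strand substring as stored;
    orient="as-annotated" reverse-complements L-strand features so the result
    reads 5'→3' on the element's own coding strand.
    """
    if orient not in ("as-annotated", "h-strand"):
        raise ValueError(f"orient must be 'as-annotated' or 'h-strand', got {orient!r}")
    if not genome.sequence:
        raise ValueError("mitogenome has no sequence")
    if f.end > len(genome.sequence):
        raise ValueError(
            f"{f.name}: end {f.end} beyond genome length {len(genome.sequence)}")
    sub = genome.sequence[f.start - 1:f.end]
    if orient == "as-annotated" and f.strand == "L":
        return reverse_complement(sub)
    return sub


# ---------------------------------------------------------------------------
# File dialects

class FeatureTableParseError(ValueError):
    pass


def read_feature_table(path: str | Path, dialect: str = "tsv") -> GeneTable:
    """Read a gene table from TSV (columns name/start/end/strand/category/
    letter_code; extra columns ignored) or from a GenBank flat file."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "genbank":
        return read_genbank(path).table
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_tsv(path: Path) -> GeneTable:
    features: list[GeneFeature] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "start", "end", "strand", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise FeatureTableParseError(
                f"{path}: header must contain columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                name = registry.canonical_name(row["name"])
            except UnknownElementError as exc:
                raise FeatureTableParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                features.append(GeneFeature(
                    name=name,
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"].strip(),
                    category=row["category"].strip(),
                    letter_code=(row.get("letter_code") or "").strip(),
                ))
            except (KeyError, ValueError) as exc:
                raise FeatureTableParseError(f"{path}:{lineno}: {exc}") from exc
    return GeneTable(features=features)


def write_feature_table(table: GeneTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for f in table:
            writer.writerow([f.name, f.start, f.end, f.strand, f.category, f.letter_code])


_GB_CATEGORY = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "rep_origin": "origin", "D-loop": "control", "misc_feature": None}


def read_genbank(path: str | Path) -> Mitogenome:
    """Read a mitogenome (sequence + features) from a GenBank flat file.

    CDS/tRNA/rRNA/rep_origin/D-loop features are mapped into the model;
    strand +/− maps to H/L. Unresolvable feature labels raise."""
    record = SeqIO.read(str(path), "genbank")
    features: list[GeneFeature] = []
    for feat in record.features:
        category = _GB_CATEGORY.get(feat.type)
        if feat.type not in _GB_CATEGORY or category is None:
            continue
        label = (feat.qualifiers.get("gene") or feat.qualifiers.get("product")
                 or feat.qualifiers.get("note") or [feat.type])[0]
        name = registry.canonical_name(label)
        features.append(GeneFeature(
            name=name,
            start=int(feat.location.start) + 1,
            end=int(feat.location.end),
            strand="L" if feat.location.strand == -1 else "H",
            category=category,
            letter_code=registry.LETTER_OF.get(name, ""),
        ))
    table = GeneTable(features=features)
    return Mitogenome(sequence=str(record.seq), table=table,
                      species=record.annotations.get("organism", ""),
                      accession=record.id)


def write_fasta(genome: Mitogenome, path: str | Path) -> None:
    header = genome.accession or genome.species or "mitogenome"
    desc = genome.species if genome.accession else ""
    with open(path, "w") as fh:
        fh.write(f">{header}{' ' + desc if desc else ''}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


def read_fasta(path: str | Path, table: GeneTable | None = None) -> Mitogenome:
    record = next(SeqIO.parse(str(path), "fasta"))
    return Mitogenome(sequence=str(record.seq), table=table or GeneTable(),
                      species=record.description.partition(" ")[2],
                      accession=record.id)
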