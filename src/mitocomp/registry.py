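"""Canonical vocabulary for the 39 elements of a vertebrate mitogenome.

The fixed complement is 13 protein-coding genes, 22 tRNAs, 2 rRNAs, the
light-strand replication origin (OL) and the control region (D-loop).
Published tables use inconsistent labels (ATPase6 vs ATP6, Cyt b vs CYTB,
O_L vs OL), so every element has a frozen canonical name plus an alias set.
"""

from __future__ import annotations

# (canonical name, category, canonical H/L strand, tRNA letter code)
# in canonical vertebrate gene order: tRNA-Phe first, D-loop last.
CANONICAL_ORDER: tuple[tuple[str, str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "H", "F"),
    ("12S-rRNA", "rRNA", "H", ""),
    ("tRNA-Val", "tRNA", "H", "V"),
    ("16S-rRNA", "rRNA", "H", ""),
    ("tRNA-Leu(UUR)", "tRNA", "H", "L1"),
    ("ND1", "PCG", "H", ""),
    ("tRNA-Ile", "tRNA", "H", "I"),
    ("tRNA-Gln", "tRNA", "L", "Q"),
    ("tRNA-Met", "tRNA", "H", "M"),
    ("ND2", "PCG", "H", ""),
    ("tRNA-Trp", "tRNA", "H", "W"),
    ("tRNA-Ala", "tRNA", "L", "A"),
    ("tRNA-Asn", "tRNA", "L", "N"),
    ("OL", "origin", "H", ""),
    ("tRNA-Cys", "tRNA", "L", "C"),
    ("tRNA-Tyr", "tRNA", "L", "Y"),
    ("COI", "PCG", "H", ""),
    ("tRNA-Ser(UCN)", "tRNA", "L", "S1"),
    ("tRNA-Asp", "tRNA", "H", "D"),
    ("COII", "PCG", "H", ""),
    ("tRNA-Lys", "tRNA", "H", "K"),
    ("ATP8", "PCG", "H", ""),
    ("ATP6", "PCG", "H", ""),
    ("COIII", "PCG", "H", ""),
    ("tRNA-Gly", "tRNA", "H", "G"),
    ("ND3", "PCG", "H", ""),
    ("tRNA-Arg", "tRNA", "H", "R"),
    ("ND4L", "PCG", "H", ""),
    ("ND4", "PCG", "H", ""),
    ("tRNA-His", "tRNA", "H", "H"),
    ("tRNA-Ser(AGY)", "tRNA", "H", "S2"),
    ("tRNA-Leu(CUN)", "tRNA", "H", "L2"),
    ("ND5", "PCG", "H", ""),
    ("ND6", "PCG", "L", ""),
    ("tRNA-Glu", "tRNA", "L", "E"),
    ("CYTB", "PCG", "H", ""),
    ("tRNA-Thr", "tRNA", "H", "T"),
    ("tRNA-Pro", "tRNA", "L", "P"),
    ("D-loop", "control", "H", ""),
)

CANONICAL_NAMES: tuple[str, ...] = tuple(r[0] for r in CANONICAL_ORDER)
CATEGORY_OF: dict[str, str] = {r[0]: r[1] for r in CANONICAL_ORDER}
LETTER_OF: dict[str, str] = {r[0]: r[3] for r in CANONICAL_ORDER}
PCG_NAMES: tuple[str, ...] = tuple(n for n, c, _, _ in CANONICAL_ORDER if c == "PCG")
TRNA_NAMES: tuple[str, ...] = tuple(n for n, c, _, _ in CANONICAL_ORDER if c == "tRNA")
CATEGORIES: tuple[str, ...] = ("PCG", "tRNA", "rRNA", "origin", "control")

_ALIASES: dict[str, str] = {
    "ATPASE6": "ATP6", "ATPASE 6": "ATP6", "ATP SYNTHASE 6": "ATP6",
    "ATPASE8": "ATP8", "ATPASE 8": "ATP8",
    "CYT B": "CYTB", "CYTB": "CYTB", "COB": "CYTB", "CYT-B": "CYTB",
    "COX1": "COI", "CO1": "COI", "COX2": "COII", "CO2": "COII",
    "COX3": "COIII", "CO3": "COIII",
    "O_L": "OL", "OL": "OL", "REP_ORIGIN": "OL", "L-STRAND ORIGIN": "OL",
    "DLOOP": "D-loop", "D_LOOP": "D-loop", "CONTROL REGION": "D-loop",
    "12S": "12S-rRNA", "RRNS": "12S-rRNA", "12S RRNA": "12S-rRNA", "S-RRNA": "12S-rRNA",
    "16S": "16S-rRNA", "RRNL": "16S-rRNA", "16S RRNA": "16S-rRNA", "L-RRNA": "16S-rRNA",
    "TRNA-LEU1": "tRNA-Leu(UUR)", "TRNL1": "tRNA-Leu(UUR)", "TRNA-LEU(TAA)": "tRNA-Leu(UUR)",
    "TRNA-LEU2": "tRNA-Leu(CUN)", "TRNL2": "tRNA-Leu(CUN)", "TRNA-LEU(TAG)": "tRNA-Leu(CUN)",
    "TRNA-SER1": "tRNA-Ser(UCN)", "TRNS1": "tRNA-Ser(UCN)", "TRNA-SER(TGA)": "tRNA-Ser(UCN)",
    "TRNA-SER2": "tRNA-Ser(AGY)", "TRNS2": "tRNA-Ser(AGY)", "TRNA-SER(GCT)": "tRNA-Ser(AGY)",
}

# three-letter tRNA names that need no disambiguation, e.g. "trnF" / "tRNA-Phe"
_AA3 = {"Phe": "F", "Val": "V", "Ile": "I", "Gln": "Q", "Met": "M", "Trp": "W",
        "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y", "Asp": "D", "Lys": "K",
        "Gly": "G", "Arg": "R", "His": "H", "Glu": "E", "Thr": "T", "Pro": "P"}
for _aa, _letter in _AA3.items():
    _ALIASES[f"TRNA-{_aa}".upper()] = f"tRNA-{_aa}"
    _ALIASES[f"TRN{_letter}"] = f"tRNA-{_aa}"
for _name in CANONICAL_NAMES:
    _ALIASES.setdefault(_name.upper(), _name)


class UnknownElementError(ValueError):
    """Raised when a label cannot be resolved against the element registry."""


def canonical_name(label: str) -> str:
    """Resolve an element label (any known alias, case-insensitive) to its
    canonical name, or raise :class:`UnknownElementError`."""
    key = label.strip().upper().replace("_", "-") if label.strip().upper().startswith("TRNA") \
        else label.strip().upper()
    if key in _ALIASES:
        return _ALIASES[key]
    # tolerate underscores / stray whitespace in non-tRNA labels too
    key2 = key.replace("_", " ").strip()
    if key2 in _ALIASES:
        return _ALIASES[key2]
    raise UnknownElementError(f"unknown mitogenome element label: {label!r}")


def is_known(label: str) -> bool:
    try:
        canonical_name(label)
        return True
    except UnknownElementError:
        return False
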