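"""Bundled reference annotation: the published gene/element feature tables of
the three Sebastiscus rockfish mitogenomes.

The TSV shipped with the package transcribes, for each of the 39 elements,
the annotated start/end coordinates of *S. tertius* (ST, MT117231),
*S. albofasciatus* (SA, MT117230) and *S. marmoratus* (SM, MT789709),
together with the table's printed Size and Intervening-spacer columns, the
per-PCG amino-acid counts and initiation/termination codons.

Six printed Size cells contradict the printed coordinates of their own rows
(the spacer column and the genome lengths corroborate the coordinates, so the
coordinates are taken as authoritative); they are frozen in
:data:`SIZE_ERRATA` as (element, species) -> (size from coordinates, printed
size).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import registry
from .genome_model import GeneFeature, GeneTable

SPECIES = ("ST", "SA", "SM")
SPECIES_FULL = {
    "ST": ("Sebastiscus tertius", "MT117231"),
    "SA": ("Sebastiscus albofasciatus", "MT117230"),
    "SM": ("Sebastiscus marmoratus", "MT789709"),
}

#: printed Size cells that are internally inconsistent with the printed
#: coordinates of the same row: (element, species) -> (computed, printed)
SIZE_ERRATA: dict[tuple[str, str], tuple[int, int]] = {
    ("tRNA-Tyr", "ST"): (71, 69),
    ("tRNA-Trp", "SA"): (72, 71),
    ("tRNA-Cys", "SA"): (67, 65),
    ("tRNA-Ser(UCN)", "SA"): (71, 69),
    ("tRNA-Ser(AGY)", "SA"): (68, 72),
    ("tRNA-Thr", "SA"): (72, 73),
}


def load_dataframe() -> pd.DataFrame:
    """The full bundled table as a DataFrame (one row per element)."""
    with resources.files("mitocomp.data").joinpath(
            "sebastiscus_gene_table.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"letter": "string", "aa": "Int64"},
                         keep_default_na=False, na_values=[""])
    return df


def gene_table(species: str) -> GeneTable:
    """The annotation of one species ('ST', 'SA' or 'SM') as a GeneTable."""
    sp = species.upper()
    if sp not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")
    df = load_dataframe()
    lo = sp.lower()
    features = [
        GeneFeature(
            name=registry.canonical_name(row["name"]),
            start=int(row[f"{lo}_start"]),
            end=int(row[f"{lo}_end"]),
            strand=row["strand"],
            category=row["category"],
            letter_code="" if pd.isna(row["letter"]) else str(row["letter"]),
        )
        for _, row in df.iterrows()
    ]
    return GeneTable(features=features)


def printed_sizes(species: str) -> dict[str, int]:
    """Element -> printed Size cell for one species."""
    df = load_dataframe()
    return {r["name"]: int(r[f"{species.lower()}_size"]) for _, r in df.iterrows()}


def printed_spacers(species: str) -> dict[str, int]:
    """Element -> printed Intervening-spacer cell (gap to the *next* element);
    the last element (D-loop) has none."""
    df = load_dataframe()
    col = f"{species.lower()}_spacer"
    return {r["name"]: int(r[col]) for _, r in df.iterrows() if pd.notna(r[col])}


def pcg_annotations(species: str) -> pd.DataFrame:
    """Per-PCG amino-acid count, initiation codon, and termination codon."""
    df = load_dataframe()
    pc = df[df["category"] == "PCG"].copy()
    pc["term"] = pc[f"{species.lower()}_term"]
    return pc[["name", "aa", "init", "term"]].reset_index(drop=True)
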