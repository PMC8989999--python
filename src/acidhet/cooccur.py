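"""Homolog-hit filtering, presence/absence matrices and co-occurrence summaries.

Protein BLAST hit tables are filtered with per-component e-value cutoffs
and a length tolerance (hit length within ±10% of the query length by
default), deduplicated to the best hit per species, and turned into a
species × component presence/absence matrix anchored on one component
(the antiporter of an acid-resistance system). Summaries report, for the
species carrying the anchor, the percentage that also carry each
regulator — the numbers annotated as rings around a homolog tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["HomologFilter", "DEFAULT_EVALUE_MAX", "filter_hits",
           "build_presence_matrix", "cooccurrence_summary",
           "conditional_cooccurrence", "taxonomy_summary", "write_itol_binary"]

#: Per-component BLAST expect-value cutoffs (strict upper bounds).
DEFAULT_EVALUE_MAX: dict[str, float] = {
    "GadC": 1e-100, "AdiC": 1e-120, "CadB": 1e-120,
    "GadE": 1e-20, "CsiR": 1e-50, "YdeO": 1e-60, "GadB": 1e-80,
    "GadW": 1e-100, "GadX": 1e-100, "EvgS": 1e-170,
    "AdiA": 1e-170, "AdiY": 1e-100,
    "CadA": 1e-170, "CadC": 1e-100, "LysP": 1e-120,
    "GadY": 1e-20,
}

REQUIRED_HIT_COLUMNS = ["component", "species_id", "accession",
                        "evalue", "hit_length", "query_length"]


@dataclass(frozen=True)
class HomologFilter:
    """E-value and length gates applied to BLAST hits.

    ``length_tolerance`` keeps hits whose aligned length is within
    ±tolerance × query length (two-sided).
    """

    evalue_max: dict = field(default_factory=lambda: dict(DEFAULT_EVALUE_MAX))
    length_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.length_tolerance < 1.0:
            raise ValueError("length_tolerance must be in [0, 1)")
        if any(e <= 0 for e in self.evalue_max.values()):
            raise ValueError("e-value cutoffs must be > 0")


def filter_hits(raw_hits: pd.DataFrame,
                filt: HomologFilter | None = None) -> pd.DataFrame:
    """Filter a homolog hit table and deduplicate to one best hit per species.

    Keeps rows with ``evalue < cutoff(component)`` and
    ``|hit_length − query_length| <= tolerance × query_length``; retains
    the lowest-e-value hit per (component, species_id). Raises ``KeyError``
    for a component without a configured cutoff.
    """
    filt = filt or HomologFilter()
    missing = [c for c in REQUIRED_HIT_COLUMNS if c not in raw_hits.columns]
    if missing:
        raise KeyError(f"hit table missing columns: {missing}")
    if raw_hits.empty:
        return raw_hits.copy()
    unknown = sorted(set(raw_hits["component"]) - set(filt.evalue_max))
    if unknown:
        raise KeyError(f"no e-value cutoff configured for: {unknown}")
    cutoff = raw_hits["component"].map(filt.evalue_max)
    ok_e = raw_hits["evalue"] < cutoff
    dev = (raw_hits["hit_length"] - raw_hits["query_length"]).abs()
    ok_len = dev <= filt.length_tolerance * raw_hits["query_length"]
    kept = raw_hits[ok_e & ok_len]
    kept = kept.sort_values("evalue", kind="mergesort")
    return (kept.drop_duplicates(subset=["component", "species_id"], keep="first")
                .sort_index().reset_index(drop=True))


def build_presence_matrix(tables: dict[str, pd.DataFrame],
                          anchor: str) -> pd.DataFrame:
    """Presence/absence matrix over the species that carry the anchor.

    ``tables`` maps component name -> filtered hit table (or any table with
    a ``species_id`` column). One row per anchor species; flag 1 iff the
    species appears in that component's table.
    """
    if anchor not in tables:
        raise KeyError(f"anchor {anchor!r} not among components {sorted(tables)}")
    anchor_species = pd.Index(sorted(tables[anchor]["species_id"].unique()),
                              name="species_id")
    if anchor_species.empty:
        raise ValueError("anchor table is empty")
    matrix = pd.DataFrame(index=anchor_species)
    matrix[anchor] = 1
    for comp, table in tables.items():
        if comp == anchor:
            continue
        present = set(table["species_id"])
        matrix[comp] = [int(s in present) for s in anchor_species]
    return matrix


def cooccurrence_summary(matrix: pd.DataFrame) -> pd.Series:
    """Percentage of anchor species carrying each component (column)."""
    if matrix.empty:
        raise ValueError("presence matrix is empty")
    return 100.0 * matrix.mean(axis=0)


def conditional_cooccurrence(matrix: pd.DataFrame, given: str,
                             target: str) -> float:
    """Percentage of ``given``-positive species that are ``target``-positive."""
    sub = matrix[matrix[given] == 1]
    if sub.empty:
        raise ValueError(f"no species with {given!r} present")
    return float(100.0 * sub[target].mean())


def taxonomy_summary(table: pd.DataFrame, rank: str = "family") -> pd.Series:
    """Fraction of species per taxon at the chosen rank, sorted descending.

    Species without a label are grouped as ``"unassigned"``; fractions sum
    to 1 over the unique species in the table.
    """
    if table.empty:
        return pd.Series(dtype=float)
    if rank not in table.columns:
        raise KeyError(f"taxonomy column {rank!r} not present")
    species = table.drop_duplicates(subset="species_id")
    labels = species[rank].fillna("unassigned").replace("", "unassigned")
    frac = labels.value_counts(normalize=True)
    return frac.sort_values(ascending=False)


def write_itol_binary(matrix: pd.DataFrame, path, dataset_label: str = "presence",
                      colors: list[str] | None = None) -> None:
    """Write an iTOL binary-dataset annotation file from a presence matrix."""
    cols = list(matrix.columns)
    if colors is None:
        palette = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e",
                   "#e6ab02", "#a6761d", "#666666"]
        colors = [palette[i % len(palette)] for i in range(len(cols))]
    lines = [
        "DATASET_BINARY",
        "SEPARATOR TAB",
        f"DATASET_LABEL\t{dataset_label}",
        "COLOR\t#000000",
        "FIELD_SHAPES\t" + "\t".join(["2"] * len(cols)),
        "FIELD_LABELS\t" + "\t".join(cols),
        "FIELD_COLORS\t" + "\t".join(colors),
        "DATA",
    ]
    for species, row in matrix.iterrows():
        flags = "\t".join(str(int(v)) for v in row[cols])
        lines.append(f"{species}\t{flags}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
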