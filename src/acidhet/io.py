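"""Shared readers and writers: cell tables, hit tables, FASTA, config."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_cell_table", "write_cell_table", "read_hits_table",
           "read_presence_table", "write_presence_table", "read_fasta",
           "write_fasta", "load_config", "read_image", "write_image"]

REQUIRED_CELL_COLUMNS = ["cell_id", "field"]

#: BLAST outfmt-6 style column names mapped onto the canonical hit schema.
_BLAST_ALIASES = {"qseqid": "component", "sseqid": "accession",
                  "length": "hit_length", "qlen": "query_length"}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell intensity table (CSV/TSV); unknown columns are kept."""
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise KeyError(f"cell table {path} missing required columns: {missing}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_hits_table(path) -> pd.DataFrame:
    """Read a homolog hit table (TSV with header, BLAST-style names accepted)."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={k: v for k, v in _BLAST_ALIASES.items()
                            if v not in df.columns})
    return df


def read_presence_table(path) -> pd.DataFrame:
    """Read a species x component 0/1 presence table (TSV, species_id column)."""
    df = pd.read_csv(path, sep="\t")
    if "species_id" not in df.columns:
        raise KeyError(f"presence table {path} missing 'species_id' column")
    return df.set_index("species_id")


def write_presence_table(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index=True)


def read_fasta(path) -> dict[str, str]:
    """Read (aligned) FASTA into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def load_config(path) -> dict:
    """Load a YAML (or TOML) run configuration."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def read_image(path) -> np.ndarray:
    from skimage.io import imread
    return np.asarray(imread(str(path)), dtype=float)


def write_image(image: np.ndarray, path) -> None:
    """Write a grayscale image as 16-bit TIFF/PNG (values clipped to uint16)."""
    from skimage.io import imsave
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    imsave(str(path), arr, check_contrast=False)
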