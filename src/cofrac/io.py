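"""Readers and writers for the tables a co-fractionation experiment touches.

All tabular data moves through pandas DataFrames with strict schema
validation.  Peptide quantification reports are long-format tables
(protein, peptide, condition, replicate, fraction, intensity) of the kind a
DIA search engine emits; annotation is GFF3 or a 4-column TSV; calibration
standards and interaction networks are plain CSV/TSV.

Conventions: fractions are 1-based integer indices; missing
(protein, fraction) cells are zero intensity, not NaN (DIA reports omit
undetected precursors and the downstream correlation math needs dense
vectors); gene coordinates are 1-based inclusive (GFF3).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO


class SchemaError(ValueError):
    """A required column is missing or the file layout is not recognised."""


class ValidationError(ValueError):
    """Rows violate a table invariant (range, sign, uniqueness)."""


PEPTIDE_COLUMNS = ("protein_id", "peptide", "condition", "replicate", "fraction", "intensity")
ANNOTATION_COLUMNS = ("gene_id", "start", "end", "strand", "genome_id", "genome_length")
STANDARD_COLUMNS = ("name", "mw_da", "apex_fraction")
NETWORK_COLUMNS = ("node_a", "node_b", "probability", "q_value", "interaction_type")

_FLOAT_FMT = "%.10g"


def _sep_for(path: str) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_peptide_table(path: str, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a long-format peptide intensity table.

    Parameters
    ----------
    path
        TSV (default) or CSV file with a header row.
    schema
        Optional map from canonical column name to the column name used in
        the file, e.g. ``{"protein_id": "Protein.Group"}``.

    Returns
    -------
    DataFrame with columns ``protein_id, peptide, condition, replicate,
    fraction, intensity`` in canonical row order (sorted by key), so parsing
    is independent of input row order.  The dataset-wide fraction count F is
    ``df["fraction"].max()``.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    return validate_peptide_table(df)


def validate_peptide_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"peptide table is missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(PEPTIDE_COLUMNS)].copy()
    df["replicate"] = df["replicate"].astype(int)
    df["fraction"] = df["fraction"].astype(int)
    df["intensity"] = df["intensity"].astype(float)

    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise ValidationError(f"negative intensity at row {int(neg[0])}")
    if (df["fraction"] < 1).any():
        bad = df.index[df["fraction"] < 1][0]
        raise ValidationError(f"fraction index < 1 at row {int(bad)}")
    if (df["replicate"] < 1).any():
        bad = df.index[df["replicate"] < 1][0]
        raise ValidationError(f"replicate < 1 at row {int(bad)}")

    key = ["protein_id", "peptide", "condition", "replicate", "fraction"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0]
        raise ValidationError(
            "duplicated peptide record key: "
            + "/".join(str(first[k]) for k in key)
        )
    return df.sort_values(key, kind="mergesort").reset_index(drop=True)


def write_peptide_table(df: pd.DataFrame, path: str) -> None:
    df.loc[:, list(PEPTIDE_COLUMNS)].to_csv(
        path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT
    )


def read_annotation(path: str) -> pd.DataFrame:
    """Read gene annotations from GFF3 or a simple TSV.

    The TSV form needs at least ``gene_id, start, end, strand`` (optional
    ``genome_id`` and ``genome_length``).  In GFF3, only rows with feature
    type ``gene`` are kept; the gene id is taken from the ``ID=`` (or
    ``gene_id=``) attribute.  Coordinates stay 1-based inclusive.
    """
    with open(path) as fh:
        head = fh.readline()
    if head.startswith("##gff") or len(head.rstrip("\n").split("\t")) == 9:
        df = _read_gff3(path)
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
        missing = [c for c in ("gene_id", "start", "end", "strand") if c not in df.columns]
        if missing:
            raise SchemaError(f"annotation table is missing column(s): {', '.join(missing)}")
        if "genome_id" not in df.columns:
            df["genome_id"] = "genome"
        if "genome_length" not in df.columns:
            df["genome_length"] = int(df["end"].max())
    return _validate_annotation(df)


def _read_gff3(path: str) -> pd.DataFrame:
    names = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    raw = pd.read_csv(path, sep="\t", comment="#", header=None, names=names)
    genes = raw[raw["type"] == "gene"].copy()

    def _gene_id(attrs: str) -> str:
        for field in str(attrs).split(";"):
            k, _, v = field.strip().partition("=")
            if k in ("ID", "gene_id", "Name"):
                return v
        return str(attrs)

    out = pd.DataFrame(
        {
            "gene_id": genes["attributes"].map(_gene_id),
            "start": genes["start"].astype(int),
            "end": genes["end"].astype(int),
            "strand": genes["strand"],
            "genome_id": genes["seqid"],
        }
    )
    out["genome_length"] = out.groupby("genome_id")["end"].transform("max").astype(int)
    return out.reset_index(drop=True)


def _validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    df = df.loc[:, list(ANNOTATION_COLUMNS)].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["genome_length"] = df["genome_length"].astype(int)
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        raise ValidationError(f"start >= end for gene {bad['gene_id'].iloc[0]}")
    bad = df[(df["start"] < 1) | (df["end"] > df["genome_length"])]
    if len(bad):
        raise ValidationError(f"coordinates outside genome for gene {bad['gene_id'].iloc[0]}")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValidationError("strand must be '+' or '-'")
    return df.sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def write_annotation(df: pd.DataFrame, path: str) -> None:
    df.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep=_sep_for(path), index=False)


def read_calibration_standards(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in STANDARD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"standards table is missing column(s): {', '.join(missing)}")
    df = df.loc[:, list(STANDARD_COLUMNS)].copy()
    df["mw_da"] = df["mw_da"].astype(float)
    df["apex_fraction"] = df["apex_fraction"].astype(float)
    if (df["mw_da"] <= 0).any():
        raise ValidationError("calibration standard with non-positive molecular weight")
    return df


def write_calibration_standards(df: pd.DataFrame, path: str) -> None:
    df.loc[:, list(STANDARD_COLUMNS)].to_csv(path, sep=_sep_for(path), index=False,
                                             float_format=_FLOAT_FMT)


def write_network(edges: pd.DataFrame, path: str) -> None:
    """Write a plain-text interaction edge list, sorted by descending probability.

    Each edge carries the classifier probability, target-decoy q-value and an
    interaction type (host-host / host-phage / phage-phage).  Ties in
    probability are broken by node names so output is byte-deterministic.
    """
    df = edges.loc[:, list(NETWORK_COLUMNS)].copy()
    df = df.sort_values(
        ["probability", "node_a", "node_b"], ascending=[False, True, True], kind="mergesort"
    )
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def read_network(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in NETWORK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"network table is missing column(s): {', '.join(missing)}")
    return df


def read_fasta(path: str) -> dict[str, str]:
    """Protein sequences keyed by record id (standard one-letter codes)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_config(config: Mapping[str, object], path: str) -> None:
    """Flat key = value file, one key per line; tuples comma-separated."""
    with open(path, "w") as fh:
        for k, v in config.items():
            if isinstance(v, (tuple, list)):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k} = {v}\n")


def read_config(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            out[k.strip()] = v.strip()
    return out
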