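"""File I/O and validation for the mat nitrogen-cycling pipeline.

All tables are tab-delimited UTF-8 with '.' decimal separator. Layer
coordinates are 1-based integers labeling 1-mm slices from the mat surface
(Layer 1 = 0-1 mm). Floating-point outputs are serialized at 17 significant
digits so that reruns of the same configuration are byte-comparable.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

FLOAT_FMT = "%.17g"

# Column schemas: name -> (required dtype kind, row-level validator or None).
# Validators receive the column as a Series and return a boolean mask of BAD rows.
QPCR_SCHEMA = {
    "marker": ("object", None),
    "layer": ("integer", lambda s: s < 1),
    "replicate": ("integer", lambda s: s < 1),
    "template": ("object", lambda s: ~s.isin(["DNA", "cDNA"])),
    "raw_copies": ("number", lambda s: s < 0),
    "mat_mass_g": ("number", lambda s: s <= 0),
    "na_mass_ng": ("number", lambda s: s <= 0),
}
ANNOTATION_SCHEMA = {
    "gene_id": ("object", None),
    "ko": ("object", None),
    "symbol": ("object", None),
    "category": ("object", None),
    "taxon": ("object", None),
}
COVERAGE_SCHEMA = {
    "gene_id": ("object", None),
    "layer": ("integer", lambda s: s < 1),
    "coverage": ("number", lambda s: s < 0),
}
ENV_SCHEMA = {
    "layer": ("integer", lambda s: s < 1),
    "nh4_um": ("number", lambda s: s < 0),
    "no3_um": ("number", lambda s: s < 0),
    "po4_um": ("number", lambda s: s < 0),
}


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a protein/nucleotide FASTA into ``[(id, sequence), ...]``.

    Wrapped lines are joined; trailing '*' stop characters are stripped with
    a warning. Duplicate ids and empty files raise ``ValueError``.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if "*" in seq:
            warnings.warn(f"stripping '*' from sequence {rec.id!r}")
            seq = seq.replace("*", "")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path, schema: dict) -> pd.DataFrame:
    """Read and validate a TSV against a column schema.

    Missing columns raise with the full expected schema; extra columns are
    preserved with a warning; row-level violations raise listing the
    offending row indices.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; "
            f"expected schema columns: {list(schema)}"
        )
    extra = [c for c in df.columns if c not in schema]
    if extra:
        warnings.warn(f"{path}: extra column(s) {extra} preserved unvalidated")
    for col, (kind, bad_mask) in schema.items():
        if kind in ("number", "integer") and not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: column {col!r} must be numeric")
        if kind == "integer":
            if not (df[col].dropna() == df[col].dropna().astype(int)).all():
                raise ValueError(f"{path}: column {col!r} must be integer-valued")
        if bad_mask is not None:
            bad = bad_mask(df[col])
            bad = bad.fillna(False) if hasattr(bad, "fillna") else bad
            if bad.any():
                rows = df.index[bad].tolist()
                raise ValueError(f"{path}: invalid values in column {col!r} at rows {rows}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV deterministically (17-significant-digit floats)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
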