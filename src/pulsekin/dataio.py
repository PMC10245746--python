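"""Reading, validation and writing of the pipeline's tabular formats.

All tables are plain TSV. The quantification table is long-format: one row
per (peptide, sample, isotopomer channel), where the channel is the number
of heavy-labeled residues the observed form carries. This single schema
covers ordinary two-channel SILAC peptides (channels 0 and 1) and the
three-channel LL/HL/HH case used for precursor-pool analysis (channels
0, 1, 2 of a peptide with two labelable residues).
"""

from __future__ import annotations

import warnings

import pandas as pd

QUANT_COLUMNS = [
    "peptide_id",
    "sequence",
    "protein_accession",
    "protein_name",
    "n_labeled_sites",
    "n_heavy_sites",
    "sample_id",
    "intensity",
]

META_COLUMNS = [
    "sample_id",
    "tissue",
    "stage",
    "time_hours",
    "replicate",
    "batch",
    "is_reference",
]

ANNOTATION_COLUMNS = ["protein_accession", "compartment"]

#: Residues that carry the heavy label (Lys8 / Arg10); tryptic peptides
#: with missed cleavages may contain more than one.
LABELABLE_RESIDUES = frozenset("KR")


class SchemaError(ValueError):
    """A table failed validation; the message names the offending row."""


def count_labelable_sites(sequence: str) -> int:
    """Number of labelable residues (K or R) in a peptide sequence."""
    return sum(1 for aa in str(sequence) if aa in LABELABLE_RESIDUES)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_quant(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a peptide quantification table in place and return it typed."""
    _require_columns(df, QUANT_COLUMNS, "quant")
    df = df.copy()
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    df["n_labeled_sites"] = df["n_labeled_sites"].astype(int)
    df["n_heavy_sites"] = df["n_heavy_sites"].astype(int)

    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise SchemaError(f"negative intensity at row {neg[0]}")

    bad_channel = df.index[
        (df["n_heavy_sites"] < 0) | (df["n_heavy_sites"] > df["n_labeled_sites"])
    ]
    if len(bad_channel):
        raise SchemaError(
            f"n_heavy_sites outside [0, n_labeled_sites] at row {bad_channel[0]}"
        )

    recomputed = df["sequence"].map(count_labelable_sites)
    mismatch = df.index[recomputed != df["n_labeled_sites"]]
    if len(mismatch):
        i = mismatch[0]
        raise SchemaError(
            f"n_labeled_sites mismatch at row {i}: sequence "
            f"{df.at[i, 'sequence']!r} has {recomputed[i]} labelable residues, "
            f"column says {df.at[i, 'n_labeled_sites']}"
        )

    key = ["peptide_id", "sample_id", "n_heavy_sites"]
    dup = df.index[df.duplicated(key, keep="first")]
    if len(dup):
        raise SchemaError(f"duplicate (peptide_id, sample_id, n_heavy_sites) at row {dup[0]}")
    return df


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata table and return it typed."""
    _require_columns(df, META_COLUMNS, "metadata")
    extra = [c for c in df.columns if c not in META_COLUMNS]
    if extra:
        warnings.warn(f"metadata has extra column(s) {extra}; preserved as-is")
    df = df.copy()
    df["time_hours"] = pd.to_numeric(df["time_hours"], errors="raise").astype(float)
    df["replicate"] = df["replicate"].astype(int)
    df["is_reference"] = df["is_reference"].map(_parse_bool)

    dup = df.index[df.duplicated("sample_id", keep="first")]
    if len(dup):
        raise SchemaError(f"duplicate sample_id at row {dup[0]}")
    neg = df.index[df["time_hours"] < 0]
    if len(neg):
        raise SchemaError(f"negative time_hours at row {neg[0]}")
    ref_no_batch = df.index[df["is_reference"] & df["batch"].isna()]
    if len(ref_no_batch):
        raise SchemaError(f"reference sample without batch at row {ref_no_batch[0]}")
    return df


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise SchemaError(f"cannot parse boolean value {x!r}")


def read_quant(path) -> pd.DataFrame:
    """Read and validate a long-format peptide quantification TSV."""
    return validate_quant(pd.read_csv(path, sep="\t", dtype={"peptide_id": str, "sample_id": str}))


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the sample metadata TSV."""
    return validate_metadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def read_annotation(path) -> pd.DataFrame:
    """Read the optional protein -> subcellular-compartment table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ANNOTATION_COLUMNS, "annotation")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as TSV with 12 significant digits on floats."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table` (no schema applied)."""
    return pd.read_csv(path, sep="\t")
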