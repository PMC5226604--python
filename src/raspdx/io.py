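"""Readers and writers for the plain-text formats the pipeline touches.

Supported formats
-----------------
* gene signatures: GMT (two records, ``<name>_UP`` and ``<name>_DN``) or a
  two-column ``gene,direction`` table;
* expression matrices: plain TSV/CSV (genes in rows, samples in columns) or
  the GCT v1.2 dialect (``#1.2`` preamble, dimension line, Description
  column ignored);
* tumor volumes: long-format delimited text with columns
  ``model,animal,arm,day,volume``;
* model annotations: delimited text with ``model_id`` and ``kras_allele``.

All readers validate and *reject* malformed input rather than repairing it
silently; the one sanctioned repair (duplicate gene rows collapsed to the
highest-mean row, duplicate signature genes de-duplicated) is logged.

The package also bundles, as plain CSV, the published table of 25 CRC-PDX
models from a cetuximab mouse clinical trial — signature score, ΔT/ΔC and
KRAS codon-12/13 allele per model — which :func:`load_cetuximab_cohort`
returns verbatim.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .types import ExpressionMatrix, GeneSignature, ModelTable, VolumeSeries

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "cetuximab_crc_pdx_cohort.csv"


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


# ---------------------------------------------------------------------------
# signatures


def read_signature(path: str | Path, format: str = "auto") -> GeneSignature:
    """Read a gene signature from a GMT or two-column file.

    GMT dialect: exactly one record named ``<name>_UP`` and one named
    ``<name>_DN`` (case-insensitive suffixes), sharing ``<name>``.
    Two-column dialect: header ``gene,direction`` with direction in
    {up, down}.  ``format="auto"`` dispatches on the file extension.
    """
    path = Path(path)
    if format == "auto":
        format = "gmt" if path.suffix.lower() == ".gmt" else "two_column"
    if format == "gmt":
        return _read_signature_gmt(path)
    if format == "two_column":
        return _read_signature_two_column(path)
    raise ValueError(f"unknown signature format {format!r}")


def _read_signature_gmt(path: Path) -> GeneSignature:
    records: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT record needs name, description, >=1 gene")
            records[parts[0]] = [g for g in parts[2:] if g.strip()]
    up_name = next((n for n in records if n.upper().endswith("_UP")), None)
    dn_name = next((n for n in records if n.upper().endswith(("_DN", "_DOWN"))), None)
    if up_name is None or dn_name is None:
        raise FormatError(
            f"{path}: expected one <name>_UP and one <name>_DN record, "
            f"found {sorted(records)}"
        )
    name = up_name[: up_name.upper().rfind("_UP")]
    return GeneSignature(name=name, up=tuple(records[up_name]), down=tuple(records[dn_name]))


def _read_signature_two_column(path: Path) -> GeneSignature:
    up: list[str] = []
    down: list[str] = []
    with open(path, newline="") as fh:
        sample = fh.readline()
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(sample))
        if reader.fieldnames is None or {"gene", "direction"} - {
            f.strip().lower() for f in reader.fieldnames
        }:
            raise FormatError(f"{path}: expected header with 'gene' and 'direction' columns")
        fields = {f.strip().lower(): f for f in reader.fieldnames}
        for lineno, row in enumerate(reader, 2):
            gene = row[fields["gene"]].strip()
            direction = row[fields["direction"]].strip().lower()
            if direction == "up":
                up.append(gene)
            elif direction in ("down", "dn"):
                down.append(gene)
            else:
                raise FormatError(f"{path}:{lineno}: direction must be 'up' or 'down', got {direction!r}")
    if not up or not down:
        raise FormatError(f"{path}: missing an 'up' or 'down' record")
    return GeneSignature(name=path.stem, up=tuple(up), down=tuple(down))


def write_signature(signature: GeneSignature, path: str | Path, format: str = "two_column") -> None:
    path = Path(path)
    if format == "gmt":
        with open(path, "w") as fh:
            fh.write("\t".join([f"{signature.name}_UP", "up genes", *signature.up]) + "\n")
            fh.write("\t".join([f"{signature.name}_DN", "down genes", *signature.down]) + "\n")
    elif format == "two_column":
        with open(path, "w") as fh:
            fh.write("gene,direction\n")
            for g in signature.up:
                fh.write(f"{g},up\n")
            for g in signature.down:
                fh.write(f"{g},down\n")
    else:
        raise ValueError(f"unknown signature format {format!r}")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path: str | Path, scale_tag: str = "log2") -> ExpressionMatrix:
    """Read a genes x samples matrix from TSV/CSV or GCT v1.2 text.

    Duplicate gene rows are resolved by keeping the row with the highest
    mean (logged); any other integrity violation raises.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#1.2"):
        df = _read_gct(path)
    else:
        sep = _sniff_delimiter(first)
        try:
            df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty expression matrix")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    df.index = df.index.astype(str).str.strip().str.upper()
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        n_before = len(df)
        df = df[~df.index.duplicated(keep="first")]
        logger.warning(
            "collapsed %d duplicate gene row(s) keeping the highest-mean row", n_before - len(df)
        )
        df = df.sort_index()
    return ExpressionMatrix(df, scale_tag=scale_tag)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"{path}: unsupported GCT version line {version!r}")
        dims = fh.readline().split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: malformed GCT dimension line") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    elif df.shape[1] == n_samples + 1:
        df = df.drop(columns=[df.columns[0]])  # unlabeled description column
    if df.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: GCT declares {n_genes}x{n_samples} but body is {df.shape[0]}x{df.shape[1]}"
        )
    return df


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; full double precision round-trips."""
    matrix.values.to_csv(Path(path), sep=sep, index_label="gene_id", float_format="%.17g")


# ---------------------------------------------------------------------------
# volumes and annotations


def read_volumes(path: str | Path) -> VolumeSeries:
    """Read long-format per-animal tumor volumes (model,animal,arm,day,volume)."""
    path = Path(path)
    with open(path) as fh:
        sep = _sniff_delimiter(fh.readline())
    try:
        df = pd.read_csv(path, sep=sep)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return VolumeSeries(df)


def write_volumes(volumes: VolumeSeries, path: str | Path) -> None:
    volumes.records.to_csv(Path(path), index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read per-model annotations; requires model_id and kras_allele columns."""
    path = Path(path)
    with open(path) as fh:
        sep = _sniff_delimiter(fh.readline())
    df = pd.read_csv(path, sep=sep)
    missing = {"model_id", "kras_allele"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: annotation table missing column(s) {sorted(missing)}")
    df["model_id"] = df["model_id"].astype(str)
    if df["model_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate model_id in annotations")
    return df


def read_model_table(path: str | Path) -> ModelTable:
    """Read a full per-model table (model_id, ras_score, delta_t_over_delta_c, kras_allele)."""
    path = Path(path)
    with open(path) as fh:
        sep = _sniff_delimiter(fh.readline())
    return ModelTable(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# bundled cohort


def load_cetuximab_cohort() -> ModelTable:
    """Return the bundled 25-model CRC-PDX cetuximab trial table.

    Values are exactly as published: RAS signature scores at three decimals,
    ΔT/ΔC at two, KRAS codon-12/13 allele strings; 15 wild-type and 10
    mutant models.  No re-derivation is performed.
    """
    with resources.files("raspdx.data").joinpath(_FIXTURE_NAME).open() as fh:
        df = pd.read_csv(fh)
    table = ModelTable(df)
    assert table.n == 25, "bundled cohort must have exactly 25 models"
    return table
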