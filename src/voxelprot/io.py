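"""Readers and writers for peptide tables, sample metadata and GO maps.

Two peptide-table dialects are supported and must be named explicitly:

``maxquant``
    A MaxQuant ``peptides.txt``: ``Sequence`` keys the peptide, ``Leading
    razor protein`` assigns it to one protein, per-run intensities live in
    ``Intensity <sample>`` (or ``LFQ intensity <sample>``) columns, and
    ``Reverse`` / ``Potential contaminant`` carry ``+`` flags. An intensity
    of 0 means "not observed".

``generic``
    ``peptide_id``, ``protein_id``, optional ``gene_symbol``, then one
    intensity column per sample. Used by the synthetic generator.

All intensities are log2-transformed on read; 0 or blank cells become NaN.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import FormatError, PeptideMatrix, SampleMetadata

logger = logging.getLogger(__name__)

_MAXQUANT_KEY = "Sequence"
_MAXQUANT_PROTEIN = "Leading razor protein"
_MAXQUANT_GENE = "Gene names"
_FLAG_COLUMNS = {"reverse": "Reverse", "contaminant": "Potential contaminant"}


def _log2_intensities(raw: pd.DataFrame) -> pd.DataFrame:
    """0 or blank -> NaN, everything else -> log2. Negative input is invalid."""
    vals = raw.apply(pd.to_numeric, errors="coerce").astype(float)
    if (vals < 0).any().any():
        raise FormatError("negative intensity values are not valid")
    vals = vals.mask(vals == 0, np.nan)
    return np.log2(vals)


def read_peptide_table(
    path: str | Path,
    dialect: str = "maxquant",
    intensity_prefix: str = "Intensity",
) -> PeptideMatrix:
    """Read a tab-delimited peptide table into a :class:`PeptideMatrix`.

    Parameters
    ----------
    path : file path of the TSV table.
    dialect : ``"maxquant"`` or ``"generic"`` (never sniffed).
    intensity_prefix : MaxQuant column family to use, ``"Intensity"`` or
        ``"LFQ intensity"``. Ignored by the generic dialect.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "maxquant":
        return _parse_maxquant(df, intensity_prefix)
    if dialect == "generic":
        return _parse_generic(df)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _parse_maxquant(df: pd.DataFrame, intensity_prefix: str) -> PeptideMatrix:
    for col in (_MAXQUANT_KEY, _MAXQUANT_PROTEIN):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    prefix = intensity_prefix + " "
    sample_cols = [c for c in df.columns if c.startswith(prefix)]
    if not sample_cols:
        raise FormatError(f"no per-sample {intensity_prefix!r} columns found")
    key = df[_MAXQUANT_KEY]
    if key.duplicated().any():
        raise FormatError(f"duplicate peptide keys: {key[key.duplicated()].tolist()}")
    abundance = _log2_intensities(df[sample_cols])
    abundance.columns = [c[len(prefix) :] for c in sample_cols]
    abundance.index = pd.Index(key, name="peptide_id")

    def flag(name: str) -> pd.Series:
        if name not in df.columns:
            logger.warning("flag column %r absent; treating all rows as unflagged", name)
            return pd.Series(False, index=abundance.index)
        return pd.Series((df[name] == "+").to_numpy(), index=abundance.index)

    gene = df.get(_MAXQUANT_GENE, pd.Series("", index=df.index))
    return PeptideMatrix(
        abundance=abundance,
        protein_id=pd.Series(df[_MAXQUANT_PROTEIN].to_numpy(), index=abundance.index),
        gene_symbol=pd.Series(gene.fillna("").to_numpy(), index=abundance.index),
        reverse=flag(_FLAG_COLUMNS["reverse"]),
        contaminant=flag(_FLAG_COLUMNS["contaminant"]),
    )


def _parse_generic(df: pd.DataFrame) -> PeptideMatrix:
    for col in ("peptide_id", "protein_id"):
        if col not in df.columns:
            raise FormatError(f"missing required column: {col!r}")
    meta_cols = ["peptide_id", "protein_id"]
    gene = df["gene_symbol"] if "gene_symbol" in df.columns else pd.Series("", index=df.index)
    if "gene_symbol" in df.columns:
        meta_cols.append("gene_symbol")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise FormatError("no intensity columns found")
    key = df["peptide_id"]
    if key.duplicated().any():
        raise FormatError(f"duplicate peptide keys: {key[key.duplicated()].tolist()}")
    abundance = _log2_intensities(df[sample_cols])
    abundance.index = pd.Index(key, name="peptide_id")
    return PeptideMatrix(
        abundance=abundance,
        protein_id=pd.Series(df["protein_id"].to_numpy(), index=abundance.index),
        gene_symbol=pd.Series(gene.fillna("").to_numpy(), index=abundance.index),
    )


def filter_contaminants_reverse(m: PeptideMatrix) -> tuple[PeptideMatrix, dict]:
    """Drop decoy (reverse) and contaminant rows; abundances are untouched.

    Returns the filtered matrix and a report dict with dropped counts.
    """
    keep = ~(m.reverse | m.contaminant)
    report = {
        "n_reverse": int(m.reverse.sum()),
        "n_contaminant": int(m.contaminant.sum()),
        "n_dropped": int((~keep).sum()),
        "n_retained": int(keep.sum()),
    }
    return m.subset(m.peptide_ids[keep]), report


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    """Read a metadata CSV/TSV (delimiter inferred from the extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("voxel_row", "voxel_col"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    df["sample_id"] = df["sample_id"].astype(str)
    return SampleMetadata(df)


def read_annotation_map(path: str | Path, fmt: str = "tsv") -> dict[str, set[str]]:
    """Read a gene -> GO-category map.

    ``tsv``: two columns, gene symbol then category id (header optional,
    detected by a first line starting with ``gene``). ``gaf``: GAF 2.x,
    columns 3 (symbol) and 5 (GO id), comment lines start with ``!``.
    Empty category sets are never stored.
    """
    path = Path(path)
    mapping: dict[str, set[str]] = {}
    if fmt == "tsv":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2 or not parts[0] or not parts[1]:
                    continue
                if parts[0].lower() in {"gene", "gene_symbol"}:
                    continue
                mapping.setdefault(parts[0], set()).add(parts[1])
    elif fmt == "gaf":
        with open(path) as fh:
            for line in fh:
                if line.startswith("!"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 5 or not parts[2] or not parts[4]:
                    continue
                mapping.setdefault(parts[2], set()).add(parts[4])
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")
    return mapping


def write_peptide_table_long(m: PeptideMatrix, path: str | Path) -> None:
    """Canonical long-format TSV: peptide_id, protein_id, sample_id, log2_abundance.

    Only observed cells are written; values round-trip at full precision.
    """
    long = m.abundance.stack()
    long.index.names = ["peptide_id", "sample_id"]
    out = long.rename("log2_abundance").reset_index()
    out.insert(1, "protein_id", m.protein_id.loc[out["peptide_id"]].to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_peptide_table_generic(m: PeptideMatrix, path: str | Path) -> None:
    """Wide generic-dialect TSV on the linear scale (2**log2; missing -> 0)."""
    linear = np.power(2.0, m.abundance)
    linear = linear.fillna(0.0)
    out = pd.DataFrame(
        {
            "peptide_id": m.peptide_ids,
            "protein_id": m.protein_id.to_numpy(),
            "gene_symbol": m.gene_symbol.to_numpy(),
        }
    )
    out = pd.concat([out.reset_index(drop=True), linear.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_matrix_tsv(abundance: pd.DataFrame, path: str | Path, index_name: str) -> None:
    out = abundance.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.17g")
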