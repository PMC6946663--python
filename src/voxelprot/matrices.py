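"""In-memory containers for the pipeline.

Abundances are stored as pandas DataFrames in log2 units with NaN as the
missing-value sentinel (never 0): rows are analytes (peptides or proteins),
columns are sample ids in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input table violates the expected layout."""


@dataclass
class PeptideMatrix:
    """Log2 peptide abundances with peptide -> protein/gene assignment.

    abundance : DataFrame (peptide_id x sample_id), log2 intensities, NaN = missing.
    protein_id : Series mapping each peptide to exactly one protein accession
        (MaxQuant razor assignment).
    gene_symbol : Series mapping each peptide to a gene symbol ('' if unknown).
    reverse / contaminant : boolean Series carrying the decoy and contaminant
        flags from the search output; filtering is a separate step.
    """

    abundance: pd.DataFrame
    protein_id: pd.Series
    gene_symbol: pd.Series = None
    reverse: pd.Series = None
    contaminant: pd.Series = None

    def __post_init__(self) -> None:
        idx = self.abundance.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate peptide ids: {dups}")
        if self.abundance.columns.has_duplicates:
            raise FormatError("duplicate sample ids in abundance table")
        if self.gene_symbol is None:
            self.gene_symbol = pd.Series("", index=idx, dtype=object)
        if self.reverse is None:
            self.reverse = pd.Series(False, index=idx)
        if self.contaminant is None:
            self.contaminant = pd.Series(False, index=idx)
        for s in (self.protein_id, self.gene_symbol, self.reverse, self.contaminant):
            if not s.index.equals(idx):
                raise FormatError("annotation index does not match abundance index")
        vals = self.abundance.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("non-finite abundance values present")

    @property
    def peptide_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_peptides(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[1]

    def subset(self, peptide_ids) -> "PeptideMatrix":
        """Row subset preserving the given order."""
        return PeptideMatrix(
            abundance=self.abundance.loc[peptide_ids],
            protein_id=self.protein_id.loc[peptide_ids],
            gene_symbol=self.gene_symbol.loc[peptide_ids],
            reverse=self.reverse.loc[peptide_ids],
            contaminant=self.contaminant.loc[peptide_ids],
        )

    def with_abundance(self, abundance: pd.DataFrame) -> "PeptideMatrix":
        """Same annotations, new values (e.g. after normalization)."""
        return PeptideMatrix(
            abundance=abundance,
            protein_id=self.protein_id,
            gene_symbol=self.gene_symbol,
            reverse=self.reverse,
            contaminant=self.contaminant,
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: group label and LCM voxel coordinates.

    table columns: sample_id, study_id, group, voxel_row, voxel_col,
    voxel_size_um. One LC-MS run = one sample = one voxel.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "study_id", "group", "voxel_row", "voxel_col", "voxel_size_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing required columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        coords = t[["study_id", "voxel_row", "voxel_col"]]
        if coords.duplicated().any():
            bad = coords[coords.duplicated()].iloc[0].tolist()
            raise FormatError(f"duplicate voxel coordinate within study: {bad}")
        if (t["voxel_row"] < 0).any() or (t["voxel_col"] < 0).any():
            raise FormatError("voxel coordinates must be nonnegative")
        if (t["voxel_size_um"] <= 0).any():
            raise FormatError("voxel_size_um must be positive")
        self.table = t.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def group_samples(self, group: str) -> list[str]:
        if group not in set(self.groups):
            raise KeyError(f"unknown group label: {group!r}")
        return list(self.table.loc[self.groups == group, "sample_id"])

    def group_pairs(self) -> list[tuple[str, str]]:
        labels = sorted(self.groups.unique())
        return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]


def check_samples_match(m: PeptideMatrix, meta: SampleMetadata) -> None:
    """Assert the abundance columns and the metadata describe the same runs."""
    a, b = set(m.sample_ids), set(meta.sample_ids)
    if a != b:
        raise FormatError(
            f"sample mismatch: only in matrix {sorted(a - b)}, only in metadata {sorted(b - a)}"
        )


@dataclass
class ProteinMatrix:
    """Rolled-up protein abundances with rollup provenance.

    provenance columns: reference_peptide_id, peptide_count, peptides_dropped.
    scaling : DataFrame (peptide_id, protein_id, scale_log2) — additive log2
    offset applied to each peptide; 0 for every reference peptide.
    """

    abundance: pd.DataFrame
    provenance: pd.DataFrame
    scaling: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundance.index

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_proteins(self) -> int:
        return self.abundance.shape[0]
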