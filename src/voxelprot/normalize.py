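"""Rank-invariant median-centering normalization.

Per-sample loading differences are removed by subtracting a per-sample
shift estimated on "rank-invariant" peptides: complete-data peptides whose
within-sample abundance rank shows no dependence on the cell-type group
(Kruskal–Wallis p > alpha, alpha = 0.2 by default — deliberately liberal so
that only clearly group-dependent peptides are excluded from the anchor
set). The shift is each sample's median over the selected peptides, so the
post-normalization median of the anchor set is exactly 0 in every sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import PeptideMatrix, SampleMetadata


@dataclass
class NormalizationResult:
    selected_peptides: list[str]
    shift: pd.Series                  # per-sample location, log2 units
    normalized: PeptideMatrix


def select_rank_invariant_peptides(
    m: PeptideMatrix,
    meta: SampleMetadata,
    alpha: float = 0.2,
) -> list[str]:
    """Complete-data peptides whose within-sample rank is group-independent.

    Candidates are the peptides with no missing values; each candidate's
    per-sample ranks (average ties, computed within the candidate set) are
    tested against group membership with a Kruskal–Wallis test, and the
    peptide is selected iff p > alpha. With a single group every complete
    peptide is selected.
    """
    complete = m.abundance.dropna(axis=0)
    if complete.shape[0] == 0:
        raise ValueError(
            "no complete-data peptides: rank-invariant selection impossible; "
            "fall back to global median centering"
        )
    groups = meta.groups.loc[complete.columns]
    labels = groups.unique()
    if len(labels) < 2:
        return list(complete.index)
    ranks = complete.rank(axis=0, method="average")
    selected = []
    group_cols = {g: [s for s in complete.columns if groups[s] == g] for g in labels}
    for pep in complete.index:
        row = ranks.loc[pep]
        samples = [row[cols].to_numpy() for cols in group_cols.values()]
        try:
            with np.errstate(invalid="ignore"):
                _, p = stats.kruskal(*samples)
        except ValueError:  # all ranks identical -> zero statistic
            p = 1.0
        if np.isnan(p):  # complete ties make the tie correction 0/0
            p = 1.0
        if p > alpha:
            selected.append(pep)
    return selected


def median_center(m: PeptideMatrix, selected: list[str]) -> NormalizationResult:
    """Subtract each sample's median over the selected peptides.

    Missing cells stay missing; only the selected (complete) peptides
    define the shift.
    """
    if not selected:
        raise ValueError("selected peptide set is empty")
    sub = m.abundance.loc[selected]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"selected peptides with missing values: {bad}")
    shift = sub.median(axis=0)
    shift.name = "shift_log2"
    normalized = m.with_abundance(m.abundance.sub(shift, axis=1))
    return NormalizationResult(
        selected_peptides=list(selected), shift=shift, normalized=normalized
    )


def normalize(
    m: PeptideMatrix, meta: SampleMetadata, alpha: float = 0.2
) -> NormalizationResult:
    """Select rank-invariant peptides and median-center in one step."""
    return median_center(m, select_rank_invariant_peptides(m, meta, alpha))
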