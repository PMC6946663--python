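"""R-rollup peptide-to-protein quantification.

For each protein the member peptide with the least missing data is the
reference; every other peptide is shifted onto the reference by the median
(over shared samples) of the reference-minus-peptide difference, and the
per-sample protein abundance is the median of the scaled peptides present
in that sample. All scaling is an additive offset in log2 space, i.e. a
ratio on the linear scale.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .matrices import PeptideMatrix, ProteinMatrix

logger = logging.getLogger(__name__)


def select_reference_peptide(abundance: pd.DataFrame) -> str:
    """Reference peptide for one protein's peptide block.

    Fewest missing values wins; ties break by highest median abundance,
    then lexicographically smallest peptide id (deterministic).
    """
    n_missing = abundance.isna().sum(axis=1)
    medians = abundance.median(axis=1)
    order = sorted(
        abundance.index,
        key=lambda p: (n_missing[p], -medians[p] if np.isfinite(medians[p]) else np.inf, str(p)),
    )
    return order[0]


def rrollup(m: PeptideMatrix, min_peptides_per_protein: int = 1) -> ProteinMatrix:
    """Roll peptide abundances up to protein abundances.

    A peptide sharing no observed sample with its protein's reference has an
    undefined offset and is dropped from the rollup (warned, and counted in
    the provenance). Proteins with fewer than ``min_peptides_per_protein``
    member peptides are excluded entirely.
    """
    prot_rows: dict[str, np.ndarray] = {}
    prov_rows = []
    scaling_rows = []
    samples = m.sample_ids
    for protein, block_idx in m.protein_id.groupby(m.protein_id).groups.items():
        block = m.abundance.loc[block_idx]
        if block.shape[0] < min_peptides_per_protein:
            continue
        ref = select_reference_peptide(block)
        ref_vals = block.loc[ref]
        scaled = []
        dropped = 0
        for pep in block.index:
            if pep == ref:
                offset = 0.0
            else:
                diff = ref_vals - block.loc[pep]
                with warnings.catch_warnings():
                    # no shared observed sample -> all-NaN diff -> NaN median
                    warnings.simplefilter("ignore", RuntimeWarning)
                    offset = diff.median()
                if not np.isfinite(offset):  # no shared observed sample
                    logger.warning(
                        "peptide %s of protein %s shares no sample with the "
                        "reference; dropped from rollup",
                        pep,
                        protein,
                    )
                    dropped += 1
                    continue
            scaled.append(block.loc[pep] + offset)
            scaling_rows.append(
                {"peptide_id": pep, "protein_id": protein, "scale_log2": float(offset)}
            )
        scaled_df = pd.DataFrame(scaled)
        with warnings.catch_warnings():
            # all-NaN sample columns legitimately yield NaN medians
            warnings.simplefilter("ignore", RuntimeWarning)
            prot_rows[protein] = scaled_df.median(axis=0).to_numpy()
        prov_rows.append(
            {
                "protein_id": protein,
                "reference_peptide_id": ref,
                "peptide_count": int(scaled_df.shape[0]),
                "peptides_dropped": dropped,
            }
        )
    abundance = pd.DataFrame.from_dict(prot_rows, orient="index", columns=samples)
    abundance = abundance.sort_index()
    abundance.index.name = "protein_id"
    provenance = (
        pd.DataFrame(prov_rows).set_index("protein_id").sort_index()
        if prov_rows
        else pd.DataFrame(columns=["reference_peptide_id", "peptide_count", "peptides_dropped"])
    )
    scaling = pd.DataFrame(scaling_rows, columns=["peptide_id", "protein_id", "scale_log2"])
    return ProteinMatrix(abundance=abundance, provenance=provenance, scaling=scaling)
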