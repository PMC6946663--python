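import numpy as np
import pandas as pd
import pytest

from voxelprot.matrices import PeptideMatrix, SampleMetadata
from voxelprot.simulate import SynthConfig, pure_group_design, simulate_dataset


def make_metadata(groups: dict[str, int], study_id: str = "study", voxel_size: float = 100.0) -> SampleMetadata:
    """Metadata with n samples per group laid out one group per grid row."""
    rows = []
    for r, (g, n) in enumerate(groups.items()):
        for c in range(n):
            rows.append(
                {
                    "sample_id": f"{g}{c + 1}",
                    "study_id": study_id,
                    "group": g,
                    "voxel_row": r,
                    "voxel_col": c,
                    "voxel_size_um": voxel_size,
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


def make_peptides(values: dict[str, list], samples: list[str], protein: dict[str, str] | None = None) -> PeptideMatrix:
    """PeptideMatrix from a dict of peptide -> row values (None = missing)."""
    ab = pd.DataFrame(
        {s: [np.nan if v is None else float(v) for v in (values[p][i] for p in values)]
         for i, s in enumerate(samples)},
        index=pd.Index(list(values), name="peptide_id"),
    )
    prot = protein or {p: f"PROT_{p}" for p in values}
    return PeptideMatrix(abundance=ab, protein_id=pd.Series([prot[p] for p in values], index=ab.index))


@pytest.fixture
def pools_dataset():
    """Small dominant-cell-population simulation: 3 groups x 5 samples."""
    cfg = SynthConfig(n_proteins=40, seed=11)
    return simulate_dataset(cfg, pure_group_design(5), study_id="pools")
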