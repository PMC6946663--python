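"""Synthetic voxel-proteomics datasets with known ground truth.

The generator emulates the statistical structure of a spatial label-free
LC-MS experiment: log-normal peptide intensities built from per-protein
baselines and per-peptide offsets, cell-type-specific effects for a subset
of proteins, per-sample loading shifts, Gaussian measurement noise, and a
two-mechanism missingness model — abundance-dependent logistic censoring
(MNAR) plus a uniform random dropout rate (MCAR). Voxels live on a 2D grid
whose default layout mimics a uterine cross section: stroma (S) background,
a contiguous luminal-epithelium (LE) band, and glandular-epithelium (GE)
spots mixed with stroma.

Mixing across cell types happens on the linear intensity scale (ion
signal is physically additive) and is logged afterwards.

Randomness is split into independent streams (cell-type map, protein/
peptide truth, noise, missingness) spawned from the master seed, so e.g.
toggling missingness never perturbs the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import PeptideMatrix, SampleMetadata

GROUPS = ("LE", "S", "GE")


@dataclass
class SynthConfig:
    """Generator parameters; defaults mirror the emulated study conditions.

    Intensities are log2 ion counts (MaxQuant-like magnitudes ~2^25);
    effects, offsets, shifts and noise are all in log2 units.
    """

    n_proteins: int = 2000
    lambda_peptides: float = 4.0       # peptides/protein = 1 + Poisson(lambda)
    mu0: float = 25.0                  # mean protein baseline, log2
    sigma0: float = 2.0                # SD of protein baselines
    sigma_pep: float = 0.3             # SD of per-peptide ionisation offsets
    fraction_de: float = 0.1           # fraction of proteins cell-type specific
    effect_size: float = 2.0           # log2 effect added in the up-group
    sigma_effect: float = 0.0          # >0 draws effects ~ N(effect_size, sigma_effect^2)
    sigma_sample: float = 0.3          # SD of per-sample loading shifts
    sigma_noise: float = 0.25          # SD of residual measurement noise
    kappa: float = 1.0                 # MNAR logistic steepness; 0 disables MNAR
    tau: float = 21.0                  # MNAR midpoint on the log2 scale
    rho: float = 0.02                  # MCAR dropout rate
    voxel_size_um: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma0", "sigma_pep", "sigma_effect", "sigma_sample", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.fraction_de <= 1:
            raise ValueError("fraction_de must be in [0, 1]")
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must be in [0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def generate_celltype_map(
    h: int,
    w: int,
    layout: str = "bands_and_spots",
    seed: int = 0,
    band_rows: int = 2,
    spot_rate: float = 3.0,
    mix_frac: float = 0.5,
) -> pd.DataFrame:
    """Per-voxel cell-type composition fractions over (LE, S, GE).

    ``bands_and_spots`` (default): stroma background, a contiguous pure-LE
    band of ``band_rows`` rows centred vertically, and Poisson(``spot_rate``)
    GE spots placed on stroma voxels as GE/S mixtures (``mix_frac`` GE).
    ``uniform``: every voxel 100% stroma. Fractions always sum to 1.
    """
    if h < 1 or w < 1:
        raise ValueError("grid dimensions must be >= 1")
    rows = []
    if layout == "uniform":
        for r in range(h):
            for c in range(w):
                rows.append({"voxel_row": r, "voxel_col": c, "LE": 0.0, "S": 1.0, "GE": 0.0})
        return pd.DataFrame(rows)
    if layout != "bands_and_spots":
        raise ValueError(f"unknown layout: {layout!r}")
    if band_rows > h:
        raise ValueError(f"band_rows={band_rows} exceeds grid height {h}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    band_start = (h - band_rows) // 2
    band = set(range(band_start, band_start + band_rows))
    frac = {}
    for r in range(h):
        for c in range(w):
            frac[(r, c)] = (1.0, 0.0, 0.0) if r in band else (0.0, 1.0, 0.0)
    stroma_cells = [(r, c) for r in range(h) for c in range(w) if r not in band]
    n_spots = min(int(rng.poisson(spot_rate)), len(stroma_cells))
    if n_spots:
        picks = rng.choice(len(stroma_cells), size=n_spots, replace=False)
        for i in picks:
            frac[stroma_cells[i]] = (0.0, 1.0 - mix_frac, mix_frac)
    for (r, c), (le, s, ge) in frac.items():
        rows.append({"voxel_row": r, "voxel_col": c, "LE": le, "S": s, "GE": ge})
    return pd.DataFrame(rows)


def pure_group_design(n_per_group: int = 5, groups: tuple[str, ...] = GROUPS) -> pd.DataFrame:
    """Composition table for a dominant-cell-population study.

    One pure voxel per sample, laid out one group per grid row — mirrors the
    pooled LE/S/GE comparison design (default 5 samples per group).
    """
    rows = []
    for r, g in enumerate(groups):
        for c in range(n_per_group):
            comp = {lab: (1.0 if lab == g else 0.0) for lab in GROUPS}
            rows.append({"voxel_row": r, "voxel_col": c, **comp})
    return pd.DataFrame(rows)


@dataclass
class SimulatedDataset:
    peptides: PeptideMatrix             # observed, log2, NaN missing
    metadata: SampleMetadata
    truth_proteins: pd.DataFrame        # baseline, up_group, effect, per-group abundance
    truth_samples: pd.DataFrame         # true per-sample shift
    truth_peptides: pd.DataFrame        # per-peptide offset and protein
    config: SynthConfig = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the generic-dialect peptide table, metadata CSV and truth TSVs."""
        from . import io as vio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "peptides": out_dir / "peptides.tsv",
            "metadata": out_dir / "metadata.csv",
            "truth_proteins": out_dir / "truth_proteins.tsv",
            "truth_samples": out_dir / "truth_samples.tsv",
            "truth_peptides": out_dir / "truth_peptides.tsv",
        }
        vio.write_peptide_table_generic(self.peptides, paths["peptides"])
        self.metadata.table.to_csv(paths["metadata"], index=False)
        self.truth_proteins.to_csv(paths["truth_proteins"], sep="\t", index=False)
        self.truth_samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        self.truth_peptides.to_csv(paths["truth_peptides"], sep="\t", index=False)
        return paths


def simulate_dataset(
    cfg: SynthConfig,
    composition: pd.DataFrame,
    study_id: str = "synthetic",
) -> SimulatedDataset:
    """Draw one dataset for the given voxel composition table.

    Each voxel becomes one sample; its dominant cell type is the group
    label. For peptide i of protein P in voxel s with composition w:

        latent_linear = sum_c w_c * 2**a[P, c]
        log2 value    = log2(latent_linear) + offset_i + shift_s + noise

    then logistic MNAR censoring (if kappa > 0) and MCAR dropout.
    """
    ss = np.random.SeedSequence(entropy=cfg.seed)
    rng_truth, rng_noise, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- truth: proteins, effects, peptides -------------------------------
    n_prot = cfg.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n_prot)]
    baseline = rng_truth.normal(cfg.mu0, cfg.sigma0, size=n_prot)
    n_de = int(round(cfg.fraction_de * n_prot))
    de_idx = rng_truth.choice(n_prot, size=n_de, replace=False)
    up_group = np.array([""] * n_prot, dtype=object)
    effect = np.zeros(n_prot)
    if n_de:
        up_group[de_idx] = rng_truth.choice(GROUPS, size=n_de)
        effect[de_idx] = (
            rng_truth.normal(cfg.effect_size, cfg.sigma_effect, size=n_de)
            if cfg.sigma_effect > 0
            else cfg.effect_size
        )
    group_abund = {
        g: baseline + np.where(up_group == g, effect, 0.0) for g in GROUPS
    }
    n_pep = 1 + rng_truth.poisson(cfg.lambda_peptides, size=n_prot)
    pep_protein = np.repeat(np.arange(n_prot), n_pep)
    total_pep = int(n_pep.sum())
    peptide_ids = [
        f"PEP{p:05d}_{j}" for p, j in zip(pep_protein, _within_counts(n_pep))
    ]
    pep_offset = rng_truth.normal(0.0, cfg.sigma_pep, size=total_pep)

    # --- samples ----------------------------------------------------------
    comp = composition.reset_index(drop=True)
    n_samp = len(comp)
    w = comp[list(GROUPS)].to_numpy(dtype=float)
    if not np.allclose(w.sum(axis=1), 1.0):
        raise ValueError("voxel composition fractions must sum to 1")
    dominant = [GROUPS[i] for i in np.argmax(w, axis=1)]
    sample_ids = [
        f"{study_id}_r{int(r)}c{int(c)}"
        for r, c in zip(comp["voxel_row"], comp["voxel_col"])
    ]
    shift = rng_truth.normal(0.0, cfg.sigma_sample, size=n_samp)

    # --- observed matrix --------------------------------------------------
    abund_pc = np.stack([group_abund[g] for g in GROUPS], axis=1)  # (P, 3)
    latent = np.power(2.0, abund_pc) @ w.T                         # (P, n_samp), linear
    log2_prot = np.log2(latent)
    x = (
        log2_prot[pep_protein]
        + pep_offset[:, None]
        + shift[None, :]
        + rng_noise.normal(0.0, cfg.sigma_noise, size=(total_pep, n_samp))
    )
    missing = np.zeros(x.shape, dtype=bool)
    if cfg.kappa > 0:
        p_mnar = 1.0 / (1.0 + np.exp(-cfg.kappa * (cfg.tau - x)))
        missing |= rng_miss.random(x.shape) < p_mnar
    if cfg.rho > 0:
        missing |= rng_miss.random(x.shape) < cfg.rho
    x = np.where(missing, np.nan, x)

    abundance = pd.DataFrame(x, index=pd.Index(peptide_ids, name="peptide_id"), columns=sample_ids)
    peptides = PeptideMatrix(
        abundance=abundance,
        protein_id=pd.Series(
            [protein_ids[p] for p in pep_protein], index=abundance.index
        ),
        gene_symbol=pd.Series(
            [f"G{p:05d}" for p in pep_protein], index=abundance.index
        ),
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "study_id": study_id,
                "group": dominant,
                "voxel_row": comp["voxel_row"].astype(int).to_numpy(),
                "voxel_col": comp["voxel_col"].astype(int).to_numpy(),
                "voxel_size_um": cfg.voxel_size_um,
            }
        )
    )
    truth_proteins = pd.DataFrame(
        {
            "protein_id": protein_ids,
            "gene_symbol": [f"G{i:05d}" for i in range(n_prot)],
            "baseline_log2": baseline,
            "up_group": up_group,
            "effect_log2": effect,
            **{f"abund_{g}": group_abund[g] for g in GROUPS},
        }
    )
    truth_samples = pd.DataFrame({"sample_id": sample_ids, "shift_log2": shift})
    truth_peptides = pd.DataFrame(
        {
            "peptide_id": peptide_ids,
            "protein_id": [protein_ids[p] for p in pep_protein],
            "offset_log2": pep_offset,
        }
    )
    return SimulatedDataset(
        peptides=peptides,
        metadata=metadata,
        truth_proteins=truth_proteins,
        truth_samples=truth_samples,
        truth_peptides=truth_peptides,
        config=cfg,
    )


def _within_counts(sizes: np.ndarray) -> np.ndarray:
    """[3, 2] -> [0, 1, 2, 0, 1] — per-protein peptide indices."""
    out = np.ones(int(sizes.sum()), dtype=int)
    out[0] = 0
    out[np.cumsum(sizes)[:-1]] = -sizes[:-1] + 1
    return np.cumsum(out)


def config_to_yaml(cfg: SynthConfig, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def config_from_yaml(path: str | Path) -> SynthConfig:
    import yaml

    return SynthConfig(**yaml.safe_load(Path(path).read_text()))
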