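"""Observation-count filtering and test-eligibility classification.

Peptides observed in fewer than ``min_obs`` samples across the whole study
are dropped before rollup. After rollup, each (protein, group-pair) is
classified by how much data it has:

* ``quantitative`` — every group has at least ``min_anova_obs`` observed
  values, enough for the ANOVA track;
* ``qualitative`` — not quantitative, but each group has at least
  ``min_gtest_n`` samples in total, so a presence/absence g-test is possible;
* ``inadequate`` — neither; the pair is not tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrices import PeptideMatrix, ProteinMatrix, SampleMetadata

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"
INADEQUATE = "inadequate"


@dataclass(frozen=True)
class EligibilityConfig:
    min_obs: int = 2          # study-wide nonmissing count to keep a peptide
    min_anova_obs: int = 2    # per-group nonmissing values for the ANOVA track
    min_gtest_n: int = 3      # per-group sample count for the g-test track


def filter_min_observations(
    m: PeptideMatrix, min_obs: int = 2
) -> tuple[PeptideMatrix, dict]:
    """Remove peptides observed in fewer than ``min_obs`` samples."""
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    counts = m.abundance.notna().sum(axis=1)
    keep = counts >= min_obs
    report = {"n_removed": int((~keep).sum()), "n_retained": int(keep.sum())}
    return m.subset(m.peptide_ids[keep]), report


def classify_test_eligibility(
    prot: ProteinMatrix,
    meta: SampleMetadata,
    pair: tuple[str, str],
    cfg: EligibilityConfig = EligibilityConfig(),
) -> pd.DataFrame:
    """Per-protein eligibility for one group pair.

    Returns a DataFrame indexed by protein_id with columns ``pair``,
    ``eligibility``, ``n_obs_<A>``, ``n_obs_<B>``, ``N_<A>``, ``N_<B>``.
    """
    a, b = pair
    samples_a = meta.group_samples(a)
    samples_b = meta.group_samples(b)
    n_a = prot.abundance[samples_a].notna().sum(axis=1)
    n_b = prot.abundance[samples_b].notna().sum(axis=1)
    quantitative = (n_a >= cfg.min_anova_obs) & (n_b >= cfg.min_anova_obs)
    qualitative = ~quantitative & (
        (len(samples_a) >= cfg.min_gtest_n) & (len(samples_b) >= cfg.min_gtest_n)
    )
    eligibility = pd.Series(INADEQUATE, index=prot.protein_ids, dtype=object)
    eligibility[qualitative] = QUALITATIVE
    eligibility[quantitative] = QUANTITATIVE
    return pd.DataFrame(
        {
            "pair": f"{a}|{b}",
            "eligibility": eligibility,
            f"n_obs_{a}": n_a,
            f"n_obs_{b}": n_b,
            f"N_{a}": len(samples_a),
            f"N_{b}": len(samples_b),
        }
    )


def eligibility_table(
    prot: ProteinMatrix,
    meta: SampleMetadata,
    cfg: EligibilityConfig = EligibilityConfig(),
) -> pd.DataFrame:
    """Eligibility for every group pair, stacked long; index protein_id."""
    parts = [classify_test_eligibility(prot, meta, p, cfg) for p in meta.group_pairs()]
    return pd.concat(parts)
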