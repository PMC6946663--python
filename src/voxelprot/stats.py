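"""Per-protein pairwise group comparisons.

Two complementary tracks, chosen per (protein, group-pair) by data adequacy
(:mod:`voxelprot.qc`):

* **quantitative** — one-way ANOVA across all groups with enough data,
  with pairwise Tukey–Kramer p-values from the studentized-range
  distribution (Kramer's rule handles unequal group sizes);
* **qualitative** — a likelihood-ratio g-test of independence on the 2x2
  observed/missing x group table, Holm-adjusted across the protein's
  pairwise comparisons.

A protein/pair is called significant when its adjusted p-value falls below
``alpha_sig`` (0.05). Across-protein multiplicity is deliberately not
adjusted by default; ``across_protein_bh=True`` adds a Benjamini–Hochberg
pass for users who want it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import ProteinMatrix, SampleMetadata
from .qc import QUALITATIVE, QUANTITATIVE

logger = logging.getLogger(__name__)

UP_IN_A = "up_in_A"
UP_IN_B = "up_in_B"
NONE = "none"


def anova_tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-way ANOVA with Tukey–Kramer pairwise p-values.

    Parameters
    ----------
    groups : mapping of group label -> 1-D array of observed (nonmissing)
        log2 abundances; every group needs >= 2 values.

    Returns a DataFrame with one row per unordered pair (A, B) and columns
    ``statistic`` (pairwise t on the pooled variance), ``p_raw`` (two-sided
    t), ``p_tukey`` and ``mean_diff`` (mean(A) - mean(B)).

    With zero pooled variance, pairs with equal means get p = 1 and pairs
    with unequal means get p clamped at machine epsilon (exact separation;
    logged) rather than a NaN.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observed values")
        if np.isnan(v).any():
            raise ValueError(f"group {g!r} contains missing values")
    k = len(labels)
    n = {g: v.size for g, v in arrays.items()}
    mean = {g: v.mean() for g, v in arrays.items()}
    N = sum(n.values())
    df_resid = N - k
    ss_within = sum(((v - mean[g]) ** 2).sum() for g, v in arrays.items())
    s2 = ss_within / df_resid
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            diff = mean[a] - mean[b]
            if s2 > 0:
                se = np.sqrt(s2 * (1.0 / n[a] + 1.0 / n[b]))
                t = diff / se
                p_raw = 2.0 * stats.t.sf(abs(t), df_resid)
                # Kramer's rule: q = |diff| / sqrt(s2/2 * (1/na + 1/nb))
                q = abs(diff) / np.sqrt(s2 / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
                p_tukey = float(stats.studentized_range.sf(q, k, df_resid))
            elif diff == 0:
                t, p_raw, p_tukey = 0.0, 1.0, 1.0
            else:  # exact separation with zero residual variance
                logger.warning("zero pooled variance with unequal means; p clamped")
                t = np.sign(diff) * np.inf
                p_raw = p_tukey = np.finfo(float).eps
            rows.append(
                {
                    "pair_a": a,
                    "pair_b": b,
                    "statistic": float(t),
                    "p_raw": float(min(max(p_raw, np.finfo(float).eps), 1.0)),
                    "p_tukey": float(min(max(p_tukey, np.finfo(float).eps), 1.0)),
                    "mean_diff": float(diff),
                }
            )
    return pd.DataFrame(rows)


def g_statistic(observed_a: int, total_a: int, observed_b: int, total_b: int) -> float:
    """Likelihood-ratio G on the 2x2 observed/missing x group table.

    G = 2 * sum O * ln(O/E) over cells with O > 0, expected counts from the
    table margins. Equals twice the saturated-vs-independence multinomial
    log-likelihood difference.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("both groups need at least one sample")
    if not (0 <= observed_a <= total_a and 0 <= observed_b <= total_b):
        raise ValueError("observed count exceeds group size")
    table = np.array(
        [
            [observed_a, observed_b],
            [total_a - observed_a, total_b - observed_b],
        ],
        dtype=float,
    )
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if (row == 0).any():  # a margin of zero leaves a degenerate 2x1 table
        return 0.0
    expected = row * col / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def holm(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment; preserves the ordering of raw p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min((m - rank) * p[idx], 1.0)
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def gtest_holm(
    counts: dict[tuple[str, str], tuple[int, int, int, int]]
) -> pd.DataFrame:
    """g-tests for a family of pairwise presence/absence comparisons.

    ``counts`` maps (A, B) -> (observed_A, total_A, observed_B, total_B).
    Raw p-values come from chi-square with 1 df; the Holm adjustment runs
    across the family (one protein's set of pairs).
    """
    rows = []
    for (a, b), (oa, na, ob, nb) in counts.items():
        g = g_statistic(oa, na, ob, nb)
        p = float(stats.chi2.sf(g, df=1)) if g > 0 else 1.0
        rows.append(
            {
                "pair_a": a,
                "pair_b": b,
                "statistic": g,
                "p_raw": p,
                "frac_diff": oa / na - ob / nb,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm(out["p_raw"].to_numpy())
    return out


@dataclass
class ComparisonSummary:
    results: pd.DataFrame       # one row per protein x pair
    counts: pd.DataFrame        # significant proteins by pair and direction


def compare_groups(
    prot: ProteinMatrix,
    meta: SampleMetadata,
    eligibility: pd.DataFrame,
    alpha_sig: float = 0.05,
    across_protein_bh: bool = False,
) -> ComparisonSummary:
    """Route every eligible (protein, pair) to its test and collect calls.

    The ANOVA is fitted once per protein on all groups with >= 2 observed
    values (so the pooled variance uses the full factor, not just the pair
    under test); qualitative pairs share one Holm family per protein.
    """
    group_samples = {g: meta.group_samples(g) for g in sorted(meta.groups.unique())}
    elig_wide = eligibility.pivot_table(
        index=eligibility.index, columns="pair", values="eligibility", aggfunc="first"
    )
    rows = []
    for protein in prot.protein_ids:
        values = prot.abundance.loc[protein]
        elig_row = elig_wide.loc[protein] if protein in elig_wide.index else None
        if elig_row is None:
            continue
        obs = {
            g: values[s].dropna().to_numpy() for g, s in group_samples.items()
        }
        anova_pairs = []
        gtest_pairs = {}
        for pair_key, elig in elig_row.items():
            a, b = pair_key.split("|")
            if elig == QUANTITATIVE:
                anova_pairs.append((a, b))
            elif elig == QUALITATIVE:
                gtest_pairs[(a, b)] = (
                    int(np.sum(~np.isnan(values[group_samples[a]].to_numpy(float)))),
                    len(group_samples[a]),
                    int(np.sum(~np.isnan(values[group_samples[b]].to_numpy(float)))),
                    len(group_samples[b]),
                )
        if anova_pairs:
            fit_groups = {g: v for g, v in obs.items() if v.size >= 2}
            res = anova_tukey(fit_groups)
            res = res.set_index(["pair_a", "pair_b"])
            for a, b in anova_pairs:
                r = res.loc[(a, b)]
                sig = bool(r["p_tukey"] < alpha_sig)
                if r["mean_diff"] > 0:
                    direction = UP_IN_A
                elif r["mean_diff"] < 0:
                    direction = UP_IN_B
                else:
                    direction = NONE
                rows.append(
                    {
                        "protein_id": protein,
                        "pair": f"{a}|{b}",
                        "test": "anova",
                        "statistic": r["statistic"],
                        "p_raw": r["p_raw"],
                        "p_adjusted": r["p_tukey"],
                        "direction": direction,
                        "significant": sig,
                    }
                )
        if gtest_pairs:
            res = gtest_holm(gtest_pairs)
            for _, r in res.iterrows():
                sig = bool(r["p_holm"] < alpha_sig)
                if r["frac_diff"] > 0:
                    direction = UP_IN_A
                elif r["frac_diff"] < 0:
                    direction = UP_IN_B
                else:
                    direction = NONE
                rows.append(
                    {
                        "protein_id": protein,
                        "pair": f"{r['pair_a']}|{r['pair_b']}",
                        "test": "gtest",
                        "statistic": r["statistic"],
                        "p_raw": r["p_raw"],
                        "p_adjusted": r["p_holm"],
                        "direction": direction,
                        "significant": sig,
                    }
                )
    results = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "pair",
            "test",
            "statistic",
            "p_raw",
            "p_adjusted",
            "direction",
            "significant",
        ],
    )
    if across_protein_bh and len(results):
        from statsmodels.stats.multitest import multipletests

        for pair in results["pair"].unique():
            mask = results["pair"] == pair
            _, p_bh, _, _ = multipletests(results.loc[mask, "p_adjusted"], method="fdr_bh")
            results.loc[mask, "p_adjusted"] = p_bh
        results["significant"] = results["p_adjusted"] < alpha_sig
    if len(results):
        results.loc[~results["significant"], "direction"] = NONE
    counts = (
        results[results["significant"]]
        .groupby(["pair", "test", "direction"])
        .size()
        .rename("n_significant")
        .reset_index()
    )
    return ComparisonSummary(results=results, counts=counts)
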