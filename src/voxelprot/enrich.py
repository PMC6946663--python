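"""EASE-adjusted Fisher exact GO-category enrichment.

The EASE adjustment makes Fisher's one-sided enrichment test conservative
by removing one gene from the list-hit cell before computing the
hypergeometric tail: a category supported by a single list gene can never
score. Enrichment scores for display are -log10 of the EASE p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def ease_fisher(a: int, n: int, K: int, N: int) -> float:
    """One-sided EASE p-value for a 2x2 enrichment table.

    a : list genes in the category, n : list size, K : background genes in
    the category, N : background size. The list-hit cell is decremented to
    max(a-1, 0) with the list size held fixed; a <= 1 gives p = 1.
    """
    if not (0 <= a <= n <= N and a <= K <= N):
        raise ValueError(f"inconsistent counts: a={a}, n={n}, K={K}, N={N}")
    if a <= 1:
        return 1.0
    a_dec = a - 1
    table = np.array(
        [
            [a_dec, n - a_dec],
            [K - a, N - n - (K - a)],
        ]
    )
    if (table < 0).any():
        raise ValueError(f"inconsistent counts: a={a}, n={n}, K={K}, N={N}")
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(min(p, 1.0))


def go_enrichment(
    sig_genes: list[str],
    background: list[str],
    annotation: dict[str, set[str]],
    min_cat: int = 2,
    category_names: dict[str, str] | None = None,
) -> pd.DataFrame:
    """EASE enrichment of a significant-gene list against a background.

    One row per category with at least ``min_cat`` background members,
    sorted by ascending p; columns category_id, list_hits, list_size,
    background_hits, background_size, p_ease, score (-log10 p).
    """
    sig = set(sig_genes)
    bg = set(background)
    stray = sig - bg
    if stray:
        raise ValueError(f"significant genes absent from background: {sorted(stray)}")
    n, N = len(sig), len(bg)
    cols = [
        "category_id",
        "category_name",
        "list_hits",
        "list_size",
        "background_hits",
        "background_size",
        "p_ease",
        "score",
    ]
    if n == 0:
        return pd.DataFrame(columns=cols)
    cat_members: dict[str, set[str]] = {}
    for gene in bg:
        for cat in annotation.get(gene, ()):
            cat_members.setdefault(cat, set()).add(gene)
    rows = []
    for cat, members in cat_members.items():
        if len(members) < min_cat:
            continue
        a = len(sig & members)
        p = ease_fisher(a, n, len(members), N)
        rows.append(
            {
                "category_id": cat,
                "category_name": (category_names or {}).get(cat, ""),
                "list_hits": a,
                "list_size": n,
                "background_hits": len(members),
                "background_size": N,
                "p_ease": p,
                "score": float(max(-np.log10(p), 0.0)) if p > 0 else np.inf,
            }
        )
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["p_ease", "category_id"], kind="stable").reset_index(drop=True)
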