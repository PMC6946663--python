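"""RMD-PAV sample outlier screening.

Each LC-MS run is summarised by five peptide-abundance-vector (PAV)
statistics — median pairwise Pearson correlation with the other runs,
fraction of missing peptides, median absolute deviation, skewness and
kurtosis — and a squared robust Mahalanobis distance (RMD²) on those
summary vectors decides whether the run is an outlier (p below ``alpha``,
0.001 by default). A separate Pearson-correlation screen is advisory only.

Distance estimators
-------------------
``loo`` (default)
    Leave-one-out Mahalanobis: each run is measured against the mean and
    covariance of the *other* runs, so the tested run never contaminates
    its own reference — the robustness relevant for single deviant runs.
    Under a multivariate-normal null the distance has an exact
    Hotelling-T²/F distribution at any sample size, giving exact p-values
    (it converges to the chi-square_k tail as n grows). Pairs of mutually
    masking outliers can evade it; screen iteratively if that is a concern.
``mcd``
    Minimum covariance determinant scatter (support fraction 0.75) with
    asymptotic chi-square_k p-values. Only adequately calibrated for n in
    the several dozens and above: at n ~ 15-24 raw MCD distances are far
    heavier-tailed than chi-square and over-flag badly.
``classical``
    Classical mean/covariance with chi-square_k p-values; not robust
    (distances are bounded by (n-1)^2/n, so small studies can never flag).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrices import PeptideMatrix

logger = logging.getLogger(__name__)

PAV_METRICS = ("r_med", "fraction_missing", "mad", "skewness", "kurtosis")


def pav_metrics(m: PeptideMatrix) -> pd.DataFrame:
    """Per-sample PAV summary metrics (rows = samples, columns = metrics).

    Correlations use pairwise-complete peptides; a sample with fewer than
    two observed values cannot be summarised and raises.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples for PAV metrics")
    counts = m.abundance.notna().sum(axis=0)
    bad = counts[counts < 2]
    if len(bad):
        raise ValueError(f"samples with <2 observed values: {list(bad.index)}")
    corr = m.abundance.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, np.nan)
    out = pd.DataFrame(
        {
            "r_med": corr.median(axis=1),
            "fraction_missing": m.abundance.isna().mean(axis=0),
            "mad": (m.abundance - m.abundance.median(axis=0)).abs().median(axis=0),
            "skewness": m.abundance.apply(lambda c: stats.skew(c.dropna()), axis=0),
            "kurtosis": m.abundance.apply(lambda c: stats.kurtosis(c.dropna()), axis=0),
        }
    )
    out.index.name = "sample_id"
    return out


@dataclass
class OutlierReport:
    table: pd.DataFrame       # metrics + rmd2, p_value, flagged per sample
    flagged: list[str]
    estimator: str


def _loo_distances(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    d2 = np.empty(n)
    for i in range(n):
        rest = np.delete(x, i, axis=0)
        mu = rest.mean(axis=0)
        cov = np.cov(rest, rowvar=False)
        c = x[i] - mu
        try:
            d2[i] = c @ np.linalg.solve(cov, c)
        except np.linalg.LinAlgError:
            d2[i] = np.nan
    return d2


def _loo_pvalues(d2: np.ndarray, n: int, k: int) -> np.ndarray:
    # x_i vs mean/cov of m = n-1 others: T2 = d2 * m/(m+1), and
    # T2 * (m-k) / (k (m-1)) ~ F(k, m-k) exactly under the MVN null.
    m = n - 1
    f = d2 * (m / (m + 1.0)) * (m - k) / (k * (m - 1.0))
    return stats.f.sf(f, k, m - k)


def rmd_pav(
    metrics: pd.DataFrame,
    alpha: float = 0.001,
    subset: tuple[str, ...] | None = None,
    estimator: str = "loo",
    seed: int = 0,
) -> OutlierReport:
    """Robust-Mahalanobis outlier flags on the PAV metric matrix.

    ``subset`` restricts the metric columns (default: all five). RMD² and
    its upper-tail p-value are computed per sample with the chosen
    ``estimator`` (see module docstring); a sample is flagged iff
    p < ``alpha``. Requires n >= k + 3 samples for k metrics so every
    leave-one-out covariance is invertible.
    """
    cols = list(subset) if subset is not None else list(metrics.columns)
    x = metrics[cols].to_numpy(dtype=float)
    n, k = x.shape
    if n < k + 3:
        raise ValueError(f"need at least k+3={k + 3} samples for {k} metrics")
    if estimator == "loo":
        rmd2 = _loo_distances(x)
        if np.isnan(rmd2).any():
            raise ValueError(
                "singular leave-one-out scatter; reduce the metric subset "
                "(e.g. drop constant metrics) and retry"
            )
        p = _loo_pvalues(rmd2, n, k)
    elif estimator in ("mcd", "classical"):
        if estimator == "mcd" and n >= 2 * k:
            from sklearn.covariance import MinCovDet

            fit = MinCovDet(support_fraction=0.75, random_state=seed).fit(x)
            loc, cov = fit.location_, fit.covariance_
        else:
            if estimator == "mcd":
                logger.warning("n < 2k; classical mean/covariance used instead of MCD")
            loc, cov = x.mean(axis=0), np.cov(x, rowvar=False)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            cov_inv = np.full((k, k), np.nan)
        if not np.isfinite(cov_inv).all():
            raise ValueError(
                "singular metric scatter matrix; reduce the metric subset "
                "(e.g. drop constant metrics) and retry"
            )
        centred = x - loc
        rmd2 = np.einsum("ij,jk,ik->i", centred, cov_inv, centred)
        p = stats.chi2.sf(rmd2, df=k)
    else:
        raise ValueError(f"unknown estimator: {estimator!r}")
    table = metrics[cols].copy()
    table["rmd2"] = rmd2
    table["p_value"] = p
    table["flagged"] = p < alpha
    return OutlierReport(
        table=table, flagged=list(table.index[table["flagged"]]), estimator=estimator
    )


def correlation_screen(metrics: pd.DataFrame, corr_k: float = 1.5) -> pd.DataFrame:
    """Advisory report of per-sample median correlations, sorted ascending.

    Samples with r_med below ``median - corr_k * IQR`` get an advisory
    flag; this screen never removes samples.
    """
    r = metrics["r_med"].sort_values()
    q1, q3 = r.quantile([0.25, 0.75])
    cutoff = r.median() - corr_k * (q3 - q1)
    out = pd.DataFrame({"r_med": r, "advisory_flag": r < cutoff})
    out.index.name = "sample_id"
    return out
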