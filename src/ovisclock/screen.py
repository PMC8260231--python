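"""Per-probe age-association screening and global methylation trend.

Each probe's methylation is correlated with chronological age (Pearson by
default, Spearman optionally); significance comes from the Student-t
transform t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees of freedom.
Missing beta values are excluded pairwise per probe.  P-values are reported
uncorrected; a Benjamini-Hochberg column is available behind a flag.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, MethylomeDataset


def _pearson_by_probe(values: np.ndarray, y: np.ndarray):
    """Row-wise Pearson r of ``values`` (probes x samples, NaN allowed)
    against ``y``, with pairwise missing-value exclusion."""
    mask = ~np.isnan(values)
    n = mask.sum(axis=1).astype(float)
    x = np.where(mask, values, 0.0)
    yb = np.where(mask, y[None, :], 0.0)
    sx, sy = x.sum(axis=1), yb.sum(axis=1)
    sxx = (x * x).sum(axis=1)
    syy = (yb * yb).sum(axis=1)
    sxy = (x * yb).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r = cov / np.sqrt(vx * vy)
    # numerical guard: |r| can exceed 1 by epsilon
    r = np.clip(r, -1.0, 1.0)
    defined = (n >= 3) & (vx > 0) & (vy > 0)
    r[~defined] = np.nan
    return r, n, defined


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, preserving NaN positions."""
    ranked = np.full_like(values, np.nan, dtype=float)
    for i in range(values.shape[0]):
        row = values[i]
        ok = ~np.isnan(row)
        if ok.any():
            ranked[i, ok] = stats.rankdata(row[ok])
    return ranked


def r_to_t_p(r: np.ndarray, n: np.ndarray):
    """Student-t statistic and two-sided p for a correlation of ``r`` at
    sample size ``n`` (n-2 degrees of freedom)."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return t, p


def screen_age(dataset: MethylomeDataset, method: str = "pearson",
               stratum=None, bh_adjust: bool = False) -> pd.DataFrame:
    """Correlate every probe's methylation with age.

    Returns one row per probe: r, n, t, p (two-sided, uncorrected), method
    and an ``ok`` flag.  Zero-variance probes are flagged undefined rather
    than dropped.  ``stratum`` restricts samples (query string or mask).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    sub = dataset.subset(stratum)
    if sub.n_samples < 3:
        raise DataError(f"stratum leaves {sub.n_samples} samples; need >= 3")
    values = sub.beta.to_numpy(dtype=float)
    ages = sub.ages.to_numpy(dtype=float)
    if method == "spearman":
        values = _rank_rows(values)
        # age ranks must respect each probe's missingness pattern
        if np.isnan(values).any():
            age_rank = np.vstack([
                _rank_age_masked(ages, row) for row in values])
        else:
            age_rank = np.tile(stats.rankdata(ages), (values.shape[0], 1))
        r, n, defined = _pearson_masked_pairs(values, age_rank)
    else:
        r, n, defined = _pearson_by_probe(values, ages)
    t, p = r_to_t_p(r, n)
    out = pd.DataFrame({
        "probe_id": sub.beta.index,
        "r": r, "n": n.astype(int), "t": t, "p": p,
        "method": method, "ok": defined,
    }).set_index("probe_id", drop=False)
    out.index.name = None
    out.loc[~out["ok"], ["t", "p"]] = np.nan
    if bh_adjust:
        out["p_bh"] = np.nan
        ok = out["ok"]
        out.loc[ok, "p_bh"] = stats.false_discovery_control(
            out.loc[ok, "p"], method="bh")
    return out


def _rank_age_masked(ages: np.ndarray, row: np.ndarray) -> np.ndarray:
    out = np.full_like(ages, np.nan, dtype=float)
    ok = ~np.isnan(row)
    out[ok] = stats.rankdata(ages[ok])
    return out


def _pearson_masked_pairs(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson where both x and y are per-row arrays with matching
    NaN patterns."""
    mask = ~np.isnan(x)
    n = mask.sum(axis=1).astype(float)
    xs = np.where(mask, x, 0.0)
    ys = np.where(mask, y, 0.0)
    sx, sy = xs.sum(axis=1), ys.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * (xs * ys).sum(axis=1) - sx * sy
        vx = n * (xs * xs).sum(axis=1) - sx * sx
        vy = n * (ys * ys).sum(axis=1) - sy * sy
        r = np.clip(cov / np.sqrt(vx * vy), -1.0, 1.0)
    defined = (n >= 3) & (vx > 0) & (vy > 0)
    r[~defined] = np.nan
    return r, n, defined


def global_trend(dataset: MethylomeDataset, stratum=None) -> dict:
    """Regress per-sample mean beta on age (ordinary least squares).

    Returns slope (beta units / year), intercept, r, p and the per-sample
    means, to probe for a global methylation drift with age.
    """
    sub = dataset.subset(stratum)
    if sub.n_samples < 3:
        raise DataError("need >= 3 samples for a global trend")
    means = sub.beta.mean(axis=0, skipna=True)
    ages = sub.ages.to_numpy(dtype=float)
    if np.allclose(means, means.iloc[0]):
        # zero-variance response: slope exactly 0, no meaningful p
        return {"slope": 0.0, "intercept": float(means.iloc[0]), "r": np.nan,
                "p": np.nan, "stderr": 0.0, "sample_means": means}
    fit = stats.linregress(ages, means.to_numpy())
    return {"slope": fit.slope, "intercept": fit.intercept, "r": fit.rvalue,
            "p": fit.pvalue, "stderr": fit.stderr, "sample_means": means}


def top_age_correlated(results: pd.DataFrame, k: int = 500,
                       positive: bool = True) -> list[str]:
    """Top-k probes by r (descending if positive, ascending otherwise);
    ties broken lexicographically by probe_id for determinism."""
    ok = results[results["ok"]].copy()
    ok = ok.sort_values(["r", "probe_id"],
                        ascending=[not positive, True], kind="mergesort")
    return ok["probe_id"].head(k).tolist()


def strata_overlap(results_by_stratum: dict[str, pd.DataFrame],
                   p_threshold: float) -> dict[tuple[str, ...], int]:
    """Counts of probes significant (p < threshold) in every stratum of each
    non-empty strata subset."""
    sig = {name: set(res.loc[res["ok"] & (res["p"] < p_threshold), "probe_id"])
           for name, res in results_by_stratum.items()}
    names = sorted(sig)
    out: dict[tuple[str, ...], int] = {}
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            out[combo] = len(set.intersection(*(sig[c] for c in combo)))
    return out
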