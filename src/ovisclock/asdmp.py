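"""Androgen-sensitive differentially methylated probes (asDMPs).

A probe is androgen-sensitive when its methylation-vs-age slope differs
between intact and castrated males.  Per group an ordinary least-squares
regression of beta on age gives slope b and standard error s; probes are
screened with

    t = (b_a - b_b) / sqrt(s_a^2 + s_b^2)

referred to a Student-t distribution with Welch-Satterthwaite degrees of
freedom on the two slope variances.  P-values are reported uncorrected.
Downstream utilities cover ranked top-k selection, the chromosomal
distribution of hits, the ranked-window association of asDMP methylation
with juvenile body mass, and the tissue-dimorphism expression test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError, MethylomeDataset


def _slopes_by_probe(values: np.ndarray, ages: np.ndarray):
    """Row-wise OLS slope, slope SE and n of beta on age, with pairwise
    missing-value exclusion.  Rows with n < 3, constant age, or zero
    residual-and-slope information are flagged undefined."""
    mask = ~np.isnan(values)
    n = mask.sum(axis=1).astype(float)
    x = np.where(mask, ages[None, :], 0.0)
    y = np.where(mask, values, 0.0)
    sx, sy = x.sum(axis=1), y.sum(axis=1)
    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    syy = (y * y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssx = sxx - sx * sx / n          # sum of squares of age
        spxy = sxy - sx * sy / n
        ssy = syy - sy * sy / n
        slope = spxy / ssx
        rss = ssy - slope * spxy         # residual sum of squares
        rss = np.maximum(rss, 0.0)       # numerical guard
        se = np.sqrt(rss / (n - 2) / ssx)
    defined = (n >= 3) & (ssx > 0)
    slope[~defined] = np.nan
    se[~defined] = np.nan
    return slope, se, n, defined


def asdmp_screen(dataset: MethylomeDataset, group_a, group_b) -> pd.DataFrame:
    """Slope-difference screen between two sample groups.

    ``group_a``/``group_b`` are pandas query strings or boolean masks and
    must not overlap.  Returns one row per probe with per-group slopes and
    SEs, the t statistic, Welch df, two-sided uncorrected p, the sign of
    (slope_a - slope_b), an ``ok`` flag and the rank among defined probes
    (ascending p, ties by |t| descending then probe_id).
    """
    mask_a = dataset.sample_mask(group_a)
    mask_b = dataset.sample_mask(group_b)
    if (mask_a & mask_b).any():
        raise DataError("group filters overlap")
    ages = dataset.ages.to_numpy(dtype=float)
    values = dataset.beta.to_numpy(dtype=float)
    res = {}
    for tag, mask in (("a", mask_a), ("b", mask_b)):
        if mask.sum() < 3:
            raise DataError(f"group_{tag} has {mask.sum()} samples; need >= 3")
        slope, se, n, ok = _slopes_by_probe(values[:, mask], ages[mask])
        res[tag] = (slope, se, n, ok)
    slope_a, se_a, n_a, ok_a = res["a"]
    slope_b, se_b, n_b, ok_b = res["b"]
    with np.errstate(invalid="ignore", divide="ignore"):
        var_a, var_b = se_a ** 2, se_b ** 2
        t = (slope_a - slope_b) / np.sqrt(var_a + var_b)
        df = (var_a + var_b) ** 2 / (var_a ** 2 / (n_a - 2)
                                     + var_b ** 2 / (n_b - 2))
    ok = ok_a & ok_b & np.isfinite(t)
    # identical zero-noise groups: t = 0/0; define as no difference
    both_zero = ok_a & ok_b & (var_a + var_b == 0)
    t[both_zero & np.isclose(slope_a, slope_b)] = 0.0
    df[both_zero] = (n_a + n_b - 4)[both_zero]
    ok |= both_zero & np.isclose(slope_a, slope_b)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "probe_id": dataset.beta.index,
        "slope_a": slope_a, "slope_b": slope_b,
        "se_a": se_a, "se_b": se_b,
        "t": t, "df": df, "p": p,
        "direction": np.sign(slope_a - slope_b),
        "ok": ok,
    }).set_index("probe_id", drop=False)
    out.index.name = None
    out.loc[~out["ok"], ["t", "df", "p", "direction"]] = np.nan
    out["rank"] = np.nan
    ranked = _ranked_order(out[out["ok"]])
    out.loc[ranked, "rank"] = np.arange(1, len(ranked) + 1, dtype=float)
    return out


def _ranked_order(results: pd.DataFrame) -> list[str]:
    tbl = results.assign(abs_t=results["t"].abs())
    tbl = tbl.sort_values(["p", "abs_t", "probe_id"],
                          ascending=[True, False, True], kind="mergesort")
    return tbl["probe_id"].tolist()


def rank_and_select(results: pd.DataFrame, k: int = 50) -> list[str]:
    """Top-k probe ids by ascending p; ties by |t| descending then probe_id."""
    if k <= 0:
        return []
    return _ranked_order(results[results["ok"]])[:k]


def chrom_distribution(probe_list, annotation: pd.DataFrame,
                       universe) -> dict:
    """Observed vs expected per-chromosome counts of a probe list against a
    probe universe, with a goodness-of-fit chi-square."""
    probe_list = list(map(str, probe_list))
    universe = list(map(str, universe))
    missing = [p for p in probe_list if p not in annotation.index]
    if missing:
        raise DataError(f"probes missing from annotation: {missing}")
    uni_chrom = annotation.loc[universe, "chrom"]
    chroms = sorted(uni_chrom.unique())
    uni_counts = uni_chrom.value_counts().reindex(chroms, fill_value=0)
    obs = annotation.loc[probe_list, "chrom"].value_counts() \
        .reindex(chroms, fill_value=0)
    expected = uni_counts / uni_counts.sum() * len(probe_list)
    keep = expected > 0
    chi2, p = stats.chisquare(obs[keep], expected[keep])
    table = pd.DataFrame({"observed": obs, "expected": expected})
    return {"table": table, "chi2": float(chi2), "p": float(p),
            "df": int(keep.sum() - 1)}


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z-test comparing two independent Pearson correlations."""
    if min(n1, n2) < 4:
        raise DataError("Fisher z needs >= 4 samples per group")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mass_window_association(dataset: MethylomeDataset, ranked_probes,
                            window_width: int = 100,
                            group_a="castrated == False",
                            group_b="castrated == True") -> pd.DataFrame:
    """Window-of-k mass association along the asDMP ranking.

    The caller restricts ``dataset`` to the cohort of interest (juvenile
    males in the study design).  Probes are cut into consecutive
    non-overlapping rank-order windows; per window the per-sample mean beta
    is correlated with body mass within each group and the two correlations
    compared by Fisher z.
    """
    missing_mass = dataset.samples.index[dataset.samples["mass"].isna()]
    if len(missing_mass):
        raise DataError(f"samples lack mass: {missing_mass.tolist()}")
    ranked_probes = list(ranked_probes)
    n_windows = len(ranked_probes) // window_width
    if n_windows < 2:
        raise DataError(
            f"{len(ranked_probes)} probes give {n_windows} full windows of "
            f"{window_width}; need >= 2")
    mask_a = dataset.sample_mask(group_a)
    mask_b = dataset.sample_mask(group_b)
    mass = dataset.samples["mass"].to_numpy(dtype=float)
    rows = []
    for w in range(n_windows):
        probes = ranked_probes[w * window_width:(w + 1) * window_width]
        means = dataset.beta.loc[probes].mean(axis=0).to_numpy(dtype=float)
        rec = {"window": w + 1}
        undefined = False
        for tag, mask in (("a", mask_a), ("b", mask_b)):
            m, mm = means[mask], mass[mask]
            if np.std(m) == 0 or np.std(mm) == 0 or mask.sum() < 4:
                rec[f"r_{tag}"], rec[f"n_{tag}"] = np.nan, int(mask.sum())
                undefined = True
            else:
                rec[f"r_{tag}"] = float(stats.pearsonr(m, mm)[0])
                rec[f"n_{tag}"] = int(mask.sum())
        if undefined:
            rec["z"], rec["p"], rec["ok"] = np.nan, np.nan, False
        else:
            rec["z"], rec["p"] = fisher_z_diff(rec["r_a"], rec["n_a"],
                                               rec["r_b"], rec["n_b"])
            rec["ok"] = True
        rows.append(rec)
    return pd.DataFrame(rows).set_index("window", drop=False)


def dimorphism_expression_test(expression: dict, dimorphic: dict) -> dict:
    """Two-sample t-test of a gene's expression between tissues that do and
    do not show sexually dimorphic methylation (pooled variance)."""
    tissues = sorted(expression)
    if set(tissues) != set(dimorphic):
        raise DataError("expression and dimorphic tissue sets differ")
    hi = [expression[t] for t in tissues if dimorphic[t]]
    lo = [expression[t] for t in tissues if not dimorphic[t]]
    if len(hi) < 2 or len(lo) < 2:
        raise DataError("need >= 2 tissues per class")
    if np.var(hi) == 0 and np.var(lo) == 0:
        # degenerate: no within-class spread; equal means carry no evidence
        same = np.mean(hi) == np.mean(lo)
        t_stat, p_val = (0.0, 1.0) if same else (np.inf, 0.0)
    else:
        res = stats.ttest_ind(hi, lo, equal_var=True)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return {"t": t_stat, "p": p_val,
            "mean_dimorphic": float(np.mean(hi)),
            "mean_other": float(np.mean(lo)),
            "n_dimorphic": len(hi), "n_other": len(lo)}
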