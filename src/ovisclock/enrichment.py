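"""Observed-vs-expected transcription-factor binding enrichment at top
asDMPs with an empirical bootstrap null.

For each factor, the observed quantity is the percentage of the k top-ranked
probes overlapped by >=1 of its peaks.  The null is built by drawing k
probes uniformly without replacement from the whole mapped probe universe,
``n_boot`` times (1000 by default, matching the 50-random-CpG bootstrap
design), and recording the bound percentage per replicate.  The empirical
one-sided p uses the add-one convention, p = (1 + #{replicate >= observed})
/ (n_boot + 1), so the smallest reportable p at 1000 replicates is 1/1001
(printed as p < 0.001).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import DataError, MethylomeDataset, TFBindingTable, probes_overlapping


def _bound_matrix(table: TFBindingTable, annotation: pd.DataFrame,
                  universe: list[str]):
    """Boolean probes x TFs matrix of peak overlap over the universe."""
    tfs = table.tf_names
    pos = {p: i for i, p in enumerate(universe)}
    bound = np.zeros((len(universe), len(tfs)), dtype=bool)
    for j, tf in enumerate(tfs):
        for probe in probes_overlapping(tf, table, annotation, universe):
            bound[pos[probe], j] = True
    return bound, tfs


def enrich(top_probes, table: TFBindingTable, annotation: pd.DataFrame,
           universe, n_boot: int = 1000, seed: int | None = None) -> pd.DataFrame:
    """Bootstrap enrichment of TF binding at ``top_probes`` against random
    same-size probe sets from ``universe``.

    Returns one row per factor: observed_pct, expected_pct (replicate mean;
    the median is also emitted), boot_min/boot_max, fold, p_emp, flagged.
    A zero expected with nonzero observed yields fold = +inf, flagged; zero
    observed and expected yields fold = NaN, flagged.  Deterministic given
    ``seed``.
    """
    top_probes = list(map(str, top_probes))
    universe = sorted(map(str, set(universe)))
    k = len(top_probes)
    if k == 0:
        raise DataError("empty top probe set")
    if k > len(universe):
        raise DataError(f"k={k} exceeds universe size {len(universe)}")
    outside = sorted(set(top_probes) - set(universe))
    if outside:
        raise DataError(f"top probes outside universe: {outside}")
    bound, tfs = _bound_matrix(table, annotation, universe)
    top_idx = np.array([universe.index(p) for p in top_probes])
    observed = bound[top_idx].mean(axis=0) * 100.0

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(tfs)))
    n_universe = len(universe)
    for b in range(n_boot):
        draw = rng.choice(n_universe, size=k, replace=False)
        boot[b] = bound[draw].mean(axis=0) * 100.0
    expected = boot.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = observed / expected
    fold = np.where((expected == 0) & (observed > 0), np.inf, fold)
    fold = np.where((expected == 0) & (observed == 0), np.nan, fold)
    p_emp = (1 + (boot >= observed[None, :]).sum(axis=0)) / (n_boot + 1)
    out = pd.DataFrame({
        "tf_name": tfs,
        "observed_pct": observed,
        "expected_pct": expected,
        "expected_pct_median": np.median(boot, axis=0),
        "boot_min": boot.min(axis=0),
        "boot_max": boot.max(axis=0),
        "fold": fold,
        "p_emp": p_emp,
    }).set_index("tf_name", drop=False)
    out.index.name = None
    out["flagged"] = _flag_mask(out)
    return out


def _flag_mask(results: pd.DataFrame, fold_threshold: float = 2.0,
               abs_diff_threshold_pct: float = 1.0) -> pd.Series:
    fold = results["fold"]
    diff = (results["observed_pct"] - results["expected_pct"]).abs()
    extreme = (fold > fold_threshold) | (fold < 1.0 / fold_threshold)
    return extreme & (diff > abs_diff_threshold_pct)


def flag(results: pd.DataFrame, fold_threshold: float = 2.0,
         abs_diff_threshold_pct: float = 1.0) -> pd.DataFrame:
    """Factors with fold > threshold (or < 1/threshold) AND an absolute
    observed-expected difference above ``abs_diff_threshold_pct`` (both
    strict inequalities)."""
    return results[_flag_mask(results, fold_threshold, abs_diff_threshold_pct)]


def batch_scan(ranked_probes, table: TFBindingTable, annotation: pd.DataFrame,
               universe, batch_size: int = 50, n_boot: int = 1000,
               seed: int | None = None) -> list[pd.DataFrame]:
    """Enrichment scan over consecutive non-overlapping rank-order batches.

    Lets the decay of enrichment down the ranking be seen (signal confined
    to the top batches, background thereafter).  A trailing short batch is
    analyzed with a warning.
    """
    ranked_probes = list(ranked_probes)
    if not ranked_probes:
        raise DataError("empty ranked probe list")
    out = []
    for start in range(0, len(ranked_probes), batch_size):
        batch = ranked_probes[start:start + batch_size]
        if len(batch) < batch_size:
            warnings.warn(f"final batch has only {len(batch)} probes",
                          stacklevel=2)
        # per-batch seed offset keeps batches independent while the first
        # batch reproduces enrich() with the same seed exactly
        batch_seed = None if seed is None else seed + start // batch_size
        res = enrich(batch, table, annotation, universe, n_boot=n_boot,
                     seed=batch_seed)
        res.insert(0, "batch", start // batch_size + 1)
        out.append(res)
    return out
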