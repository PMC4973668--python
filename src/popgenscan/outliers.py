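"""Empirical FST outlier windows and the modified nearest-neighbour-index test.

Outlier windows are the top quantile (1% and 5% by default) of valid
non-overlapping-window FST values.  Whether outliers cluster along the
genome is tested with a nearest-neighbour index (NNI) adapted to a
multi-chromosome genome: distances are counted in window-bin units and only
within linkage groups, and the null expectation is taken from permutations
(re-drawing the same number of outlier windows uniformly among all valid
windows genome-wide) rather than from the classical points-per-length
formula, which assumes one linear genome.  The modified NNI is
``observed mean NN distance / permutation mean``; values below 1 indicate
clustering.  Significance is assessed both by a Z-statistic against the
permutation distribution and by the empirical permutation p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admixture import z_to_p

logger = logging.getLogger("popgenscan.outliers")


@dataclass(frozen=True)
class NNIResult:
    """Modified nearest-neighbour-index test outcome."""

    n_outliers: int
    obs_mean_nn: float
    perm_mean: float
    perm_sd: float
    nni: float
    z: float
    p_emp: float
    p_z: float
    n_perm: int
    n_empty_perm: int
    seed: int


def top_quantile_windows(window_stats: pd.DataFrame, q: float) -> np.ndarray:
    """Boolean flags for the ``ceil(q * n)`` highest-FST valid windows.

    Ties at the cutoff are broken by genome order (the row order of
    *window_stats*, which is (linkage group, start)) for determinism.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    n = len(window_stats)
    if n == 0:
        raise ValueError("no valid windows to flag outliers in")
    k = math.ceil(q * n)
    fst = window_stats["fst"].to_numpy(dtype=float)
    order = np.lexsort((np.arange(n), -fst))  # descending FST, then genome order
    flags = np.zeros(n, dtype=bool)
    flags[order[:k]] = True
    return flags


def _mean_nn_distance(lg_codes: np.ndarray, bins: np.ndarray) -> float:
    """Mean over outliers of the min within-LG bin distance; NaN if no pair shares an LG."""
    if lg_codes.size < 2:
        return float("nan")
    order = np.lexsort((bins, lg_codes))
    c = lg_codes[order]
    b = bins[order]
    diff = np.abs(np.diff(b)).astype(float)
    same = c[1:] == c[:-1]
    prev = np.full(c.size, np.inf)
    nxt = np.full(c.size, np.inf)
    prev[1:][same] = diff[same]
    nxt[:-1][same] = diff[same]
    nn = np.minimum(prev, nxt)
    has = np.isfinite(nn)
    if not has.any():
        return float("nan")
    return float(nn[has].mean())


def nearest_neighbour_distances(
    flags: np.ndarray, lg: np.ndarray, bins: np.ndarray
) -> np.ndarray:
    """Per-outlier nearest-neighbour distances in bin units, within LGs only.

    Outliers that are the sole outlier on their linkage group contribute no
    distance (their count is logged, not an error).
    """
    flags = np.asarray(flags, dtype=bool)
    c = pd.factorize(np.asarray(lg)[flags])[0]
    b = np.asarray(bins)[flags].astype(np.int64)
    order = np.lexsort((b, c))
    c = c[order]
    b = b[order]
    diff = np.abs(np.diff(b)).astype(float)
    same = c[1:] == c[:-1]
    prev = np.full(c.size, np.inf)
    nxt = np.full(c.size, np.inf)
    prev[1:][same] = diff[same]
    nxt[:-1][same] = diff[same]
    nn = np.minimum(prev, nxt)
    lone = int((~np.isfinite(nn)).sum())
    if lone:
        logger.info("%d outliers are alone on their linkage group (no distance)", lone)
    return nn[np.isfinite(nn)]


def nni_permutation_test(
    window_stats: pd.DataFrame,
    flags: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NNIResult:
    """Modified-NNI permutation test for clustering of outlier windows.

    *window_stats* must carry ``lg`` and ``bin`` columns for all valid
    windows; *flags* marks the outliers.  Each permutation re-draws the same
    number of outliers uniformly without replacement among all valid windows
    genome-wide and recomputes the mean within-LG nearest-neighbour bin
    distance.  NNI = observed / permutation mean; Z compares the observed
    statistic with the permutation distribution; the empirical p is
    one-sided toward clustering with the +1 correction.  Permutations whose
    outliers share no linkage group have an undefined statistic and are
    excluded from the permutation mean/sd (their count is reported).
    """
    flags = np.asarray(flags, dtype=bool)
    k = int(flags.sum())
    if k < 2:
        raise ValueError("need at least 2 outlier windows")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lg_codes = pd.factorize(window_stats["lg"].to_numpy())[0]
    bins = window_stats["bin"].to_numpy(dtype=np.int64)
    n = lg_codes.size

    observed = _mean_nn_distance(lg_codes[flags], bins[flags])
    if math.isnan(observed):
        raise ValueError("observed outliers share no linkage group; NNI undefined")

    rng = np.random.default_rng(seed)
    stats = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        stats[i] = _mean_nn_distance(lg_codes[idx], bins[idx])
    defined = ~np.isnan(stats)
    n_empty = int((~defined).sum())
    good = stats[defined]
    if good.size == 0:
        raise ValueError("every permutation replicate had an undefined statistic")
    perm_mean = float(good.mean())
    perm_sd = float(good.std(ddof=1)) if good.size > 1 else 0.0
    nni = observed / perm_mean if perm_mean > 0 else float("nan")
    if perm_sd > 0:
        z = (observed - perm_mean) / perm_sd
        p_z = z_to_p(z)
    else:
        logger.warning("degenerate permutation distribution (sd = 0); Z undefined")
        z = float("nan")
        p_z = float("nan")
    p_emp = (1 + int((good <= observed).sum())) / (n_perm + 1)
    return NNIResult(
        n_outliers=k,
        obs_mean_nn=observed,
        perm_mean=perm_mean,
        perm_sd=perm_sd,
        nni=nni,
        z=z,
        p_emp=p_emp,
        p_z=p_z,
        n_perm=n_perm,
        n_empty_perm=n_empty,
        seed=seed,
    )


def nni_report_all(
    window_stats_by_comparison: Mapping[str, pd.DataFrame],
    quantiles: Sequence[float] = (0.01, 0.05),
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One NNI test row per comparison x outlier quantile."""
    rows = []
    for i, (label, stats) in enumerate(window_stats_by_comparison.items()):
        for j, q in enumerate(quantiles):
            flags = top_quantile_windows(stats, q)
            res = nni_permutation_test(stats, flags, n_perm=n_perm, seed=seed + 131 * i + j)
            rows.append(
                {
                    "comparison": label,
                    "quantile": q,
                    "n_outliers": res.n_outliers,
                    "obs_mean_nn": res.obs_mean_nn,
                    "perm_mean": res.perm_mean,
                    "perm_sd": res.perm_sd,
                    "nni": res.nni,
                    "z": res.z,
                    "p_emp": res.p_emp,
                    "p_z": res.p_z,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "quantile", "n_outliers", "obs_mean_nn", "perm_mean",
            "perm_sd", "nni", "z", "p_emp", "p_z", "n_perm", "seed",
        ],
    )
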