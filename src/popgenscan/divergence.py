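"""Relative (FST) and absolute (DXY) divergence, window scans, p-distances.

FST uses the Weir & Cockerham (1984) variance-component estimator for a
biallelic site: among-population (a), between-individual-within-population
(b) and within-individual (c) components, with the site estimate
``a / (a + b + c)``.  Window estimates combine sites as a ratio of sums
(``sum(a) / sum(a+b+c)``), which is stabler than averaging per-site ratios
when per-site information is low.

DXY is the mean between-population allelic difference per site,
``pA(1-pB) + pB(1-pA)`` averaged over the sites usable in both populations.

Windows are 0-based half-open internally; VCF positions are converted from
1-based on use.  Window makers emit full-size windows anchored at each
linkage group's origin (a linkage group shorter than one window yields a
single truncated window).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_data import GenomeLayout
from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger("popgenscan.divergence")

WINDOW_COLUMNS = ["lg", "start", "end", "n_sites", "fst", "dxy"]


# ---------------------------------------------------------------------------
# Weir-Cockerham site components
# ---------------------------------------------------------------------------

def _pop_site_summaries(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n genotyped, alt frequency, het proportion) for one population."""
    ok = dosages != MISSING
    n = ok.sum(axis=0).astype(float)
    alt = np.where(ok, dosages, 0).sum(axis=0)
    het = (np.where(ok, dosages, 0) == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def site_variance_components(
    n1: float | np.ndarray,
    p1: float | np.ndarray,
    h1: float | np.ndarray,
    n2: float | np.ndarray,
    p2: float | np.ndarray,
    h2: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) components (a, b, c) for a two-population site.

    Parameters are per population: diploid sample size ``n``, alternate
    allele frequency ``p`` and observed heterozygote proportion ``h``.
    Vectorised over sites.  Sites with fewer than 2 genotyped diploids in
    either population yield NaN components (callers skip them).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return a, b, c


def site_fst(gm: GenotypeMatrix, popA: str, popB: str) -> pd.DataFrame:
    """Per-site WC84 components, FST and DXY for one population pair.

    Returns a DataFrame aligned with ``gm.sites`` (columns ``a b c fst dxy``);
    unusable sites (under 2 genotyped diploids in either population) are NaN.
    """
    dA = gm.dosages[gm.pop_rows(popA)]
    dB = gm.dosages[gm.pop_rows(popB)]
    n1, p1, h1 = _pop_site_summaries(dA)
    n2, p2, h2 = _pop_site_summaries(dB)
    a, b, c = site_variance_components(n1, p1, h1, n2, p2, h2)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        fst = np.where(np.abs(denom) > 0, a / denom, np.nan)
        dxy = np.where((n1 > 0) & (n2 > 0), p1 * (1 - p2) + p2 * (1 - p1), np.nan)
    return pd.DataFrame({"a": a, "b": b, "c": c, "fst": fst, "dxy": dxy})


# ---------------------------------------------------------------------------
# Window makers
# ---------------------------------------------------------------------------

def sliding_windows(
    layout: GenomeLayout,
    size: int = 1_000_000,
    step: int = 100_000,
    min_sites: int = 10_000,
) -> pd.DataFrame:
    """Sliding windows [start, start+size) per linkage group, starts 0, step apart.

    Only fully contained windows are emitted, except that a linkage group
    shorter than *size* yields a single truncated window.  *min_sites* is
    recorded in ``attrs`` and applied when windows are populated with sites.
    """
    if size < step:
        raise ValueError("window size must be >= step")
    rows: list[tuple[str, int, int]] = []
    for lg, length in zip(layout.lg_names, layout.lg_lengths):
        if length < size:
            rows.append((lg, 0, int(length)))
            continue
        start = 0
        while start + size <= length:
            rows.append((lg, start, start + size))
            start += step
    df = pd.DataFrame(rows, columns=["lg", "start", "end"])
    df.attrs["min_sites"] = min_sites
    return df


def nonoverlapping_windows(
    layout: GenomeLayout, size: int = 100_000, min_sites: int = 1_000
) -> pd.DataFrame:
    """Non-overlapping tiling (step = size); bin number is ``start // size``."""
    df = sliding_windows(layout, size=size, step=size, min_sites=min_sites)
    df["bin"] = df["start"] // size
    df.attrs["min_sites"] = min_sites
    return df


# ---------------------------------------------------------------------------
# Windowed divergence
# ---------------------------------------------------------------------------

def window_divergence(
    gm: GenotypeMatrix,
    popA: str,
    popB: str,
    windows: pd.DataFrame,
    min_sites: int | None = None,
) -> pd.DataFrame:
    """FST and DXY per genomic window for one population pair.

    Window FST is the ratio of summed WC84 components over the window's
    usable sites; window DXY is the mean per-site between-population allelic
    difference.  A site counts toward ``n_sites`` only when usable in both
    populations; windows with fewer than *min_sites* such sites (default:
    the window maker's recorded threshold) are omitted.
    """
    if min_sites is None:
        min_sites = int(windows.attrs.get("min_sites", 1))
    per_site = site_fst(gm, popA, popB)
    lg_arr = gm.sites["lg"].to_numpy()
    pos0 = gm.sites["pos"].to_numpy() - 1  # 0-based
    a_v = per_site["a"].to_numpy()
    den_v = a_v + per_site["b"].to_numpy() + per_site["c"].to_numpy()
    dxy_v = per_site["dxy"].to_numpy()
    usable = ~np.isnan(dxy_v) & ~np.isnan(a_v)

    # per-LG prefix sums over usable sites -> O(sites + windows) aggregation
    by_lg: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for lg in pd.unique(lg_arr):
        sel = (lg_arr == lg) & usable
        p = pos0[sel]
        by_lg[lg] = (
            p,
            np.concatenate([[0.0], np.cumsum(a_v[sel])]),
            np.concatenate([[0.0], np.cumsum(den_v[sel])]),
            np.concatenate([[0.0], np.cumsum(dxy_v[sel])]),
            np.concatenate([[0], np.cumsum(np.ones(p.size, dtype=np.int64))]),
        )

    out_rows = []
    has_bin = "bin" in windows.columns
    for row in windows.itertuples(index=False):
        entry = by_lg.get(row.lg)
        if entry is None:
            continue
        p, cum_a, cum_den, cum_dxy, cum_n = entry
        lo = int(np.searchsorted(p, row.start, side="left"))
        hi = int(np.searchsorted(p, row.end, side="left"))
        n = int(cum_n[hi] - cum_n[lo])
        if n == 0 or n < min_sites:
            continue
        a = cum_a[hi] - cum_a[lo]
        denom = cum_den[hi] - cum_den[lo]
        fst = a / denom if denom != 0 else np.nan
        dxy = (cum_dxy[hi] - cum_dxy[lo]) / n
        rec = {"lg": row.lg, "start": row.start, "end": row.end,
               "n_sites": n, "fst": fst, "dxy": dxy}
        if has_bin:
            rec["bin"] = row.bin
        out_rows.append(rec)
    cols = WINDOW_COLUMNS + (["bin"] if has_bin else [])
    return pd.DataFrame(out_rows, columns=cols)


def genome_fst(
    gm: GenotypeMatrix,
    popA: str,
    popB: str,
    layout: GenomeLayout,
    size: int = 100_000,
    min_sites: int = 1,
) -> float:
    """Genome-wide FST: unweighted mean of non-negative 100-kb window values.

    Windows with negative FST are removed before averaging.  Returns NaN
    when no window survives.
    """
    windows = nonoverlapping_windows(layout, size=size, min_sites=min_sites)
    stats = window_divergence(gm, popA, popB, windows, min_sites=min_sites)
    result = mean_nonnegative_fst(stats["fst"].to_numpy(dtype=float))
    if np.isnan(result):
        logger.warning("genome_fst(%s, %s): no non-negative windows", popA, popB)
    return result


def mean_nonnegative_fst(values: np.ndarray) -> float:
    """Unweighted mean of window FST values after removing negative windows.

    NaN windows are ignored; returns NaN when nothing survives (the
    undefined-result marker for identical populations).
    """
    values = np.asarray(values, dtype=float)
    vals = values[~np.isnan(values) & (values >= 0)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def genome_fst_matrix(
    gm: GenotypeMatrix,
    layout: GenomeLayout,
    pops: Sequence[str] | None = None,
    size: int = 100_000,
    min_sites: int = 1,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise genome-wide FST values."""
    pops = list(pops) if pops is not None else gm.populations()
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = genome_fst(gm, a, b, layout, size=size, min_sites=min_sites)
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


# ---------------------------------------------------------------------------
# Uncorrected p-distances
# ---------------------------------------------------------------------------

def p_distance_matrix(gm: GenotypeMatrix, percent: bool = False) -> pd.DataFrame:
    """Uncorrected pairwise p-distance between samples.

    Each jointly genotyped site contributes ``|d_i - d_j| / 2`` for dosages
    ``d`` (0 for identical genotypes, 0.5 het vs hom, 1 opposite
    homozygotes), averaged over shared sites.  NaN where a pair shares no
    genotyped site.  ``percent=True`` scales by 100.
    """
    if gm.n_samples < 2:
        raise ValueError("p-distance needs at least two samples")
    d = gm.dosages.astype(float)
    d[gm.dosages == MISSING] = np.nan
    n = gm.n_samples
    ids = gm.sample_ids()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.abs(d[i] - d[j]) / 2.0
            shared = ~np.isnan(diff)
            if shared.sum() == 0:
                logger.warning("samples %s and %s share no genotyped sites", ids[i], ids[j])
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = float(np.nanmean(diff))
    if percent:
        out = out * 100.0
    return pd.DataFrame(out, index=ids, columns=ids)


def write_windows_tsv(stats: pd.DataFrame, path) -> None:
    """Write window statistics as BED-like TSV (0-based half-open coordinates)."""
    stats.to_csv(path, sep="\t", index=False)
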