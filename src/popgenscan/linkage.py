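"""Linkage-disequilibrium decay with distance and cross-LG background.

LD between two SNPs is measured as the squared Pearson correlation (r²) of
unphased 0/1/2 dosage vectors (composite LD) over pairwise-complete
samples.  Within-linkage-group pairs are averaged in physical-distance
bins; the background is the mean r² between SNPs on different linkage
groups, which is what within-LG decay converges to once sites are
effectively unlinked.  The profile reports the first distance bin at which
mean r² reaches background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger("popgenscan.linkage")

#: Distance bin edges in bp: 0-10 kb, 10-50, 50-100, 100-500 kb, 0.5-1 Mb, 1-5 Mb.
DEFAULT_BIN_EDGES = (0, 10_000, 50_000, 100_000, 500_000, 1_000_000, 5_000_000)

#: Minimum jointly genotyped samples for a pair to be usable.
MIN_COMPLETE = 4


@dataclass(frozen=True)
class LDDecayProfile:
    """Mean r² per distance bin plus the cross-LG background level."""

    population: str
    bin_edges: tuple[int, ...]
    bin_mean_r2: np.ndarray  # NaN where a bin holds no usable pair
    bin_n_pairs: np.ndarray
    background_mean_r2: float  # NaN when only one linkage group is present
    background_n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "bin_start": self.bin_edges[i],
                "bin_end": self.bin_edges[i + 1],
                "mean_r2": self.bin_mean_r2[i],
                "n_pairs": int(self.bin_n_pairs[i]),
            }
            for i in range(len(self.bin_edges) - 1)
        ]
        rows.append(
            {
                "bin_start": -1,
                "bin_end": -1,
                "mean_r2": self.background_mean_r2,
                "n_pairs": self.background_n_pairs,
            }
        )
        return pd.DataFrame(rows)


def genotype_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise-complete).

    Returns NaN when fewer than :data:`MIN_COMPLETE` samples are jointly
    genotyped or either site is monomorphic among them (the pair is then
    excluded from averages, signalled by the NaN rather than an exception).
    """
    dos_i = np.asarray(dos_i)
    dos_j = np.asarray(dos_j)
    ok = (dos_i != MISSING) & (dos_j != MISSING)
    if ok.sum() < max(2, MIN_COMPLETE):
        return float("nan")
    x = dos_i[ok].astype(float)
    y = dos_j[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pair_r2_batch(d: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    """Vectorised r² for site-index pairs (columns of dosage matrix *d*)."""
    x = d[:, idx_i].astype(float)
    y = d[:, idx_j].astype(float)
    mx = d[:, idx_i] != MISSING
    my = d[:, idx_j] != MISSING
    ok = mx & my
    n = ok.sum(axis=0).astype(float)
    x[~ok] = 0.0
    y[~ok] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = x.sum(axis=0) / n
        sy = y.sum(axis=0) / n
        sxx = (x * x).sum(axis=0) / n - sx * sx
        syy = (y * y).sum(axis=0) / n - sy * sy
        sxy = (x * y).sum(axis=0) / n - sx * sy
        r2 = sxy * sxy / (sxx * syy)
    r2[(n < max(2, MIN_COMPLETE)) | (sxx <= 0) | (syy <= 0)] = np.nan
    return r2


def ld_decay(
    gm: GenotypeMatrix,
    pop: str,
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    max_pairs_per_bin: int = 50_000,
    max_background_pairs: int = 2_000_000,
    seed: int = 0,
) -> LDDecayProfile:
    """LD decay profile for one population.

    Within-LG site pairs are assigned to distance bins by ``|pos_i - pos_j|``
    and subsampled uniformly (seeded) when a bin exceeds
    *max_pairs_per_bin*; the background is estimated from up to
    *max_background_pairs* random cross-LG pairs.  Pairs with an undefined
    r² (missingness, monomorphism) are excluded from the averages.
    """
    edges = np.asarray(bin_edges)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    rows = gm.pop_rows(pop)
    if rows.size < 4:
        raise ValueError(f"population {pop!r} has {rows.size} samples; need >= 4")
    d = gm.dosages[rows]
    rng = np.random.default_rng(seed)
    lg = gm.sites["lg"].to_numpy()
    pos = gm.sites["pos"].to_numpy()

    n_bins = edges.size - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for g in pd.unique(lg):
        cols = np.flatnonzero(lg == g)
        if cols.size < 2:
            continue
        p = pos[cols]
        ii, jj = np.triu_indices(cols.size, k=1)
        dist = p[jj] - p[ii]  # positions sorted, so nonnegative
        which = np.searchsorted(edges, dist, side="right") - 1
        inside = (which >= 0) & (which < n_bins)
        for b in range(n_bins):
            sel = np.flatnonzero(inside & (which == b))
            if sel.size == 0:
                continue
            if sel.size > max_pairs_per_bin:
                sel = rng.choice(sel, size=max_pairs_per_bin, replace=False)
            r2 = _pair_r2_batch(d, cols[ii[sel]], cols[jj[sel]])
            good = ~np.isnan(r2)
            sums[b] += r2[good].sum()
            counts[b] += int(good.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        bin_means = np.where(counts > 0, sums / counts, np.nan)

    # cross-LG background
    lgs = pd.unique(lg)
    if lgs.size < 2:
        logger.warning("single linkage group: cross-LG background undefined")
        bg_mean, bg_n = float("nan"), 0
    else:
        n_sites = lg.size
        lg_codes = pd.factorize(lg)[0]
        want = max_background_pairs
        draw = min(want * 2, 4_000_000)
        a = rng.integers(0, n_sites, size=draw)
        b_ = rng.integers(0, n_sites, size=draw)
        cross = lg_codes[a] != lg_codes[b_]
        a, b_ = a[cross][:want], b_[cross][:want]
        bg_sum = 0.0
        bg_n = 0
        chunk = 200_000
        for s in range(0, a.size, chunk):
            r2 = _pair_r2_batch(d, a[s : s + chunk], b_[s : s + chunk])
            good = ~np.isnan(r2)
            bg_sum += r2[good].sum()
            bg_n += int(good.sum())
        bg_mean = bg_sum / bg_n if bg_n else float("nan")

    return LDDecayProfile(
        population=pop,
        bin_edges=tuple(int(e) for e in edges),
        bin_mean_r2=bin_means,
        bin_n_pairs=counts,
        background_mean_r2=bg_mean,
        background_n_pairs=bg_n,
    )


def background_crossing(profile: LDDecayProfile) -> tuple[int, int] | None:
    """First distance bin whose mean r² is at or below background.

    Returns the (bin_start, bin_end) pair in bp, or ``None`` when decay
    never reaches the background level (or background is undefined).
    """
    if np.isnan(profile.background_mean_r2):
        raise ValueError("profile has no background estimate")
    for i in range(len(profile.bin_edges) - 1):
        m = profile.bin_mean_r2[i]
        if not np.isnan(m) and m <= profile.background_mean_r2:
            return (profile.bin_edges[i], profile.bin_edges[i + 1])
    return None
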