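"""Genotype-matrix data model, VCF input/output, quality masks and site filters.

The central container is :class:`GenotypeMatrix`: a diploid dosage matrix
(samples x sites, values 0/1/2 with ``-1`` for missing) plus per-site
metadata (linkage group, 1-based bp position, alleles, site QUAL, mapping
quality) and per-sample metadata (population, species, site code).
Optional per-genotype depth (DP) and genotype-quality (GQ) layers carry the
information the RAD-seq quality masks operate on.

Filtering follows the usual RAD pipeline cascade: site-level quality/mapping
thresholds, genotype-level GQ/DP masks (including a per-sample high-coverage
percentile cut), biallelic/missingness/minor-allele-frequency site filters,
distance thinning to obtain approximately unlinked markers, and preparation
of a complete-data unlinked panel with the stationary mutation rates (u, v)
required by SNP-based species-tree inference (SNAPP).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("popgenscan.variant_io")

#: Sentinel dosage for a missing genotype.
MISSING = -1

SAMPLE_COLUMNS = ["id", "population", "species", "site_code"]
SITE_COLUMNS = ["lg", "pos", "ref", "alt", "qual", "mq", "n_alt"]


class VCFParseError(ValueError):
    """Raised when a VCF cannot be parsed into the genotype data model."""


class DegeneratePanelError(ValueError):
    """Raised when a SNAPP panel has a fixed mean allele frequency (0 or 1)."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with site and sample metadata.

    Attributes
    ----------
    samples
        One row per sample: ``id``, ``population``, ``species``, ``site_code``.
    sites
        One row per site, sorted by (``lg``, ``pos``): ``lg``, ``pos`` (1-based
        bp), ``ref``, ``alt``, ``qual``, ``mq``, ``n_alt``.
    dosages
        ``int8`` array of shape (n_samples, n_sites); alternate-allele dosage
        in {0, 1, 2} or :data:`MISSING`.
    depth, geno_qual
        Optional per-genotype DP / GQ layers with the same shape.
    """

    samples: pd.DataFrame
    sites: pd.DataFrame
    dosages: np.ndarray
    depth: np.ndarray | None = None
    geno_qual: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.sites = self.sites.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosages shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or -1 (missing)")
        self._check_sorted_sites()

    def _check_sorted_sites(self) -> None:
        if len(self.sites) < 2:
            return
        lg = self.sites["lg"].to_numpy()
        pos = self.sites["pos"].to_numpy()
        order = np.lexsort((pos, lg))
        if not np.array_equal(order, np.arange(len(pos))):
            raise ValueError("sites must be sorted by (linkage group, position)")
        same_lg = lg[1:] == lg[:-1]
        if np.any(same_lg & (pos[1:] == pos[:-1])):
            raise ValueError("duplicate positions within a linkage group")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_ids(self) -> list[str]:
        return self.samples["id"].tolist()

    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def pop_rows(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        rows = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if rows.size == 0:
            raise KeyError(f"no samples in population {population!r}")
        return rows

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to the given sample ids (kept in the given order)."""
        index = {s: i for i, s in enumerate(self.samples["id"])}
        missing_ids = [s for s in ids if s not in index]
        if missing_ids:
            raise KeyError(f"unknown sample ids: {missing_ids}")
        rows = np.array([index[s] for s in ids], dtype=int)
        return GenotypeMatrix(
            samples=self.samples.iloc[rows],
            sites=self.sites,
            dosages=self.dosages[rows],
            depth=None if self.depth is None else self.depth[rows],
            geno_qual=None if self.geno_qual is None else self.geno_qual[rows],
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Restrict to sites where boolean *mask* (or an index array) selects."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            cols = np.flatnonzero(mask)
        else:
            cols = mask
        return GenotypeMatrix(
            samples=self.samples,
            sites=self.sites.iloc[cols],
            dosages=self.dosages[:, cols],
            depth=None if self.depth is None else self.depth[:, cols],
            geno_qual=None if self.geno_qual is None else self.geno_qual[:, cols],
        )

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per site over non-missing genotypes.

        Returns NaN for sites with no genotyped sample among *rows*.
        """
        d = self.dosages if rows is None else self.dosages[rows]
        ok = d != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def missing_fraction(self) -> np.ndarray:
        """Fraction of missing genotypes per site."""
        return (self.dosages == MISSING).mean(axis=0)


# ---------------------------------------------------------------------------
# Population map and VCF input
# ---------------------------------------------------------------------------

def load_pop_map(path: str | Path) -> pd.DataFrame:
    """Read a sample->population TSV (columns: sample, population[, species, site_code])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs at least two columns (sample, population)")
    df = df.rename(columns={df.columns[0]: "id", df.columns[1]: "population"})
    if "species" not in df.columns:
        df["species"] = df["population"]
    if "site_code" not in df.columns:
        df["site_code"] = ""
    return df[SAMPLE_COLUMNS]


def _sample_table(ids: Sequence[str], pop_map) -> pd.DataFrame:
    if isinstance(pop_map, (str, Path)):
        pop_map = load_pop_map(pop_map)
    if isinstance(pop_map, pd.DataFrame):
        table = pop_map.set_index("id")
        unmapped = [s for s in ids if s not in table.index]
        if unmapped:
            raise KeyError(f"samples absent from population map: {unmapped}")
        sub = table.loc[list(ids)].reset_index()
        for col in ("species", "site_code"):
            if col not in sub.columns:
                sub[col] = sub["population"] if col == "species" else ""
        return sub[SAMPLE_COLUMNS]
    if isinstance(pop_map, Mapping):
        unmapped = [s for s in ids if s not in pop_map]
        if unmapped:
            raise KeyError(f"samples absent from population map: {unmapped}")
        return pd.DataFrame(
            {
                "id": list(ids),
                "population": [pop_map[s] for s in ids],
                "species": [pop_map[s] for s in ids],
                "site_code": ["" for _ in ids],
            }
        )
    raise TypeError("pop_map must be a mapping, DataFrame or TSV path")


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    pop_map=None,
) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Diploid genotypes become alternate-allele dosages (multi-allelic records
    are read against the first ALT and flagged through ``n_alt``; any
    genotype containing a no-call allele, including half-calls, is recorded
    as missing).  Positions keep the VCF 1-based inclusive convention.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises bare exceptions on malformed input
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    ids = list(vcf.samples)
    if sample_subset is not None:
        unknown = [s for s in sample_subset if s not in ids]
        if unknown:
            raise KeyError(f"samples not in VCF: {unknown}")
        keep_rows = np.array([ids.index(s) for s in sample_subset])
        ids = list(sample_subset)
    else:
        keep_rows = np.arange(len(ids))

    lgs: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    mqs: list[float] = []
    n_alts: list[int] = []
    dosages: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    gqs: list[np.ndarray] = []
    have_dp = have_gq = True

    try:
        for i, var in enumerate(vcf):
            lgs.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0] if var.ALT else ".")
            quals.append(var.QUAL if var.QUAL is not None else np.nan)
            mq = var.INFO.get("MQ")
            mqs.append(float(mq) if mq is not None else np.nan)
            n_alts.append(len(var.ALT))
            gt = var.gt_types[keep_rows].astype(np.int8)  # 0/1/2, 3 = unknown
            gt[gt == 3] = MISSING
            dosages.append(gt)
            dp = var.format("DP")
            if dp is None:
                have_dp = False
            else:
                depths.append(dp[keep_rows, 0].astype(np.int32))
            gq = var.format("GQ")
            if gq is None:
                have_gq = False
            else:
                gqs.append(gq[keep_rows, 0].astype(np.int32))
    except Exception as exc:
        raise VCFParseError(
            f"malformed VCF {path} near record {len(poss) + 1}: {exc}"
        ) from exc

    sites = pd.DataFrame(
        {
            "lg": lgs,
            "pos": np.array(poss, dtype=np.int64),
            "ref": refs,
            "alt": alts,
            "qual": quals,
            "mq": mqs,
            "n_alt": np.array(n_alts, dtype=np.int16),
        }
    )
    order = np.lexsort((sites["pos"].to_numpy(), sites["lg"].to_numpy()))
    sites = sites.iloc[order]
    dos = np.column_stack(dosages)[:, order] if dosages else np.zeros((len(ids), 0), np.int8)
    dp_arr = np.column_stack(depths)[:, order] if (have_dp and depths) else None
    gq_arr = np.column_stack(gqs)[:, order] if (have_gq and gqs) else None

    samples = _sample_table(ids, pop_map) if pop_map is not None else pd.DataFrame(
        {"id": ids, "population": "pop0", "species": "pop0", "site_code": ""}
    )
    return GenotypeMatrix(samples=samples, sites=sites, dosages=dos, depth=dp_arr, geno_qual=gq_arr)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write the matrix as VCF 4.2 with GT:DP:GQ genotype fields.

    Round-trips losslessly through :func:`read_vcf` (dosage 1 is written as
    the unphased het ``0/1``; missing as ``./.``).
    """
    if gm.n_sites == 0 or gm.n_samples == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    path = Path(path)
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lgs = gm.sites["lg"].to_numpy()
    lengths = {lg: int(gm.sites["pos"][lgs == lg].max()) for lg in pd.unique(lgs)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgenscan\n")
        for lg, ln in lengths.items():
            fh.write(f"##contig=<ID={lg},length={ln}>\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples["id"])
            + "\n"
        )
        depth = gm.depth
        gq = gm.geno_qual
        for j in range(gm.n_sites):
            site = gm.sites.iloc[j]
            qual = "." if pd.isna(site["qual"]) else f"{site['qual']:g}"
            info = "." if pd.isna(site["mq"]) else f"MQ={site['mq']:g}"
            fields = [
                str(site["lg"]),
                str(int(site["pos"])),
                ".",
                str(site["ref"]),
                str(site["alt"]),
                qual,
                "PASS",
                info,
                "GT:DP:GQ",
            ]
            for i in range(gm.n_samples):
                d = int(gm.dosages[i, j])
                dp = int(depth[i, j]) if depth is not None else 0
                q = int(gq[i, j]) if gq is not None else 0
                fields.append(f"{gt_str[d]}:{dp}:{q}")
            fh.write("\t".join(fields) + "\n")
    return path


def write_pop_map(gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write the two-column sample->population TSV companion file."""
    path = Path(path)
    gm.samples[SAMPLE_COLUMNS].rename(columns={"id": "sample"}).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Quality masks and site filters
# ---------------------------------------------------------------------------

def _nearest_rank_cutoff(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = np.sort(values)
    if v.size == 0:
        return math.inf
    k = max(1, math.ceil(percentile / 100.0 * v.size))
    return float(v[min(k, v.size) - 1])


def apply_quality_masks(
    gm: GenotypeMatrix,
    snp_qual: float = 20.0,
    geno_qual: float = 20.0,
    map_qual: float = 20.0,
    min_depth: int = 5,
    high_depth_percentile: float = 99.5,
) -> GenotypeMatrix:
    """Apply site- and genotype-level RAD quality masks.

    Sites with QUAL below *snp_qual* or mapping quality below *map_qual* are
    dropped (a value at or above the threshold passes; missing QUAL/MQ
    annotations pass).  Genotypes with GQ below *geno_qual*, depth below
    *min_depth*, or depth above the sample's own *high_depth_percentile*
    nearest-rank cutoff of its per-site depth distribution are set missing.
    """
    if gm.depth is None:
        raise ValueError("genotype matrix has no DP layer; quality masks need depths")
    if gm.geno_qual is None:
        raise ValueError("genotype matrix has no GQ layer; quality masks need genotype qualities")

    qual = gm.sites["qual"].to_numpy(dtype=float)
    mq = gm.sites["mq"].to_numpy(dtype=float)
    site_keep = (np.isnan(qual) | (qual >= snp_qual)) & (np.isnan(mq) | (mq >= map_qual))
    out = gm.subset_sites(site_keep)
    n_dropped = int((~site_keep).sum())
    if n_dropped:
        logger.info("quality masks: dropped %d sites below QUAL/MQ thresholds", n_dropped)

    dos = out.dosages.copy()
    present = dos != MISSING
    bad = present & ((out.geno_qual < geno_qual) | (out.depth < min_depth))
    # per-sample high-coverage cut over that sample's own per-site depths
    for i in range(out.n_samples):
        dp_i = out.depth[i][present[i]]
        cutoff = _nearest_rank_cutoff(dp_i, high_depth_percentile)
        bad[i] |= present[i] & (out.depth[i] > cutoff)
    n_masked = int(bad.sum())
    if n_masked:
        logger.info("quality masks: set %d genotypes missing (GQ/DP rules)", n_masked)
    dos[bad] = MISSING
    return replace(out, dosages=dos)


def filter_sites(
    gm: GenotypeMatrix,
    biallelic_only: bool = True,
    max_missing_frac: float = 1.0,
    min_maf: float = 0.0,
) -> GenotypeMatrix:
    """Site filters: biallelic, per-site missingness cap, minimum MAF.

    Minor-allele frequency is computed from non-missing dosages only.  An
    empty result is allowed (a warning is emitted, not an error).
    """
    for name, v in (("max_missing_frac", max_missing_frac), ("min_maf", min_maf)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    keep = np.ones(gm.n_sites, dtype=bool)
    if biallelic_only:
        keep &= gm.sites["n_alt"].to_numpy() == 1
    keep &= gm.missing_fraction() <= max_missing_frac
    if min_maf > 0:
        p = gm.allele_frequencies()
        maf = np.fmin(p, 1.0 - p)
        keep &= ~np.isnan(maf) & (maf >= min_maf)
    out = gm.subset_sites(keep)
    logger.info("site filters: kept %d of %d sites", out.n_sites, gm.n_sites)
    if out.n_sites == 0:
        warnings.warn("site filters removed every site", stacklevel=2)
    return out


def thin_by_distance(gm: GenotypeMatrix, min_bp: int = 500_000) -> GenotypeMatrix:
    """Greedy left-to-right distance thinning within each linkage group.

    The first site on each linkage group is kept; a subsequent site is kept
    iff its position is at least *min_bp* beyond the last kept position, so
    retained sites on one linkage group are pairwise >= *min_bp* apart.
    """
    lg = gm.sites["lg"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    keep = np.zeros(gm.n_sites, dtype=bool)
    last_lg: object = None
    last_pos = -np.inf
    for j in range(gm.n_sites):
        if lg[j] != last_lg or pos[j] - last_pos >= min_bp:
            keep[j] = True
            last_lg = lg[j]
            last_pos = pos[j]
    return gm.subset_sites(keep)


# ---------------------------------------------------------------------------
# SNAPP panel preparation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnappPanel:
    """Unlinked complete-data biallelic panel plus mutation-rate arithmetic.

    ``u`` and ``v`` are the backward and forward mutation rates that make the
    stationary distribution match the mean alternate-allele frequency
    ``pi1`` (with ``pi0 = 1 - pi1``) under the unit-rate normalisation
    ``pi1*u + pi0*v = 1``, i.e. ``u = 1/(2*pi1)`` and ``v = 1/(2*pi0)``.
    ``theta = alpha/beta`` is the mean of the gamma prior on the population
    size parameter.
    """

    site_index: np.ndarray
    pi1: float
    u: float
    v: float
    alpha: float
    beta: float

    @property
    def pi0(self) -> float:
        return 1.0 - self.pi1

    @property
    def theta(self) -> float:
        return self.alpha / self.beta

    @property
    def n_sites(self) -> int:
        return int(self.site_index.size)


def snapp_rates(pi1: float) -> tuple[float, float]:
    """Stationary unit-rate mutation rates (u, v) from mean derived frequency."""
    if not 0.0 < pi1 < 1.0:
        raise DegeneratePanelError(f"mean allele frequency {pi1} is fixed; rates undefined")
    return 1.0 / (2.0 * pi1), 1.0 / (2.0 * (1.0 - pi1))


def snapp_prepare(
    gm: GenotypeMatrix,
    min_bp: int = 500_000,
    alpha: float = 2.0,
    beta: float = 2000.0,
) -> SnappPanel:
    """Prepare the unlinked, complete-data panel and its rate parameters.

    Sites are restricted to those genotyped in every sample, thinned to a
    minimum spacing of *min_bp* within each linkage group, and summarised by
    the mean alternate-allele frequency ``pi1`` from which u and v follow.
    """
    if not (gm.sites["n_alt"].to_numpy() == 1).all():
        raise ValueError("SNAPP panel requires a biallelic-only matrix")
    complete = (gm.dosages != MISSING).all(axis=0)
    sub = gm.subset_sites(complete)
    thinned = thin_by_distance(sub, min_bp=min_bp)
    if thinned.n_sites == 0:
        raise DegeneratePanelError("no complete-data sites survive thinning")
    # map retained sites back to indices in the input matrix
    orig = np.flatnonzero(complete)
    key = set(
        zip(thinned.sites["lg"].tolist(), thinned.sites["pos"].tolist())
    )
    sel = [
        j
        for j in orig
        if (gm.sites["lg"].iat[j], gm.sites["pos"].iat[j]) in key
    ]
    pi1 = float(np.mean(thinned.dosages / 2.0))
    u, v = snapp_rates(pi1)
    logger.info("SNAPP panel: %d sites, pi1=%.4f, u=%.4f, v=%.4f", len(sel), pi1, u, v)
    return SnappPanel(site_index=np.array(sel), pi1=pi1, u=u, v=v, alpha=alpha, beta=beta)


def write_snapp_summary(panel: SnappPanel, gm: GenotypeMatrix, path: str | Path) -> Path:
    """Write the panel site list and rate summary as TSV."""
    path = Path(path)
    sites = gm.sites.iloc[panel.site_index][["lg", "pos"]]
    with open(path, "w") as fh:
        fh.write(f"# n_sites={panel.n_sites}\tpi1={panel.pi1:.6f}\tu={panel.u:.4f}\t"
                 f"v={panel.v:.4f}\ttheta={panel.theta:g}\talpha={panel.alpha:g}\t"
                 f"beta={panel.beta:g}\n")
        sites.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Merging per-population call sets
# ---------------------------------------------------------------------------

def merge_genotype_matrices(matrices: Iterable[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge call sets genotyped separately, by positional intersection.

    Sites are matched by (linkage group, position) across all inputs; a site
    is kept only when present in every input with consistent REF/ALT alleles
    (conflicts are dropped with a logged warning).  Sample sets must be
    disjoint.
    """
    mats = list(matrices)
    if not mats:
        raise ValueError("nothing to merge")
    if len(mats) == 1:
        return mats[0]
    ids = [s for m in mats for s in m.sample_ids()]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids overlap between call sets")

    keys = [
        {(lg, pos): j for j, (lg, pos) in enumerate(zip(m.sites["lg"], m.sites["pos"]))}
        for m in mats
    ]
    shared = set(keys[0])
    for k in keys[1:]:
        shared &= set(k)
    consistent = []
    n_conflict = 0
    for key in shared:
        alleles = {
            (m.sites["ref"].iat[k[key]], m.sites["alt"].iat[k[key]])
            for m, k in zip(mats, keys)
        }
        if len(alleles) == 1:
            consistent.append(key)
        else:
            n_conflict += 1
    if n_conflict:
        logger.warning("merge: dropped %d sites with conflicting REF/ALT", n_conflict)
    consistent.sort()
    cols = [np.array([k[key] for key in consistent], dtype=int) for k in keys]
    first = mats[0].subset_sites(cols[0])
    samples = pd.concat([m.samples for m in mats], ignore_index=True)
    dosages = np.vstack([m.dosages[:, c] for m, c in zip(mats, cols)])
    have_dp = all(m.depth is not None for m in mats)
    have_gq = all(m.geno_qual is not None for m in mats)
    return GenotypeMatrix(
        samples=samples,
        sites=first.sites,
        dosages=dosages,
        depth=np.vstack([m.depth[:, c] for m, c in zip(mats, cols)]) if have_dp else None,
        geno_qual=np.vstack([m.geno_qual[:, c] for m, c in zip(mats, cols)]) if have_gq else None,
    )
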