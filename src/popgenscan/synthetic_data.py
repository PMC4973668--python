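"""Synthetic multi-population SNP datasets with drift, admixture, LD and noise.

Emulates the statistical structure of a reduced-representation (RAD-seq)
SNP matrix: a handful of populations differentiated by genetic drift along
a rooted population tree, optional single-pulse admixture edges, linkage
disequilibrium that decays to background beyond a block span, per-genotype
missingness, and per-genotype depth/quality annotations so the filter
cascade is exercisable end to end.

Drift follows the Balding–Nichols model: given a parent frequency ``p`` and
a differentiation parameter ``F`` in (0, 1), a daughter population's
frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean ``p`` and yields
an expected Weir–Cockerham FST of about ``F`` against the parent.  Applied
recursively along the tree, internal branches induce the shared-drift
covariance that four-population (f4) tests rely on.

Linkage disequilibrium is induced by a Gaussian-copula device at the
haplotype level: haplotypes sample their alleles at every site in the same
*block* through one shared latent uniform, lightly perturbed per site, so
dosage correlation (r²) is high within a block and at background across
blocks, while single-site marginals remain exactly Binomial(2, p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .variant_io import MISSING, GenotypeMatrix, write_vcf  # noqa: F401  (write_vcf re-exported)

logger = logging.getLogger("popgenscan.synthetic_data")

Topology = tuple | str  # nested tuples of population labels, e.g. (("A","B"),("C","D"))


def _leaves(topology: Topology) -> list[str]:
    if isinstance(topology, str):
        return [topology]
    out: list[str] = []
    for child in topology:
        out.extend(_leaves(child))
    return out


@dataclass(frozen=True)
class PopulationModel:
    """Demography for frequency simulation.

    Parameters
    ----------
    topology
        Rooted population tree as nested tuples of unique leaf labels.
    drift_F
        Per-population Balding–Nichols differentiation in (0, 1); keys are
        leaf labels.  Internal branches use ``internal_F``.
    admix_edges
        Single-pulse admixture events ``(source, target, alpha)`` applied to
        the target's frequency after drift: ``(1-alpha)*own + alpha*source``.
    ancestral_freq_range
        Interval within (0, 1) from which ancestral frequencies are drawn
        uniformly per site.
    """

    topology: Topology
    drift_F: dict[str, float]
    admix_edges: tuple[tuple[str, str, float], ...] = ()
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    internal_F: float = 0.05

    def __post_init__(self) -> None:
        labels = _leaves(self.topology)
        if len(labels) != len(set(labels)):
            raise ValueError("topology leaves must be unique population labels")
        missing = set(labels) - set(self.drift_F)
        if missing:
            raise ValueError(f"drift_F missing populations: {sorted(missing)}")
        for pop, F in self.drift_F.items():
            if not 0.0 < F < 1.0:
                raise ValueError(f"drift_F[{pop!r}]={F} must be strictly in (0, 1)")
        if not 0.0 < self.internal_F < 1.0:
            raise ValueError("internal_F must be strictly in (0, 1)")
        for src, tgt, a in self.admix_edges:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"admixture proportion {a} for {src}->{tgt} not in [0, 1]")
            for p in (src, tgt):
                if p not in labels:
                    raise ValueError(f"admixture edge names unknown population {p!r}")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be an interval within (0, 1)")

    @property
    def populations(self) -> list[str]:
        return _leaves(self.topology)

    @property
    def n_pops(self) -> int:
        return len(self.populations)


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered linkage groups with lengths in bp (positions are 1-based)."""

    lg_names: tuple[str, ...]
    lg_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.lg_names) != len(self.lg_lengths):
            raise ValueError("lg_names and lg_lengths must align")
        if len(set(self.lg_names)) != len(self.lg_names):
            raise ValueError("linkage-group names must be unique")
        if any(length <= 0 for length in self.lg_lengths):
            raise ValueError("linkage-group lengths must be positive")

    @classmethod
    def uniform(cls, n_lg: int = 22, lg_bp: int = 40_000_000, prefix: str = "LG") -> "GenomeLayout":
        """Evenly sized linkage groups named ``LG01..LGnn``."""
        width = len(str(n_lg))
        return cls(
            lg_names=tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n_lg)),
            lg_lengths=tuple([lg_bp] * n_lg),
        )

    @property
    def total_bp(self) -> int:
        return sum(self.lg_lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lg": self.lg_names, "length_bp": self.lg_lengths})


def write_layout(layout: GenomeLayout, path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def load_layout(path) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    return GenomeLayout(tuple(df.iloc[:, 0].astype(str)), tuple(df.iloc[:, 1].astype(int)))


# ---------------------------------------------------------------------------
# Frequency simulation
# ---------------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Daughter frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); fixed sites stay fixed."""
    ratio = (1.0 - F) / F
    a = np.clip(p * ratio, 1e-12, None)
    b = np.clip((1.0 - p) * ratio, 1e-12, None)
    out = rng.beta(a, b)
    out[p <= 0.0] = 0.0
    out[p >= 1.0] = 1.0
    return out


def simulate_frequencies(
    model: PopulationModel, n_sites: int, seed: int
) -> pd.DataFrame:
    """Per-population allele-frequency table (n_sites x populations).

    Ancestral frequencies are uniform on ``model.ancestral_freq_range``;
    each branch applies one Balding–Nichols drift step (leaf branches use
    the leaf's ``drift_F``, internal branches ``internal_F``); admixture
    edges then replace the target by the alpha-mixture with the source.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = model.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=n_sites)

    freqs: dict[str, np.ndarray] = {}

    def descend(node: Topology, parent: np.ndarray) -> None:
        # every branch (leaf or internal) applies one drift step from its parent
        if isinstance(node, str):
            freqs[node] = _balding_nichols(rng, parent, model.drift_F[node])
            return
        here = _balding_nichols(rng, parent, model.internal_F)
        for child in node:
            descend(child, here)

    if isinstance(model.topology, str):
        descend(model.topology, ancestral)
    else:
        # the root itself contributes no drift; its children do
        for child in model.topology:
            descend(child, ancestral)

    for src, tgt, a in model.admix_edges:
        freqs[tgt] = (1.0 - a) * freqs[tgt] + a * freqs[src]

    table = pd.DataFrame({pop: freqs[pop] for pop in model.populations})
    assert ((table.to_numpy() >= 0.0) & (table.to_numpy() <= 1.0)).all()
    return table


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def _place_sites(rng: np.random.Generator, layout: GenomeLayout, n_sites: int) -> pd.DataFrame:
    """Uniform site placement over the genome; unique positions per LG, sorted."""
    weights = np.array(layout.lg_lengths, dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(n_sites, weights)
    lgs: list[str] = []
    poss: list[np.ndarray] = []
    for name, length, k in zip(layout.lg_names, layout.lg_lengths, counts):
        if k == 0:
            continue
        if k > length:
            raise ValueError(f"cannot place {k} unique sites on {name} of length {length}")
        # rejection-sample unique positions (avoids permuting the whole LG)
        pos = np.unique(rng.integers(1, length + 1, size=int(k * 1.2) + 16))
        while pos.size < k:
            extra = rng.integers(1, length + 1, size=k)
            pos = np.unique(np.concatenate([pos, extra]))
        if pos.size > k:
            pos = np.sort(rng.choice(pos, size=k, replace=False))
        lgs.extend([name] * k)
        poss.append(pos)
    return pd.DataFrame(
        {"lg": lgs, "pos": np.concatenate(poss) if poss else np.array([], dtype=np.int64)}
    )


def sample_genotypes(
    freqs: pd.DataFrame,
    layout: GenomeLayout,
    n_per_pop: dict[str, int] | int,
    missing_rate: float = 0.0,
    ld_block_bp: int = 0,
    seed: int = 0,
    site_noise: float = 0.1,
    mean_depth: float = 20.0,
) -> GenotypeMatrix:
    """Draw diploid genotypes from the frequency table onto a genome layout.

    Each individual carries two haplotypes; within an ``ld_block_bp`` block
    on a linkage group a haplotype's alleles at every site derive from one
    shared latent uniform (re-drawn per site with probability *site_noise*),
    so r² is high within blocks and at background beyond them while each
    site's allele frequency stays exact.  ``ld_block_bp=0`` makes all sites
    independent.  Genotypes are masked missing i.i.d. at *missing_rate*, and
    Poisson depths plus genotype/site quality fields are attached so
    filtering can be exercised.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    pops = list(freqs.columns)
    if isinstance(n_per_pop, int):
        n_per_pop = {p: n_per_pop for p in pops}
    if set(n_per_pop) != set(pops):
        raise ValueError(
            f"n_per_pop populations {sorted(n_per_pop)} do not match model populations {sorted(pops)}"
        )
    rng = np.random.default_rng(seed)
    n_sites = len(freqs)
    sites = _place_sites(rng, layout, n_sites)
    lg_arr = sites["lg"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    if ld_block_bp > 0:
        lg_code = pd.factorize(lg_arr)[0].astype(np.int64)
        block_id = lg_code * (max(layout.lg_lengths) // ld_block_bp + 2) + (
            (pos_arr - 1) // ld_block_bp
        )
    else:
        block_id = np.arange(n_sites)  # every site its own block -> independence
    block_codes = pd.factorize(block_id)[0]
    n_blocks = int(block_codes.max()) + 1 if n_sites else 0

    sample_ids: list[str] = []
    sample_pops: list[str] = []
    rows: list[np.ndarray] = []
    for pop in pops:
        n = n_per_pop[pop]
        p = freqs[pop].to_numpy()
        for k in range(n):
            hap_dos = np.zeros(n_sites, dtype=np.int8)
            for _hap in range(2):
                u = rng.uniform(size=n_blocks)[block_codes]
                fresh = rng.uniform(size=n_sites)
                use_fresh = rng.uniform(size=n_sites) < site_noise
                u = np.where(use_fresh, fresh, u)
                hap_dos += (u < p).astype(np.int8)
            rows.append(hap_dos)
            sample_ids.append(f"{pop}_{k:02d}")
            sample_pops.append(pop)
    dosages = np.vstack(rows)

    if missing_rate > 0:
        mask = rng.uniform(size=dosages.shape) < missing_rate
        dosages = np.where(mask, MISSING, dosages).astype(np.int8)

    depth = rng.poisson(mean_depth, size=dosages.shape).astype(np.int32)
    depth[dosages == MISSING] = 0
    # genotype quality roughly tracks depth, capped at 99
    gq = np.minimum(99, (depth * 3 + rng.integers(0, 10, size=dosages.shape))).astype(np.int32)
    gq[dosages == MISSING] = 0

    site_table = pd.DataFrame(
        {
            "lg": lg_arr,
            "pos": pos_arr.astype(np.int64),
            "ref": "A",
            "alt": "T",
            "qual": np.round(rng.uniform(30, 60, size=n_sites), 1),
            "mq": np.round(rng.uniform(40, 60, size=n_sites), 1),
            "n_alt": np.int16(1),
        }
    )
    samples = pd.DataFrame(
        {
            "id": sample_ids,
            "population": sample_pops,
            "species": sample_pops,
            "site_code": "",
        }
    )
    # layout order may differ from lexicographic (lg, pos) order required downstream
    order = np.lexsort((site_table["pos"].to_numpy(), site_table["lg"].to_numpy()))
    site_table = site_table.iloc[order]
    logger.info(
        "simulated %d samples x %d sites (ld_block_bp=%d, missing_rate=%.2f)",
        len(sample_ids), n_sites, ld_block_bp, missing_rate,
    )
    return GenotypeMatrix(
        samples=samples,
        sites=site_table,
        dosages=dosages[:, order],
        depth=depth[:, order],
        geno_qual=gq[:, order],
    )


# ---------------------------------------------------------------------------
# One-call study-like dataset
# ---------------------------------------------------------------------------

def default_model() -> PopulationModel:
    """Four drift-differentiated populations on a balanced tree, no admixture."""
    return PopulationModel(
        topology=(("popA", "popB"), ("popC", "popD")),
        drift_F={"popA": 0.05, "popB": 0.05, "popC": 0.05, "popD": 0.05},
        internal_F=0.05,
    )


def simulate_dataset(
    model: PopulationModel | None = None,
    layout: GenomeLayout | None = None,
    n_sites: int = 25_000,
    n_per_pop: dict[str, int] | int = 12,
    missing_rate: float = 0.1,
    ld_block_bp: int = 200_000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GenomeLayout]:
    """Generate a study-shaped dataset (~25k SNPs over 22 linkage groups)."""
    model = model or default_model()
    layout = layout or GenomeLayout.uniform()
    freqs = simulate_frequencies(model, n_sites, seed=seed)
    gm = sample_genotypes(
        freqs,
        layout,
        n_per_pop=n_per_pop,
        missing_rate=missing_rate,
        ld_block_bp=ld_block_bp,
        seed=seed + 1,
    )
    return gm, layout
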