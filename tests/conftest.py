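"""Shared fixtures: hand-built and simulated genotype matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popgenscan import GenomeLayout, GenotypeMatrix, PopulationModel
from popgenscan.synthetic_data import sample_genotypes, simulate_frequencies


def make_gm(
    dosages,
    populations=None,
    lg=None,
    pos=None,
    depth=None,
    geno_qual=None,
    qual=50.0,
    mq=50.0,
):
    """Build a GenotypeMatrix from a plain dosage array with sane defaults."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    if populations is None:
        populations = ["pop0"] * n_samples
    if lg is None:
        lg = ["LG01"] * n_sites
    if pos is None:
        pos = 1 + 1000 * np.arange(n_sites)
    samples = pd.DataFrame(
        {
            "id": [f"s{i:02d}" for i in range(n_samples)],
            "population": populations,
            "species": populations,
            "site_code": "",
        }
    )
    sites = pd.DataFrame(
        {
            "lg": lg,
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": "A",
            "alt": "T",
            "qual": np.broadcast_to(np.asarray(qual, dtype=float), (n_sites,)).copy(),
            "mq": np.broadcast_to(np.asarray(mq, dtype=float), (n_sites,)).copy(),
            "n_alt": np.int16(1),
        }
    )
    return GenotypeMatrix(
        samples=samples,
        sites=sites,
        dosages=dosages,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        geno_qual=None if geno_qual is None else np.asarray(geno_qual, dtype=np.int32),
    )


@pytest.fixture(scope="session")
def two_pop_gm():
    """Two drift-differentiated populations, moderate size, no LD, complete data."""
    model = PopulationModel(topology=("A", "B"), drift_F={"A": 0.1, "B": 0.1})
    freqs = simulate_frequencies(model, 4000, seed=11)
    layout = GenomeLayout.uniform(n_lg=6, lg_bp=10_000_000)
    gm = sample_genotypes(freqs, layout, n_per_pop=12, missing_rate=0.0,
                          ld_block_bp=0, seed=12)
    return gm, layout


@pytest.fixture(scope="session")
def four_pop_gm():
    """Balanced four-population tree without admixture, some missingness."""
    model = PopulationModel(
        topology=(("A", "B"), ("C", "D")),
        drift_F={p: 0.05 for p in "ABCD"},
    )
    freqs = simulate_frequencies(model, 5000, seed=21)
    layout = GenomeLayout.uniform(n_lg=8, lg_bp=20_000_000)
    gm = sample_genotypes(freqs, layout, n_per_pop=8, missing_rate=0.05,
                          ld_block_bp=0, seed=22)
    return gm, layout
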