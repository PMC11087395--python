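import numpy as np
import pandas as pd
import pytest

from kaspanel import simulate as sim
from kaspanel.datamodel import VariantTable


@pytest.fixture(scope="session")
def desk_dataset():
    """One small full simulation shared across tests (seed pinned)."""
    cfg, regions = sim.desk_scale_config(seed=7, scale=0.02)
    ds = sim.generate_dataset(cfg, regions)
    return ds


@pytest.fixture(scope="session")
def desk_config():
    cfg, regions = sim.desk_scale_config(seed=7, scale=0.02)
    return cfg, regions


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_variant_table(rng, n_sites=50, samples=("S1", "S2", "S3", "S4")):
    """Small random biallelic table with some missingness."""
    pos = np.sort(rng.choice(np.arange(1, 100_000), size=n_sites, replace=False))
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, n_sites)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    sites = pd.DataFrame({"chrom": "1", "pos": pos, "ref": ref, "alt": alt})
    geno = pd.DataFrame(
        rng.choice([0, 1, 2, -1], p=[0.4, 0.2, 0.3, 0.1], size=(n_sites, len(samples))),
        columns=list(samples),
    )
    return VariantTable(sites, geno).validate()


@pytest.fixture
def small_table(rng):
    return random_variant_table(rng)


def driver_class_means(ds, min_class=10):
    """Per-population class means at each population's driver locus.

    Returns dict with lists germ_pos/germ_neg/meso_pos/meso_neg (10 cm),
    one entry per population whose driver has both homozygote classes of at
    least ``min_class`` progeny.
    """
    from kaspanel.datamodel import HOM_ALT, HOM_REF

    pops, ph = ds["populations"], ds["phenotypes"]
    out = {"germ_pos": [], "germ_neg": [], "meso_pos": [], "meso_neg": []}
    for pop, marker in ds["drivers"].items():
        if marker is None:
            continue
        idx = pops.index[pops == pop]
        col = ds["truth"].loc[idx, marker]
        pos_idx = col.index[col == HOM_ALT]
        neg_idx = col.index[col == HOM_REF]
        if len(pos_idx) < min_class or len(neg_idx) < min_class:
            continue
        out["germ_pos"].append(ph.loc[pos_idx, "germination_pct_10cm"].mean())
        out["germ_neg"].append(ph.loc[neg_idx, "germination_pct_10cm"].mean())
        out["meso_pos"].append(ph.loc[pos_idx, "mesocotyl_cm_10cm"].mean())
        out["meso_neg"].append(ph.loc[neg_idx, "mesocotyl_cm_10cm"].mean())
    return out
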