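import numpy as np
import pandas as pd
import pytest

from cernet.cerna import build_cerna
from cernet.diffexpr import call_de, wilcoxon_de
from cernet.dysreg import build_dysreg
from cernet.synthetic import SimConfig, simulate_cohort, write_fixture_bundle

SMALL_CONFIG = SimConfig(
    n_subtypes=3,
    n_tumor_per_subtype=30,
    n_normal=30,
    n_mrna=150,
    n_lncrna=40,
    n_mirna=80,
    n_couples=10,
    couple_mirna_pool=40,
    seed=7,
)


@pytest.fixture(scope="session")
def default_sim():
    """One cohort under the standard fixture settings."""
    return simulate_cohort(SimConfig(seed=0))


def run_network_stages(sim, subtype, dysreg_p=0.01, shared_fdr=0.01, min_r=0.5, corr_fdr=0.01):
    """DE -> dysreg -> ceRNA for one subtype of a simulated cohort."""
    expr, ann = sim.expression, sim.annotation
    called = pd.concat(
        [call_de(wilcoxon_de(mat, ann, subtype)) for mat in expr.values()],
        ignore_index=True,
    )
    de_mirnas = set(called.loc[called["class"] == "miRNA", "gene"])
    de_targets = dict(
        zip(
            called.loc[called["class"] != "miRNA", "gene"],
            called.loc[called["class"] != "miRNA", "class"],
        )
    )
    tumor = ann.samples_in(subtype)
    dnet = build_dysreg(de_mirnas, de_targets, sim.target_map, expr, subtype, tumor, dysreg_p)
    cnet = build_cerna(dnet, expr, tumor, shared_fdr, min_r, corr_fdr)
    return called, dnet, cnet


@pytest.fixture(scope="session")
def default_networks(default_sim):
    """Called DE tables and both networks for every subtype of the default cohort."""
    out = {}
    for s in default_sim.config.subtypes:
        out[s] = run_network_stages(default_sim, s)
    return out


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 3-subtype fixture bundle on disk for pipeline-level tests."""
    sim = simulate_cohort(SMALL_CONFIG)
    directory = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(sim, directory, overwrite=True)
    return sim, directory, paths


def exact_corr_vector(rng, base: np.ndarray, r: float) -> np.ndarray:
    """A vector whose sample correlation with ``base`` is exactly ``r``."""
    noise = rng.normal(size=base.size)
    b = base - base.mean()
    n = noise - noise.mean()
    n = n - (n @ b) / (b @ b) * b  # orthogonalize
    b = b / np.sqrt(b @ b)
    n = n / np.sqrt(n @ n)
    return r * b + np.sqrt(1 - r * r) * n
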