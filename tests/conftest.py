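import numpy as np
import pytest

from mtspike.synthetic_data import SequencingSpec, SubsetTruth, \
    draw_cell_heteroplasmy


def subset_vafs(seed, n, pi_true, mu=0.02, sigma=0.05):
    """Seeded per-cell VAFs from a planted subset, nudged into (0,1)."""
    rng = np.random.default_rng(seed)
    t = SubsetTruth("S", "T", n_cells=n, pi_true=pi_true,
                    mu_true=mu, sigma_true=sigma)
    y = draw_cell_heteroplasmy(t, rng, size=n)
    return np.clip(y, 1e-4, 1 - 1e-4)


@pytest.fixture(scope="session")
def error_free_spec():
    """Sequencing layer with no miscalls, doublets, failures or
    contamination and uniformly high base qualities: the configuration in
    which the read-level pipeline is an exact identity."""
    return SequencingSpec(error_rate=0.0, doublet_rate=0.0,
                          failed_well_rate=0.0, contaminated_plate_rate=0.0,
                          base_quality_sd=0.0)
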