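import numpy as np
import pandas as pd
import pytest

from imputeqc import GenotypePanel, SimConfig, simulate_panel


def make_panel(dosages, positions=None, chrom="1", accessions=None, inbred=None):
    """Build a small panel from a dosage matrix."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if accessions is None:
        accessions = [f"a{i}" for i in range(n)]
    variants = pd.DataFrame({
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "T",
        "vid": [f"{chrom}_{p}" for p in positions],
    })
    if inbred is None:
        inbred = not (d == 1).any()
    return GenotypePanel(variants, accessions, d, inbred_mode=inbred)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated panel shared across tests (read-only)."""
    cfg = SimConfig(n_founders=8, n_accessions=60, n_variants=400,
                    chrom_length_bp=200_000, chip_fraction=0.4, seed=11)
    return simulate_panel(cfg)
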