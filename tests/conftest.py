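import numpy as np
import pandas as pd
import pytest

from recscan import PhasedPanel, PlantedHaplotype, SimConfig, simulate_panel


def make_panel(hap_rows, chrom="1", spacing=1000, samples=None):
    """Panel from a list of 0/1 strings (two consecutive rows per sample)."""
    hap = np.array([[int(c) for c in row] for row in hap_rows], dtype=np.uint8)
    n = hap.shape[0] // 2
    m = hap.shape[1]
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": spacing * np.arange(1, m + 1),
            "id": [f"m{j}" for j in range(m)],
        }
    )
    samples = samples or [f"s{i}" for i in range(n)]
    return PhasedPanel(markers, samples, hap)


@pytest.fixture
def six_sample_panel():
    # per-sample window-2 diplotypes: (11|00) x3, (00|00), (00|01), (01|00)
    rows = ["11", "00", "11", "00", "11", "00", "00", "00", "00", "01", "01", "00"]
    return make_panel(rows)


@pytest.fixture(scope="session")
def lethal_sim():
    """Planted embryonic-lethal haplotype at q=0.05 in a census of 4,843."""
    rng = np.random.default_rng(7)
    span = (400, 430)
    allele = "".join(rng.integers(0, 2, span[1] - span[0]).astype(str))
    planted = PlantedHaplotype(
        chromosome="1",
        marker_span=span,
        allele_string=allele,
        target_frequency=0.05,
        lethality="embryonic",
        penetrance=1.0,
    )
    cfg = SimConfig(
        n_samples=4843,
        n_chromosomes=1,
        markers_per_chromosome=1000,
        risk_haplotypes=(planted,),
        seed=11,
    )
    panel, truth = simulate_panel(cfg)
    return cfg, panel, truth
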