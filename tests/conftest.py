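import pandas as pd
import pytest

from cqscan import SimulationConfig, simulate_genome_layout, simulate_viral_hits


@pytest.fixture
def small_genome_config():
    """Two autosomes plus a sex chromosome with a window-aligned planted
    M locus; balanced 100/100 depth, no female leak."""
    return SimulationConfig(
        chrom_lengths={"1": 400_000, "2": 400_000, "3": 1_000_000},
        window_size=500,
        female_depth=100.0,
        male_depth=100.0,
        m_locus=("3", 200_000, 400_000),
        seed=11,
    )


@pytest.fixture
def viral_fixture():
    """Hit-table fixture: 10 planted integrations + 5 host false positives."""
    config = SimulationConfig(
        chrom_lengths={"1": 600_000, "2": 600_000, "3": 1_200_000},
        n_viral_hits=10,
        n_host_false_positives=5,
        seed=7,
    )
    layout = simulate_genome_layout(config)
    return simulate_viral_hits(config, layout)


def make_windows(rows):
    """Build a classified-window DataFrame from (chrom, start, end, f, m,
    maskfrac, cq, status) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "female_hits", "male_hits",
                 "masked_fraction", "cq", "status"],
    )
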