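import numpy as np
import pandas as pd
import pytest

from chipchip import (
    SimConfig,
    TrueDE,
    TrueRegion,
    default_truth_regions,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Zero-noise, flag-free dataset: 3 spiked regions, 4 DE genes at 14 h."""
    config = SimConfig(
        genome_length=40_000,
        n_genes=24,
        noise_sd=0.0,
        dye_bias=0.0,
        flag_rate=0.0,
        timepoints=(14.0,),
        rng_seed=11,
    )
    regions = [
        TrueRegion(center=6_000, shape="monophasic", amplitude=2.0, width=120.0),
        TrueRegion(center=18_000, shape="biphasic", amplitude=2.0, width=120.0,
                   peak_separation=600.0, amplitude_ratio=0.5),
        TrueRegion(center=31_000, shape="monophasic", amplitude=2.0, width=120.0),
    ]
    de = [
        TrueDE("SCO1003", 14.0, 1.5),
        TrueDE("SCO1008", 14.0, -1.5),
        TrueDE("SCO1015", 14.0, 1.5),
        TrueDE("SCO1020", 14.0, -1.5),
    ]
    chip, expr, ann, truth = simulate_dataset(config, regions, de)
    return {
        "config": config, "chip": chip, "expr": expr, "annotation": ann,
        "truth": truth, "regions": regions, "de": de,
    }


@pytest.fixture(scope="session")
def default_dataset():
    """The default noisy benchmark: 12 spiked regions in 100 kb at sd 0.3."""
    config = SimConfig(rng_seed=5)
    regions = default_truth_regions(config)
    chip, expr, ann, truth = simulate_dataset(config, regions, [])
    return {"config": config, "chip": chip, "expr": expr, "annotation": ann,
            "truth": truth, "regions": regions}


@pytest.fixture
def tiny_bundle():
    """Hand-sized bundle: 6 probes, one timepoint, 2 strains x 2 reps."""
    from chipchip.io import SignalBundle

    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(6)],
            "chrom": "chr",
            "start": [1, 101, 201, 301, 401, 501],
            "end": [60, 160, 260, 360, 460, 560],
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "d1", "d2"],
            "strain": ["comp", "comp", "del", "del"],
            "timepoint": [14.0] * 4,
            "replicate": [1, 2, 1, 2],
            "assay": ["chip"] * 4,
            "ip_dye": ["Cy5", "Cy3", "Cy5", "Cy3"],
        }
    )
    rng = np.random.default_rng(0)
    values = rng.normal(0, 1, (6, 4))
    flags = np.zeros((6, 4, 2), dtype=bool)
    return SignalBundle(probes=probes, samples=samples, raw_log2=values, flags=flags)
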