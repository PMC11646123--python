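import pytest

from splicemap.events import Thresholds, differential_test
from splicemap.regions import MapLayout, extract_regions
from splicemap.simulate import SimConfig, default_map_plants, simulate_events, simulate_genome


@pytest.fixture(scope="session")
def layout():
    return MapLayout()


@pytest.fixture(scope="session")
def small_cohort(layout):
    """300-event cohort with the default motif plants and truth labels."""
    cfg = SimConfig(seed=42, n_events=300, motif_plants=default_map_plants())
    events, truth = simulate_events(cfg)
    genome = simulate_genome(cfg, events, truth)
    regions = {e.event_id: extract_regions(e, genome, layout) for e in events}
    return {"config": cfg, "events": events, "truth": truth,
            "genome": genome, "regions": regions}


@pytest.fixture(scope="session")
def tested_cohort(small_cohort):
    """Same cohort with the stand-in differential test applied."""
    return differential_test(small_cohort["events"])


@pytest.fixture(scope="session")
def thresholds_small():
    return Thresholds(ref_sample_size=150)
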