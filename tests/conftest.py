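import numpy as np
import pytest

import nestvar as nv


@pytest.fixture(scope="session")
def small_design():
    """Compact study: 4 years x 8 sites, high occupancy, ~900 records."""
    return nv.StudyDesign(n_years=4, n_sites=8, occupancy=0.8, mean_visits_per_day=3)


@pytest.fixture(scope="session")
def small_table(small_design):
    table, truth = nv.generate_ivi_table(small_design, nv.GeneratorTruth(seed=3))
    return table, truth


@pytest.fixture(scope="session")
def small_frame(small_table):
    table, _ = small_table
    return nv.build_model_frame(table)


def spec_by_name(name: str) -> nv.ModelSpec:
    if name == "across_pairs":
        return nv.across_pairs_spec()
    return {s.name: s for s in nv.build_ladder()}[name]


@pytest.fixture(scope="session")
def quick_m1a_fit():
    """m1a fitted to data generated without random effects (n ~ 2000)."""
    design = nv.StudyDesign(n_years=4, n_sites=25, occupancy=0.9, mean_visits_per_day=4)
    truth = nv.GeneratorTruth(
        seed=21, sd_site=0.0, sd_pair=0.0, sd_year=(0.0, 0.0, 0.0),
        failure_rate=0.0, outlier_rate=0.0,
    )
    table, truth = nv.generate_ivi_table(design, truth)
    frame = nv.build_model_frame(table)
    cfg = nv.SamplerConfig(seed=4, chains=2, warmup=400, draws=400)
    return nv.fit(frame, spec_by_name("m1a"), cfg, check=False), truth, frame
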