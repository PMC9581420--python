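import numpy as np
import pytest

from urbanbirds import ingest
from urbanbirds.simulate import (SyntheticConfig, generate_community,
                                 generate_landscape)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across tests (30 sites, 10 species)."""
    cfg = SyntheticConfig(n_sites=30, n_species=10, seed=42)
    cov = generate_landscape(cfg)
    records, visits, truth = generate_community(cfg, cov)
    return {"config": cfg, "covariates": cov, "records": records,
            "visits": visits, "truth": truth}


@pytest.fixture(scope="session")
def small_responses(small_study):
    filtered = ingest.filter_detections(small_study["records"],
                                        purpose="presence")
    return ingest.build_responses(filtered, visits=small_study["visits"])


@pytest.fixture(scope="session")
def small_frames(small_study, small_responses):
    cov = small_study["covariates"].drop(columns=["x", "y"])
    frames = {}
    for season in ("winter", "spring"):
        sub = small_responses[small_responses["season"] == season]
        frames[season], _ = ingest.build_modeling_frame(sub, cov)
    return frames


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
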