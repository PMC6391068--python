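import numpy as np
import pytest

from enscircuit import analyze_movie, classify_records
from enscircuit.synthetic import SimMovieConfig, generate_movie


def small_movie_config(**overrides) -> SimMovieConfig:
    """Compact movie conditions for fast unit tests: same statistics as the
    defaults, smaller field and shorter inter-stimulus gap."""
    cfg = SimMovieConfig(
        field_size_um=(700.0, 550.0),
        n_ganglia=8,
        neurons_per_ganglion=2,
        stim_gap_s=15.0,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def noise_free_small():
    """Noise-free compact movie plus its analysis, shared across tests."""
    cfg = small_movie_config()
    movie, rois, truth = generate_movie(cfg, seed=11)
    responses = analyze_movie(movie, rois)
    records = classify_records(responses)
    return {
        "config": cfg,
        "movie": movie,
        "rois": rois,
        "truth": truth,
        "responses": responses,
        "records": records,
    }
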