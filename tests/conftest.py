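import numpy as np
import pytest
from hypothesis import settings

from isoweb.synthetic import (
    SimConfig,
    generate_community,
    sample_guts,
    sample_isotopes,
    write_fixture,
)
from isoweb.types import MixingProblem, SourceSpec

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def community():
    """Small seeded community used across modules."""
    cfg = SimConfig(
        n_sources=3,
        n_consumers=5,
        samples_per_taxon=20,
        gut_samples_per_consumer=20,
        seed=11,
    )
    truth = generate_community(cfg)
    isotopes = sample_isotopes(truth, cfg)
    guts = sample_guts(truth, cfg)
    return cfg, truth, isotopes, guts


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, community):
    cfg, truth, isotopes, guts = community
    outdir = tmp_path_factory.mktemp("fixture")
    write_fixture(truth, isotopes, guts, outdir)
    return outdir


@pytest.fixture()
def toy_two_source():
    """Two sources 10‰ apart on δ13C, consumer halfway between."""
    sources = [
        SourceSpec("A", -30.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
        SourceSpec("B", -20.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0),
    ]
    obs = np.random.default_rng(0).normal([-25.0, 0.0], 0.5, size=(10, 2))
    return MixingProblem("toy", obs, sources)


@pytest.fixture()
def triangle_sources():
    """Well-separated source triangle for polygon tests."""
    return [
        SourceSpec("A", -30.0, 0.5, 2.0, 0.5),
        SourceSpec("B", -20.0, 0.5, 2.0, 0.5),
        SourceSpec("C", -25.0, 0.5, 10.0, 0.5),
    ]
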