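"""Shared fixtures: a small synthetic cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import cereconn as cc
from cereconn import synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """Desk-scale cohort: 3 groups x 15 subjects, 2 sites, cerebellum only."""
    return synth.SynthConfig(
        n_per_group={"HC": 15, "MS": 15, "NMOSD": 15},
        n_sites=2,
        cerebral_regions=[],
        n_vertices_per_region=80,
        n_timepoints=150,
        n_genes=400,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synth.generate_all(small_config)


@pytest.fixture(scope="session")
def hc_multiplex(small_config, small_cohort):
    """Group-mean HC multiplex built from the small cohort."""
    cb = small_config.cerebellar_regions
    hc = small_cohort.cohort.loc[small_cohort.cohort.group == "HC", "id"]
    morph = [cc.morph_network(small_cohort.thickness[s], cb).matrix for s in hc]
    func = [cc.func_network(small_cohort.timeseries[s], small_config.regions, cb, cb).matrix for s in hc]
    return cc.build_group_multiplex(morph, func, cb)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
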