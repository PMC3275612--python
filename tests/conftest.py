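"""Shared fixtures: every dataset is generated at test time from the
synthetic module, so expensive populations are built once per session."""

import warnings

import numpy as np
import pandas as pd
import pytest

from flowworm.events import EventTable
from flowworm.pipeline import build_cycle_scheme, extract_cycle_profile
from flowworm.synth import (default_phase_model, make_dna_mixture,
                            sample_histogram, sample_population,
                            sample_replicates)

FIG2_SEED = 20120208  # fixed sampling seed for the proof-of-principle runs


@pytest.fixture(scope="session")
def model():
    return default_phase_model()


@pytest.fixture(scope="session")
def fig2_mixture():
    """The 8-component DNA mixture: 60% G1, 30% S (6 components), 10% G2+M."""
    return make_dna_mixture(0.60, 0.30, 0.10, g1_mean=100.0, cv=0.03,
                            n_s_components=6)


@pytest.fixture(scope="session")
def fig2_sample(fig2_mixture):
    return sample_histogram(fig2_mixture, 50_000, seed=FIG2_SEED)


@pytest.fixture(scope="session")
def pop50(model):
    """One 50k-event asynchronous population (age-weighted, default noise)."""
    return sample_population(model, 50_000, seed=7)


@pytest.fixture(scope="session")
def panels(model):
    """Two independently simulated single-cyclin panels with their schemes.

    Panel A measures cyclin A2 + PHH3 (+DNA), panel B cyclin B1 + PHH3
    (+DNA); each panel is segmented along its own cyclin-vs-PHH3 worm.
    """
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key, cyclin, seed in (("a2", "cyclin_a2", 11), ("b1", "cyclin_b1", 22)):
            pop = sample_population(model, 200_000, seed=seed)
            scheme = build_cycle_scheme(pop.events, cyclin)
            profile, labels = extract_cycle_profile(
                pop.events, scheme, ["dna", cyclin, "phh3"])
            out[key] = dict(pop=pop, scheme=scheme, profile=profile,
                            labels=labels, cyclin=cyclin)
    return out


@pytest.fixture(scope="session")
def dna_replicates(model):
    """Three independently stained/measured 50k replicates plus profiles.

    Used for the direct-vs-indirect DNA comparison: each replicate is
    analyzed independently (its own scheme, its own histogram boundaries).
    """
    from flowworm.pipeline import direct_dna_profile
    pops = sample_replicates(model, 50_000, 3, seed=777)
    indirect, direct = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for pop in pops:
            scheme = build_cycle_scheme(pop.events, "cyclin_a2")
            prof, _ = extract_cycle_profile(pop.events, scheme, ["dna"])
            indirect.append(prof)
            dprof, _ = direct_dna_profile(pop.events)
            direct.append(dprof)
    return dict(pops=pops, indirect=indirect, direct=direct)


@pytest.fixture()
def simple_events():
    """Tiny deterministic table for gate-algebra and assignment tests."""
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "x": rng.uniform(0, 10, 400),
        "y": rng.uniform(0, 10, 400),
    })
    return EventTable(data)
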