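"""Shared fixtures: small registries and seeded synthetic tables."""

import numpy as np
import pytest

import weevilinf as wv
from weevilinf.registry import CovariateSpec


@pytest.fixture(scope="session")
def registry():
    return wv.default_registry()


@pytest.fixture(scope="session")
def table138(registry):
    """One default-study synthetic table (n=138, calibrated truth)."""
    table, truth = wv.generate_dataset(registry, seed=11)
    return wv.attach_response(table), truth


@pytest.fixture(scope="session")
def small_registry():
    """Seven covariates: five strong reported effects plus two null controls."""
    full = {s.name: s for s in wv.default_registry()}
    names = ["perimeter_area", "storage_units", "insecticide_jan",
             "insecticide_dec", "current_potato", "soil_ph",
             "manure_fertilization"]
    return [full[n] for n in names]


@pytest.fixture(scope="session")
def small_table(small_registry):
    truth = wv.default_truth(small_registry, seed=5)
    table, truth = wv.generate_dataset(small_registry, truth=truth)
    return wv.attach_response(table), truth


def make_table(registry, seed, sigma=None, n_fields=138):
    truth = wv.default_truth(registry, seed=seed)
    if sigma is not None:
        truth = truth.with_(sigma=sigma)
    table, truth = wv.generate_dataset(registry, n_fields=n_fields, truth=truth)
    return wv.attach_response(table), truth
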