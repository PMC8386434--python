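"""Shared fixtures: synthetic studies and their derived products.

Expensive builds (default and yield-linked studies, their networks and
property tables) are session-scoped so the unit and acceptance suites share
one copy.
"""

from __future__ import annotations

import numpy as np
import pytest

from rhizonet import compositional as comp
from rhizonet import cooccurrence_networks as nets
from rhizonet import synthetic_data as sd


@pytest.fixture(scope="session")
def tiny_study():
    return sd.generate_study(sd.fixture_config("tiny", 7))


@pytest.fixture(scope="session")
def default_study():
    return sd.generate_study(sd.SyntheticConfig(seed=1))


def _networks_and_props(study):
    t16, tits, meta, truth = study
    inc16 = nets.incidence_matrix(t16)
    incits = nets.incidence_matrix(tits)
    n16 = nets.build_metacommunity(inc16, nets.filter_otus(inc16, 0.30), table=t16)
    nits = nets.build_metacommunity(incits, nets.filter_otus(incits, 0.10), table=tits)
    networks = {"16S": n16, "ITS": nits}
    props = nets.properties_table(networks, {"16S": t16, "ITS": tits}, meta)
    return networks, props


@pytest.fixture(scope="session")
def default_networks_props(default_study):
    return _networks_and_props(default_study)


@pytest.fixture(scope="session")
def default_clr(default_study):
    t16, tits, _, _ = default_study
    clr16 = comp.clr_transform(comp.replace_zeros(t16))
    clrits = comp.clr_transform(comp.replace_zeros(tits))
    return clr16, clrits


@pytest.fixture(scope="session")
def default_ordination(default_clr):
    clr16, clrits = default_clr
    return comp.joint_projection(clr16, clrits, n_components=70)


@pytest.fixture(scope="session")
def yield_linked_study():
    return sd.generate_study(sd.fixture_config("yield-linked", 2))


@pytest.fixture(scope="session")
def yield_linked_networks_props(yield_linked_study):
    return _networks_and_props(yield_linked_study)


@pytest.fixture(scope="session")
def yield_linked_ordination(yield_linked_study):
    t16, tits, _, _ = yield_linked_study
    clr16 = comp.clr_transform(comp.replace_zeros(t16))
    clrits = comp.clr_transform(comp.replace_zeros(tits))
    return comp.joint_projection(clr16, clrits, n_components=70)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
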