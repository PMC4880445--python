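import numpy as np
import pytest

from intasome import (
    FixtureConfig,
    assemble,
    load_registry,
    make_components,
)
from intasome.assembly import AssemblyModel, Bridge, build_core
from intasome.geometry import DuplexPath, generate_bdna
from intasome.registry import ensemble


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def components():
    return make_components(FixtureConfig(seed=0))


@pytest.fixture(scope="session")
def excisive_model(registry, components):
    return assemble("excisive", registry, components)


@pytest.fixture(scope="session")
def integrative_model(registry, components):
    return assemble("integrative", registry, components)


class MinimalModel(AssemblyModel):
    """A bare one-arm model (straight duplex, no proteins) for isolation tests."""


@pytest.fixture()
def bare_duplex_model(registry):
    n = 127
    path = generate_bdna("A" * n)
    junction = build_core()
    # park the junction far away so only the host duplex occludes
    from intasome.geometry import RigidTransform

    junction.transform = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
    dna = {
        "P": path,
        "P'": generate_bdna("A" * 76).transformed(
            RigidTransform(np.eye(3), np.array([0.0, 500.0, 0.0]))
        ),
        "B": generate_bdna("A" * 15).transformed(
            RigidTransform(np.eye(3), np.array([0.0, -500.0, 0.0]))
        ),
        "B'": generate_bdna("A" * 15).transformed(
            RigidTransform(np.eye(3), np.array([0.0, 0.0, 500.0]))
        ),
    }
    dna_att = {
        "P": -4 - np.arange(n),
        "P'": 4 + np.arange(76),
        "B": -4 - np.arange(15),
        "B'": 4 + np.arange(15),
    }
    return MinimalModel(
        pathway="excisive",
        registry=registry,
        ensemble=ensemble(registry, "excisive"),
        junction=junction,
        dna=dna,
        dna_att=dna_att,
        subunits=[],
        bridges=[],
        ntd_anchor={},
        ctd_anchor={},
    )
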