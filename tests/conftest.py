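import numpy as np
import pytest

import assemblage as asm
from assemblage.density import GridSpec
from assemblage.synthetic import generate_assembly


@pytest.fixture
def two_particle_model():
    """Two free spheres 8 Å apart along x."""
    m = asm.Model()
    m.create_particle("a", (0.0, 0.0, 0.0), radius=2.0, mass=100.0, subunit="A")
    m.create_particle("b", (8.0, 0.0, 0.0), radius=2.0, mass=100.0, subunit="B")
    return m


@pytest.fixture
def small_model():
    """Five free spheres in a deterministic random cloud."""
    rng = np.random.default_rng(42)
    m = asm.Model()
    for i in range(5):
        m.create_particle(
            f"P.{i + 1}",
            rng.uniform(-15, 15, 3),
            radius=float(rng.uniform(1.5, 4.0)),
            mass=float(rng.uniform(50, 500)),
            subunit="P",
        )
    return m


@pytest.fixture(scope="session")
def toy_assembly():
    """The default 4-subunit ground-truth assembly (session-wide, read-only:
    tests must not mutate its model in place)."""
    return generate_assembly(seed=7)


def make_state_space(rng, n_components=None, n_states=None):
    """A random discrete instance: point components with pairwise distance
    terms and random thresholds.  Shared by unit and acceptance tests."""
    n_components = n_components or int(rng.integers(2, 5))
    n_states = n_states or int(rng.integers(2, 7))
    model = asm.Model()
    comps = [f"c{i}" for i in range(n_components)]
    for c in comps:
        model.create_particle(f"{c}.p", (0, 0, 0), radius=1.0, mass=1.0, subunit=c)
    states = {
        c: [{f"{c}.p": rng.uniform(-10, 10, 3)} for _ in range(n_states)] for c in comps
    }
    space = asm.DiscreteStateSpace(model, states)
    terms = []
    for t in range(int(rng.integers(1, 4))):
        i, j = rng.choice(n_components, 2, replace=False)
        terms.append(
            asm.HarmonicDistanceRestraint(
                f"{comps[i]}.p",
                f"{comps[j]}.p",
                d0=float(rng.uniform(0, 15)),
                k=1.0,
                name=f"t{t}",
                threshold=float(rng.uniform(0, 30)),
            )
        )
    return space, asm.ScoringFunction(terms)


@pytest.fixture
def simple_grid_spec():
    return GridSpec(origin=(-30.0, -30.0, -30.0), spacing=2.0, dims=(31, 31, 31))
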