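import numpy as np
import pytest

from pedmorph import Individual, Pedigree, make_paper_like_fixture


@pytest.fixture(scope="session")
def study_fixture():
    """Deterministic study-shaped pedigree: 40 parents, 58 offspring."""
    return make_paper_like_fixture(seed=0)


@pytest.fixture
def trio():
    """Minimal sire-dam-offspring pedigree."""
    return Pedigree(
        [
            Individual("sire1", sex="male", morph="O", prop_orange=0.3,
                       prop_yellow=0.0),
            Individual("dam1", sex="female", morph="G", prop_orange=0.0,
                       prop_yellow=0.0),
            Individual(
                "kid1", sex="male", generation="F1", sire_id="sire1",
                dam_id="dam1", morph="O", prop_orange=0.2, prop_yellow=0.0,
            ),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pedigree(rng, n_founders=8, n_offspring=12):
    """Small random two-generation pedigree without phenotypes."""
    ped = Pedigree()
    males = [f"m{i}" for i in range(n_founders)]
    females = [f"f{i}" for i in range(n_founders)]
    for m in males:
        ped.add(Individual(m, sex="male", morph="G"))
    for f in females:
        ped.add(Individual(f, sex="female", morph="G"))
    for k in range(n_offspring):
        ped.add(
            Individual(
                f"o{k}",
                sex="male" if rng.random() < 0.5 else "female",
                generation="F1",
                sire_id=males[int(rng.integers(n_founders))],
                dam_id=females[int(rng.integers(n_founders))],
                clutch_id=f"c{k % 4}",
                morph="G",
            )
        )
    return ped
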