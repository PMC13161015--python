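import numpy as np
import pandas as pd
import pytest

from flocknet import FlockMatrix, Phylogeny, SimulationConfig, simulate_study


@pytest.fixture
def toy_matrix() -> FlockMatrix:
    """Three flocks {ABC}, {ABD}, {BCD} over four species."""
    occ = np.array(
        [
            [1, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 1, 1, 1],
        ]
    )
    return FlockMatrix("toy", ["f1", "f2", "f3"], list("ABCD"), occ)


@pytest.fixture
def flock_dir(tmp_path):
    """Two small locality CSVs on disk."""
    d = tmp_path / "flocks"
    d.mkdir()
    m1 = pd.DataFrame(
        [[1, 1, 1, 0], [1, 1, 0, 1], [0, 1, 1, 1], [1, 0, 1, 1]],
        index=["f1", "f2", "f3", "f4"],
        columns=["A", "B", "C", "D"],
    )
    m2 = pd.DataFrame(
        [[1, 1, 1], [1, 1, 1], [1, 1, 1], [0, 1, 1], [1, 1, 1]],
        index=["g1", "g2", "g3", "g4", "g5"],
        columns=["A", "B", "E"],
    )
    m1.to_csv(d / "loc1.csv")
    m2.to_csv(d / "loc2.csv")
    return d


@pytest.fixture
def tree3() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused across test modules."""
    cfg = SimulationConfig(
        seed=1,
        n_species=60,
        n_localities=6,
        flocks_per_locality=20,
        pool_size=20,
        eye_coverage=1.0,
        n_trees=3,
    )
    return simulate_study(cfg)
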