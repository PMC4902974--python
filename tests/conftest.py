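import warnings

import numpy as np
import pytest

from homeokit import origin, simlocus

# the simulator warns about pseudogenizing insertions etc. on purpose
warnings.filterwarnings("ignore", category=UserWarning)


SMALL_STUDY_CONFIG = dict(
    seed=0,
    marker_length=2000,
    te_ages_years=(0.0, 1.0e6),
    n_segmental_per_haplotype=1,
    segmental_length_range=(1000, 3000),
    species_b_deleted_genes=("g05",),
    n_queries={"A": 2, "B": 1},
)


def small_study(seed: int = 0, **overrides) -> simlocus.StudyBundle:
    kwargs = dict(SMALL_STUDY_CONFIG, seed=seed, **overrides)
    cfg = simlocus.SimulationConfig(**kwargs)
    return simlocus.simulate_study(cfg, simlocus.small_template(6))


@pytest.fixture(scope="session")
def study():
    """One compact two-species study bundle shared across the suite."""
    return small_study(seed=0)


@pytest.fixture(scope="session")
def study_classified(study):
    """The shared study plus its origin classification (expensive)."""
    panel_a = origin.SpeciesPanel("A", study.panels["A"])
    panel_b = origin.SpeciesPanel("B", study.panels["B"])
    store = origin.AlignmentStore()
    calls, markers = origin.classify_all(panel_a, panel_b, study.queries, store)
    return {
        "study": study,
        "panel_a": panel_a,
        "panel_b": panel_b,
        "store": store,
        "calls": {c.haplotype: c for c in calls},
        "markers": markers,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
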