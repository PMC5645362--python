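import pytest

from mapdiff.quant import ConditionProfile
from mapdiff.simulate import SimDesign, generate_proteome, generate_psm_tables


def make_profile(condition: str, scores: dict[str, float], n_replicates: int = 2,
                 presence: dict[str, int] | None = None) -> ConditionProfile:
    """Condition profile straight from a score dict (SpC mirrors Score)."""
    return ConditionProfile(
        condition=condition,
        n_replicates=n_replicates,
        scores=dict(scores),
        spcs=dict(scores),
        presence_counts=presence or {a: n_replicates for a in scores},
    )


@pytest.fixture(scope="session")
def small_proteome():
    return generate_proteome(20, seed=11, fixed_length=60)


@pytest.fixture(scope="session")
def small_experiment(small_proteome):
    """20 proteins, 2 conditions x 2 replicates, one exclusive, one 4-fold."""
    accs = [r.id for r in small_proteome]
    design = SimDesign(
        n_proteins=20,
        conditions=("A", "B"),
        fold_change_map={accs[0]: {"A": 4.0}},
        exclusive_map={accs[1]: frozenset({"B"})},
        abundance_map={accs[0]: 40.0, accs[1]: 40.0},
        noise_fraction=0.1,
        seed=11,
    )
    tables, truth = generate_psm_tables(design, small_proteome)
    return design, tables, truth
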