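import numpy as np
import pytest

from tersurvey.pipeline import run_survey, score_recovery
from tersurvey.simulate import CladeSimConfig, simulate_clade


@pytest.fixture(scope="session")
def default_clade():
    """One simulated clade under the default study conditions."""
    cfg = CladeSimConfig(seed=0)
    genomes, truths = simulate_clade(cfg)
    return cfg, genomes, truths


def _survey_once(seed: int, multiplier: float):
    cfg = CladeSimConfig(
        seed=seed,
        background_sub_rate=1.0 * multiplier,
        island_sub_rate=0.02 * multiplier,
        indel_rate=min(0.05 * multiplier, 0.3),
    )
    genomes, truths = simulate_clade(cfg)
    seed_sp = truths[0].species_id
    known = [truths[0].to_annotation()]
    result = run_survey(genomes, cfg.tree, known)
    truth_anns = [t.to_annotation() for t in truths if t.species_id != seed_sp]
    pred = [a for a in result.annotations if a.species != seed_sp]
    metrics = score_recovery(pred, truth_anns)
    return metrics, result


DIVERGENCE_GRID = (1.0, 3.0, 8.0, 20.0)
GRID_SEEDS = range(10)


@pytest.fixture(scope="session")
def divergence_grid():
    """End-to-end survey recovery across an increasing-divergence grid.

    The first grid point is the default (low-divergence) condition. Returns
    {multiplier: {"recalls": [...], "metrics": [...], "graphs": [...]}}.
    """
    out = {}
    for mult in DIVERGENCE_GRID:
        recalls, metrics, graphs = [], [], []
        for seed in GRID_SEEDS:
            m, res = _survey_once(seed, mult)
            recalls.append(m.locus_recall)
            metrics.append(m)
            graphs.append(res.graph)
        out[mult] = {"recalls": recalls, "metrics": metrics, "graphs": graphs}
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture()
def make_seq(rng):
    def _make(n, r=None):
        return random_seq(r or rng, n)

    return _make
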