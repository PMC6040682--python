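import numpy as np
import pytest

from decidatac import diffacc, simulate as sim


@pytest.fixture(scope="session")
def pwms():
    return sim.default_pwms()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact genome with planted repeats, genes and peaks."""
    cfg = sim.SimulationConfig(
        seed=11, genome_length=300_000, n_genes=12, n_peaks=60,
        n_opening=8, n_closing=6,
    )
    return sim.make_genome(cfg)


@pytest.fixture(scope="session")
def default_run():
    """The full default simulation pushed through fragment counting and the
    differential test; shared by the recovery and association checks."""
    cfg = sim.SimulationConfig(seed=1)
    bundle = sim.make_genome(cfg)
    fragments = sim.make_fragments(cfg, bundle)
    counts = diffacc.count_fragments(fragments, bundle.peaks)
    _, conditions = sim.sample_labels(cfg)
    stats = diffacc.nb_differential(counts, conditions)
    ranked = diffacc.classify_dynamic(diffacc.rank_peaks(stats))
    return {
        "config": cfg,
        "bundle": bundle,
        "fragments": fragments,
        "counts": counts,
        "ranked": ranked,
    }
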