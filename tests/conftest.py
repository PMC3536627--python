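import numpy as np
import pytest

from cisevo import landscape as ls


def table_from_binders(binders, tf_id="toy", gamma=0.05):
    """Build a SpecificityTable directly from a {kmer: kappa} mapping."""
    dense = np.zeros(ls.N_KMERS)
    for kmer, kappa in binders.items():
        dense[ls.kmer_to_index(kmer)] = kappa
    return ls.SpecificityTable(
        tf_id=tf_id, gamma=gamma, lam=ls.lambda_from_gamma(gamma), dense=dense
    )


@pytest.fixture(scope="session")
def default_panel():
    """The default 10-TF synthetic panel at gamma = 0.05."""
    return ls.generate_panel(n_tfs=10, gamma=0.05, seed=42)


@pytest.fixture(scope="session")
def default_tables(default_panel):
    return ls.tables_of(default_panel)


@pytest.fixture(scope="session")
def small_landscape():
    """A single fast landscape used by unit tests."""
    params = ls.LandscapeParams(n_binders=300, seed=7)
    return ls.generate_landscape(params, gamma=0.05)


def _run_arm(gamma, n_reps, seed0, generations=600, M=50, L=50):
    """One batch of scaled evolution runs; returns (first, last) records."""
    from cisevo import evolution

    panel = ls.generate_panel(n_tfs=10, gamma=gamma, seed=42)
    tables = ls.tables_of(panel)
    out = []
    for r in range(n_reps):
        cfg = evolution.SimulationConfig(
            M=M, L=L, generations=generations, eval_interval=generations,
            gamma=gamma, seed=seed0 + r, eval_sample=40,
            robustness_mutants=100,
        )
        recs = evolution.run_simulation(cfg, tables)
        out.append((recs[0], recs[-1]))
    return out


@pytest.fixture(scope="session")
def scaled_runs_gamma005():
    """Shared scaled-run arm: gamma=0.05, L=50, M=50, 600 generations, x8.

    Desk-scale stand-in for the reference protocol (M=500, 2000 generations,
    100 replicates); used by the selection-response and connectivity trend
    tests so the simulations run once per session.
    """
    return _run_arm(gamma=0.05, n_reps=8, seed0=1200)


@pytest.fixture(scope="session")
def scaled_runs_gamma020():
    """Shared scaled-run arm: gamma=0.20, L=50, M=50, 600 generations, x6."""
    return _run_arm(gamma=0.20, n_reps=6, seed0=1400)
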