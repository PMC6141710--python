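import numpy as np
import pytest

import intercells as ic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_config(scenario="aCD3", n=24, seed=7, **run_kwargs):
    """A small scenario dict with explicit low counts for fast tests."""
    init = {
        "TCR": {"kind": "gaussian_clusters", "n_clusters": 2,
                "pts_per_cluster": 8, "cluster_sd": 30.0},
        "CD45": {"kind": "uniform", "n": 20},
        "CD11": {"kind": "uniform", "n": 10},
    }
    if scenario == "APC":
        init.update({"pMHC": {"kind": "uniform", "n": 12},
                     "ICAM": {"kind": "uniform", "n": 10}})
    run = {"seed": seed}
    run.update(run_kwargs)
    return {"scenario": scenario, "grid": {"n_rows": n, "n_cols": n},
            "run": run, "initial": init}


@pytest.fixture
def small_sim():
    return ic.build_scenario(small_config()).build()


def free_species(name="X", D=1250.0, **kw):
    """A non-interacting mobile species (no spring, no ligand, no pinning)."""
    kw.setdefault("l_mol", 10.0)
    kw.setdefault("k_mol", 0.0)
    return ic.SpeciesSpec(name, "t_cell", D=D, J_self=0.0, **kw)


def free_simulation(n=64, n_mol=50, D=1250.0, seed=0, sigma_z=0.0,
                    translocation=None, placements=None, n_steps=100):
    """Simulation of freely diffusing, non-interacting molecules."""
    spec = free_species(D=D)
    table = ic.CompiledSpecies.compile([spec])
    grid = ic.InterfaceGrid(n, n)
    rng = np.random.default_rng(seed)
    if placements is None:
        flat = rng.choice(n * n, size=n_mol, replace=False)
        rows, cols = flat // n, flat % n
    else:
        rows, cols = placements
    grid.add_molecules(0, rows, cols, 0)
    membrane = ic.MembraneSpec(kappa1=30.0, sigma_z=sigma_z)
    cfg = ic.SimConfig(n_steps=n_steps, seed=seed, save_every=n_steps,
                       translocation=translocation)
    return ic.Simulation(grid, table, membrane, cfg)
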