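import numpy as np
import pytest

from quenchbind import SimConfig, simulate_titration, write_titration_table

# Per-temperature association constants and fitted thermodynamics of the
# reference serum-albumin/piperine system, used across modules as inputs.
REFERENCE_TEMPS = (288.0, 298.0, 308.0)
REFERENCE_KA = (3.90e4, 2.77e4, 2.06e4)
REFERENCE_KSV = (3.77e4, 2.78e4, 2.54e4)


@pytest.fixture
def noiseless_sim():
    """Three noiseless titrations at 2/4/8 µM protein, true n=3, Kb=7e4."""
    config = SimConfig(noise_rel=0.0)
    series, truth = simulate_titration(config)
    return config, series, truth


@pytest.fixture
def single_site_series():
    """Single-site, q_max=1, negligible-depletion titration: the regime where
    F0/F = 1 + Kb*[L]free holds exactly."""
    config = SimConfig(
        k_b_true=3.77e4,
        n_sites_true=1.0,
        q_max=1.0,
        protein_concs=(1e-8,),
        ligand_grid=np.arange(0, 13, dtype=float) * 1e-6,
        noise_rel=0.0,
    )
    series, truth = simulate_titration(config)
    return config, series[0], truth


@pytest.fixture
def titration_csv(tmp_path):
    """A simulated titration written to CSV, for I/O and CLI tests."""
    config = SimConfig(
        k_b_true=3.9e4,
        n_sites_true=1.0,
        q_max=1.0,
        protein_concs=(4e-6,),
        ligand_grid=np.arange(0, 16, dtype=float) * 1e-6,
        noise_rel=0.0,
        temperature=288.0,
    )
    series, _ = simulate_titration(config)
    path = tmp_path / "titration.csv"
    write_titration_table(series[0], path)
    return path
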