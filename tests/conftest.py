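import numpy as np
import pytest

from quenchkit import SimulationScenario, simulate_fluorescence_titration

GUEST_GRID = tuple(np.linspace(0.0, 300e-6, 13))


def static_scenario(**overrides) -> SimulationScenario:
    """The canonical static-quenching regime: 10 uM host, guest to 300 uM,
    K = 3000 M^-1, non-emissive complex, titrant absorbing at the
    excitation wavelength (delta-A up to 0.30 at the last point)."""
    kw = dict(
        K_true=3000.0,
        host_total=10e-6,
        guest_grid=GUEST_GRID,
        eps_guest=1000.0,  # 1000 M^-1 cm^-1 x 300 uM = 0.30 AU
        noise_rel_F=0.01,
        noise_rel_A=0.002,
        seed=0,
    )
    kw.update(overrides)
    return SimulationScenario(**kw)


@pytest.fixture
def noiseless_static_series():
    return simulate_fluorescence_titration(
        static_scenario(noise_rel_F=0.0, noise_rel_A=0.0)
    )


@pytest.fixture
def titration_csv(tmp_path):
    """Write a small titration table to disk and return its path."""

    def _write(rows, header="host_total,guest_total,F,A_ex", name="titr.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return _write
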