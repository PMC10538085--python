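import numpy as np
import pytest

from pillartrap.types import CellSpec, PowerLawModel, SweepRecord, TrapGeometry


@pytest.fixture(scope="session")
def default_model():
    return PowerLawModel()  # coefficient 0.027, exponent 2


@pytest.fixture(scope="session")
def a549():
    return CellSpec(diameter=17.0, youngs_modulus=430.0)


@pytest.fixture(scope="session")
def geometry8():
    return TrapGeometry(gap=8.0)


def make_grid_records(coefficient=0.027, exponent=2.0,
                      moduli=(350.0, 430.0, 500.0, 650.0),
                      diameters=(10.0, 15.0, 20.0, 25.0, 30.0),
                      gaps=(4.0, 6.0, 8.0, 10.0),
                      noise_sigma=0.0, seed=0):
    """Noiseless (or lognormally perturbed) records generated exactly by the
    power law, used as regression ground truth."""
    rng = np.random.default_rng(seed)
    records = []
    for E in moduli:
        for a in diameters:
            for g in gaps:
                pc = coefficient * E * (a / g) ** exponent
                if noise_sigma > 0:
                    pc *= float(np.exp(rng.normal(0.0, noise_sigma)))
                records.append(
                    SweepRecord(
                        cell=CellSpec(diameter=a, youngs_modulus=E),
                        geometry=TrapGeometry(gap=g),
                        critical_pressure=pc,
                    )
                )
    return records


@pytest.fixture(scope="session")
def grid_records():
    return make_grid_records()
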