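import logging

import numpy as np
import pytest

from gradff import fixtures as fx
from gradff import structure_io as sio
from gradff.calibration import default_calibration

logging.getLogger("gradff").setLevel(logging.ERROR)
logging.getLogger().setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calib():
    """Calibration fitted once on the default synthetic reference set."""
    return default_calibration(seed=0)


@pytest.fixture(scope="session")
def helix10(calib):
    """Ideal 10-residue helix with polar hydrogens."""
    s = fx.build_peptide(fx.FixtureSpec(sequence="AKLEGVFSTW", preset="helix"))
    return sio.add_polar_hydrogens(s)


@pytest.fixture(scope="session")
def noisy_helix(calib):
    """The seeded perturbed helix (sigma = 0.3 A, seed 17)."""
    s = fx.build_peptide(fx.FixtureSpec(sequence="AKLEGVFSTW", preset="helix",
                                        noise_sigma=0.3, seed=17))
    return sio.add_polar_hydrogens(s)


def fd_gradient(f, x0, h=1e-4):
    """Central finite-difference gradient of a scalar function of (n,3)."""
    g = np.zeros_like(x0)
    for i in range(x0.shape[0]):
        for k in range(x0.shape[1]):
            xp = x0.copy()
            xp[i, k] += h
            xm = x0.copy()
            xm[i, k] -= h
            g[i, k] = (f(xp) - f(xm)) / (2 * h)
    return g
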