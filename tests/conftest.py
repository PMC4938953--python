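import numpy as np
import pytest

from fluxdrift.experiment_io import default_genotype
from fluxdrift.pathway_kinetics import EnzymeParams, Genotype, KineticEnvironment


@pytest.fixture
def env():
    return KineticEnvironment()


@pytest.fixture
def genotype():
    return default_genotype()


@pytest.fixture
def rng():
    return np.random.default_rng(20160708)


@pytest.fixture
def random_genotypes():
    """Deterministic factory of solver-friendly random genotypes: every
    parameter of the default genotype scaled by a log-uniform factor."""

    def make(n, seed=42, spread=4.0):
        rng = np.random.default_rng(seed)
        base = default_genotype()
        out = []
        for _ in range(n):
            enzymes = []
            for e in base.enzymes:
                f = np.exp(rng.uniform(-np.log(spread), np.log(spread), size=6))
                enzymes.append(EnzymeParams(
                    enzyme_conc=e.enzyme_conc * f[0],
                    k_cat=e.k_cat * f[1],
                    K_M=e.K_M * f[2],
                    k_catr=e.k_catr * f[3],
                    K_Mr=e.K_Mr * f[4],
                    K_I=None if e.K_I is None else e.K_I * f[5],
                ))
            out.append(Genotype(enzymes))
        return out

    return make
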