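import numpy as np
import pytest

from periprog.synthetic_data import SimulationConfig, make_multiome_pair, make_program_cohort
from periprog.workflows import discover_recurrent_programs, infer_regulators


@pytest.fixture(scope="session")
def default_cohort():
    """Three samples, three shared + one private program each, noise 0.1."""
    cfg = SimulationConfig(seed=7)
    return make_program_cohort(cfg)


@pytest.fixture(scope="session")
def onehot_cohort():
    """Same layout with one-hot usages (each cell expresses one program)."""
    cfg = SimulationConfig(usage_concentration=0.0, seed=7)
    return make_program_cohort(cfg)


@pytest.fixture(scope="session")
def rp_result(default_cohort):
    """Full recurrent-program discovery on the default cohort."""
    mats, truth = default_cohort
    n_rp = (len(truth.shared_program_ids)
            + sum(len(v) for v in truth.programs_by_sample.values())
            - len(mats) * len(truth.shared_program_ids))
    return discover_recurrent_programs(mats, n_rp=n_rp, seed=0)


@pytest.fixture(scope="session")
def multiome():
    """Paired multiome, 500 cells, planted TF coupled at strength 2."""
    cfg = SimulationConfig(seed=3, n_cells_per_sample=500, tf_coupling=2.0)
    return make_multiome_pair(cfg)


@pytest.fixture(scope="session")
def regulator_result(multiome):
    modules = {f"program{i + 1}": genes
               for i, genes in enumerate(multiome.truth.program_genes)}
    return infer_regulators(multiome, modules, seed=3)


def signature_truth_labels(signatures, truth):
    """Map each NMF signature to the planted program with maximal overlap."""
    blocks = [set(b) for b in truth.program_genes]
    return [int(np.argmax([len(set(s.genes) & b) for b in blocks]))
            for s in signatures]
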