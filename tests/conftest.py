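import numpy as np
import pytest

from dinolnc.genome_io import Annotation, GeneModel, Genome
from dinolnc.simulate import SimulationConfig, simulate_truth_bundle


@pytest.fixture(scope="session")
def bundle():
    """One shared synthetic study with planted truth (seed fixed)."""
    return simulate_truth_bundle(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cascade_result(bundle):
    from dinolnc.identify import run_cascade

    lncrnas, attrition = run_cascade(bundle.alignments, bundle.annotation, bundle.counts)
    return lncrnas, attrition


@pytest.fixture()
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 30000)])
    return Genome({"chr1": seq, "chr2": seq[:12000]})


@pytest.fixture()
def toy_annotation():
    genes = [
        GeneModel("gA", "chr1", "+",
                  exons=((1500, 1800), (2200, 2500), (3000, 3400)),
                  cds=((1550, 1800), (2200, 2500), (3000, 3300))),
        GeneModel("gB", "chr1", "-",
                  exons=((10000, 10600),),
                  cds=((10100, 10500),)),
        GeneModel("gC", "chr2", "+",
                  exons=((300, 700), (1200, 1600)),
                  cds=((350, 700), (1200, 1500))),
    ]
    return Annotation(genes)
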