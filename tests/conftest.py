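import numpy as np
import pytest

from ricelnc.classify import classify_lnc, annotate_neighbors
from ricelnc.identify import run_identification
from ricelnc.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """The default synthetic bundle (seed 42) shared across the suite."""
    return generate(GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def identified(bundle):
    lnc, report = run_identification(
        bundle.candidates, bundle.annotation, bundle.genome, bundle.fpkm
    )
    return lnc, report


@pytest.fixture(scope="session")
def mrnas(bundle):
    return [t for t in bundle.annotation if t.biotype == "known_mRNA"]


@pytest.fixture(scope="session")
def calls(identified, mrnas):
    lnc, _ = identified
    return annotate_neighbors(classify_lnc(lnc, mrnas), mrnas)


@pytest.fixture(scope="session")
def lincs(calls):
    return [c.transcript for c in calls if c.lnc_class == "lincRNA"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
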