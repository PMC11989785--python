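import numpy as np
import pandas as pd
import pytest

from lrcrosstalk.diffexpr import study_contrasts
from lrcrosstalk.io_formats import CountsMatrix, SampleSheet
from lrcrosstalk.simulate import IMADC_CONTRAST, SimulationConfig, generate_counts


@pytest.fixture
def study_sheet() -> SampleSheet:
    rows = []
    for cell in ("IMAdC", "SMSC"):
        for culture in ("mono", "co"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{cell}_{culture}_{rep}",
                        "cell_type": cell,
                        "culture": culture,
                        "replicate": rep,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def tiny_counts(study_sheet) -> CountsMatrix:
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(100, size=(20, 12)),
        index=pd.Index([f"G{i:02d}" for i in range(1, 21)], name="gene_id"),
        columns=study_sheet.sample_ids,
    )
    return CountsMatrix(counts, study_sheet)


@pytest.fixture(scope="session")
def imadc_spec():
    return next(c for c in study_contrasts() if c.name == IMADC_CONTRAST)


@pytest.fixture(scope="session")
def planted_study():
    """A small study with 40 genes planted at |log2fc| = 2 in the IMAdC contrast."""
    planted = tuple(
        (f"G{i:03d}", IMADC_CONTRAST, 2.0 if i <= 20 else -2.0) for i in range(1, 41)
    )
    config = SimulationConfig(
        n_genes=300,
        dispersion=0.05,
        baseline_log2_mean=7.0,
        baseline_log2_sd=0.5,
        planted_de=planted,
        seed=42,
    )
    counts, truth = generate_counts(config)
    return config, counts, truth
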