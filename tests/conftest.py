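import numpy as np
import pandas as pd
import pytest

from lysopipe import quantify, synthetic
from lysopipe.taxonomy import Taxonomy


@pytest.fixture(scope="session")
def taxonomy():
    return Taxonomy.default()


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition lipidomics draw shared across tests."""
    spec = synthetic.default_lipidome_spec()
    tbl, truth, effects = synthetic.simulate_lipidomics(spec, seed=11)
    return spec, tbl, truth, effects


@pytest.fixture(scope="session")
def filtered_table(default_sim):
    _, tbl, _, _ = default_sim
    molar = quantify.to_molar(tbl)
    _, filt = quantify.filter_species(molar)
    return filt


def make_molar_table(
    molar: pd.DataFrame, samples: pd.DataFrame, taxonomy: Taxonomy
) -> quantify.MolarTable:
    """Assemble a MolarTable directly from a molar matrix."""
    tbl = quantify.MolarTable(
        molar=molar,
        molpct=pd.DataFrame(np.nan, index=molar.index, columns=molar.columns),
        samples=samples,
        taxonomy=taxonomy,
    )
    return quantify.to_molpct(tbl)


def toy_samples(replicates: int = 3) -> pd.DataFrame:
    rows = []
    for fraction in quantify.FRACTIONS:
        for treatment in quantify.TREATMENTS:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{fraction}_{treatment}_r{rep}",
                        "fraction": fraction,
                        "treatment": treatment,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
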