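"""Shared synthetic fixtures.

Everything is generated at test time from fixed seeds; session scope keeps
the more expensive cohorts shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest

from ehrgenpop import synthdata as sd
from ehrgenpop.matrix import GenotypeMatrix


def toy_matrix(dosages, chrom=None, bp=None, allele1=None, allele2=None, sample_ids=None):
    """Hand-built GenotypeMatrix for small oracle tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "bp": bp if bp is not None else np.arange(1, m + 1) * 1000,
            "id": [f"v{j}" for j in range(m)],
            "allele1": allele1 if allele1 is not None else ["A"] * m,
            "allele2": allele2 if allele2 is not None else ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {"id": sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]}
    )
    return GenotypeMatrix(d, variants, samples)


@pytest.fixture(scope="session")
def two_pop_model():
    return sd.PopulationModel.simulate(K=2, M=2000, fst=0.15, seed=11)


@pytest.fixture(scope="session")
def two_pop_cohort(two_pop_model):
    """Two nearly unadmixed groups of 100, plus truth and demographics."""
    spec = sd.CohortSpec(
        groups=[
            sd.GroupSpec("g0", 100, [30.0, 0.3], "NH-White"),
            sd.GroupSpec("g1", 100, [0.3, 30.0], "NH-Asian"),
        ],
        label_noise_rate=0.0,
    )
    return sd.simulate_admixed_cohort(two_pop_model, spec, seed=12)


@pytest.fixture(scope="session")
def five_pop_reference():
    """Well-separated 5-population panel (fst 0.1, 200/pop) + admixed study
    cohort of 1000, mirroring the continental-GIA design."""
    model = sd.PopulationModel.simulate(K=5, M=3000, fst=0.1, seed=21)
    panel = sd.simulate_reference_panel(
        model, 200, seed=22, pop_names=["EUR", "AFR", "EAS", "AMR", "SAS"]
    )
    groups = []
    sires = ["NH-White", "NH-AfAm", "NH-Asian", "HL-Other", "SA"]
    for k, sire in enumerate(sires):
        alpha = np.full(5, 0.3)
        alpha[k] = 40.0
        groups.append(sd.GroupSpec(f"S{k}", 200, alpha, sire))
    spec = sd.CohortSpec(groups=groups, label_noise_rate=0.05)
    study, truth, demo = sd.simulate_admixed_cohort(model, spec, seed=23)
    return model, panel, study, truth, demo
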