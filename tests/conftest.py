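from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lwas.qc import FeatureTable

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_panel():
    from lwas.nomenclature import load_reference_panel
    return load_reference_panel()


def make_table(areas: np.ndarray, types: list[str], *, names=None,
               polarity=None, dilution=None, orders=None) -> FeatureTable:
    """Hand-build a small FeatureTable for unit tests."""
    areas = np.atleast_2d(np.asarray(areas, float))
    n_feat, n_inj = areas.shape
    fids = [f"F{i}" for i in range(n_feat)]
    inj = [f"i{j}" for j in range(n_inj)]
    if names is None:
        names = [f"PC(3{i}:1)" for i in range(n_feat)]
    if polarity is None:
        polarity = ["positive"] * n_feat
    manifest = pd.DataFrame({
        "order": orders if orders is not None else np.arange(1, n_inj + 1),
        "type": types,
        "dilution_percent": dilution if dilution is not None
        else [np.nan] * n_inj,
        "sample_id": [f"s{j}" if t == "study" else None
                      for j, t in enumerate(types)],
    }, index=pd.Index(inj, name="injection"))
    features = pd.DataFrame({"lipid_name": names, "polarity": polarity},
                            index=pd.Index(fids, name="feature_id"))
    return FeatureTable(
        features=features,
        areas=pd.DataFrame(areas, index=features.index, columns=inj),
        manifest=manifest,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant cohort (10 per group) for fast model tests."""
    from lwas.synthetic import CohortConfig, GroupConfig, generate_cohort
    cfg = CohortConfig(groups={
        (age, sex): GroupConfig(10, (25.0 if age == "young" else 74.0, 2.5),
                                (24.0, 6.0), (5.2, 0.3), (260.0, 60.0),
                                (6.0, 2.0), 0.1)
        for age in ("young", "aged") for sex in ("female", "male")
    })
    return generate_cohort(cfg, seed=11)
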