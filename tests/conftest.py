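import numpy as np
import pandas as pd
import pytest

from spatialtme.phenotyping import gate_cohort
from spatialtme.simulate import SimulationParams, generate_cohort


def make_cells(rows):
    """Build a cell table from compact per-row dicts (defaults filled in)."""
    defaults = dict(
        patient_id="P1", field_id="F1", x_um=0.0, y_um=0.0,
        compartment="stroma", cd3=False, cd8=False, foxp3=False,
        ki67=False, ck=False, grb_intensity=0.0,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


def make_fields(rows):
    defaults = dict(
        patient_id="P1", field_id="F1",
        area_epithelium_mm2=0.3, area_stroma_mm2=0.6, area_other_mm2=0.1,
    )
    out = []
    for r in rows:
        row = {**defaults, **r}
        total = (row["area_epithelium_mm2"] + row["area_stroma_mm2"]
                 + row["area_other_mm2"])
        row.setdefault("epithelium_fraction", row["area_epithelium_mm2"] / total)
        out.append(row)
    return pd.DataFrame(out)


def random_gated_cohort(rng, n_patients=3, n_fields=2, n_cells=120, field_um=300.0):
    """A random (non-generative-model) gated cell table for oracle tests."""
    rows = []
    for p in range(n_patients):
        for f in range(n_fields):
            for _ in range(rng.integers(n_cells // 2, n_cells + 1)):
                rows.append(dict(
                    patient_id=f"P{p + 1}", field_id=f"F{f + 1}",
                    x_um=rng.uniform(0, field_um), y_um=rng.uniform(0, field_um),
                    compartment=rng.choice(["epithelium", "stroma", "other"]),
                    cd3=bool(rng.integers(2)), cd8=bool(rng.integers(2)),
                    foxp3=bool(rng.integers(2)), ki67=bool(rng.integers(2)),
                    ck=bool(rng.integers(2)),
                    grb_intensity=float(rng.uniform(0, 1)),
                ))
    return gate_cohort(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_patients=8, fields_per_patient=2)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return generate_cohort(small_params, seed=11)


@pytest.fixture(scope="session")
def small_gated(small_cohort):
    return gate_cohort(small_cohort.cells)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
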