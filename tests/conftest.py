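import numpy as np
import pandas as pd
import pytest

from fibredist.io import CANONICAL_COLUMNS, MetaDataset, clean_dataframe
from fibredist.synthdata import GeneratorConfig, generate


@pytest.fixture(scope="session")
def small_world():
    """A small noisy nonlinear meta-dataset with ground truth (5 studies)."""
    return generate(GeneratorConfig(n_studies=5, rows_per_study=(12, 18), seed=42))


@pytest.fixture(scope="session")
def small_ds(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def linear_world():
    """Deterministic linear world: zero noise, zero study effects."""
    config = GeneratorConfig(
        n_studies=4,
        rows_per_study=(12, 16),
        response="linear",
        noise_sd=0.0,
        study_effect_sd=0.0,
        seed=7,
    )
    return generate(config)


def make_dataset(df_rows: list[dict]) -> MetaDataset:
    """Build a cleaned MetaDataset from partial row dicts (test helper)."""
    defaults = {
        "study_id": "s1",
        "polymer": "PVA",
        "concentration": 10.0,
        "needle_gauge": 20.0,
        "rotation_speed": 1000.0,
        "voltage": 20.0,
        "flow_rate": 1.0,
        "distance": 12.0,
        "diameter": 200.0,
    }
    rows = [{**defaults, **r} for r in df_rows]
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return clean_dataframe(df)


@pytest.fixture
def toy_csv(tmp_path):
    """Write a 5-row literature-style CSV; one row has a blank voltage."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "DOI,Polymer,Solvent1,Solvent1_ratio (%),Concentration (%),Needle diameter,"
        "Type of collector,Rotation speed (rpm),Voltage (kV),Flow rate (mL/h),"
        "Tip-to-collector distance (cm),Temperature (C),Humidity (%),Fibre diameter (nm)\n"
        "10.1/a,PVA,water,100,12%,20 G,rotating drum,2000,25,1,11,25,45,250\n"
        "10.1/a,PVA,water,100,10,20,rotating drum,2000,,1,11,25,45,220\n"
        "10.1/b,PCL,chloroform,100,8,22,static plate,0,15,0.5,15,,,480\n"
        "10.1/b,PCL,chloroform,100,\"1,5\",22,static plate,0,18,0.5,15,,,510\n"
        "10.1/c,PVA,water,100,14,18,rotating drum,1500,22,2,10,25,50,300\n"
    )
    return path
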