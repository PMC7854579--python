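import numpy as np
import pandas as pd
import pytest

import phytotraits as pt


@pytest.fixture(scope="session")
def valid_table():
    """A mid-sized schema-valid synthetic trait table."""
    return pt.generate_table(n_taxa=200, seed=0)


@pytest.fixture(scope="session")
def small_table():
    return pt.generate_table(n_taxa=30, seed=11)


def random_cells_table(rng: np.random.Generator, n_rows: int = 3) -> pt.TraitTable:
    """Schema-valid table with arbitrary per-kind cell values and missingness.

    Unlike the synthetic generator this draws each cell independently, so
    round-trip tests cover the whole value space of every trait kind.
    """
    schema = pt.default_schema()
    data = {}
    for tdef in schema.identity + schema.traits:
        col = []
        for i in range(n_rows):
            required = tdef.required or tdef.name == "Taxa_Name"
            if not required and rng.random() < 0.25:
                col.append(None)
            elif tdef.kind == "continuous":
                col.append(float(np.round(rng.uniform(0.01, 1e6), 4)))
            elif tdef.kind == "boolean":
                col.append(int(rng.integers(2)))
            elif tdef.kind == "categorical":
                col.append(tdef.allowed_values[rng.integers(len(tdef.allowed_values))])
            else:
                col.append(f"text {rng.integers(1_000_000)}")
        data[tdef.name] = col
    # codes must be unique for the loader
    data["Taxa_Code"] = [
        "".join(chr(65 + rng.integers(26)) for _ in range(6)) for _ in range(n_rows)
    ]
    df = pd.DataFrame(data, columns=list(schema.columns))
    for tdef in schema.identity + schema.traits:
        if tdef.kind == "continuous":
            df[tdef.name] = pd.to_numeric(df[tdef.name]).astype(float)
        elif tdef.kind == "boolean":
            df[tdef.name] = pd.array(
                [pd.NA if v is None else v for v in df[tdef.name]], dtype="Int64"
            )
        else:
            df[tdef.name] = pd.array(
                [pd.NA if v is None else v for v in df[tdef.name]], dtype=object
            )
    return pt.TraitTable(df, schema)
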