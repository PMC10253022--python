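import numpy as np
import pandas as pd
import pytest

from riceflavor.core import CompoundTable, GCOPanel
from riceflavor.fixtures import load_paper_fixtures
from riceflavor.quantify import presence_matrix

CLASSES = ("alcohol", "phenol", "aldehyde", "acid", "ester", "hydrocarbon",
           "ketone", "heterocycle")


@pytest.fixture(scope="session")
def fx():
    """Packaged study fixtures (class summaries, shared table, consensus,
    flavor map)."""
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def table2(fx):
    return fx["table2_table"]


@pytest.fixture(scope="session")
def pm_table2(table2):
    return presence_matrix(table2)


def make_random_table(rng: np.random.Generator, n_samples=4, n_compounds=12,
                      dialect="area") -> CompoundTable:
    """A random valid compound table: lognormal areas, random class labels,
    ~70% presence per (sample, compound)."""
    rows = []
    compounds = [f"cmpd-{i:02d}" for i in range(n_compounds)]
    classes = {c: CLASSES[rng.integers(len(CLASSES))] for c in compounds}
    for s in range(n_samples):
        present = [c for c in compounds if rng.random() < 0.7]
        if not present:
            present = [compounds[0]]
        for c in present:
            rows.append({
                "sample": f"S{s + 1}",
                "compound": c,
                "chem_class": classes[c],
                "value": float(rng.lognormal(1.0, 0.8)),
                "retention_time": float(rng.uniform(5, 35)),
            })
    table = CompoundTable(pd.DataFrame(rows), dialect="area")
    if dialect == "percent":
        from riceflavor.quantify import relative_content

        return relative_content(table)
    return table


def make_random_panel(rng: np.random.Generator, samples=("S1",), n_events=8,
                      compounds=("a", "b", "c")) -> pd.DataFrame:
    """Random *assigned* GC-O events (compound column already filled)."""
    rows = []
    for _ in range(n_events):
        rows.append({
            "sample": samples[rng.integers(len(samples))],
            "evaluator": f"E{rng.integers(4) + 1}",
            "time_min": float(rng.uniform(5, 35)),
            "descriptor": "note",
            "intensity": int(rng.integers(1, 6)),
            "compound": compounds[rng.integers(len(compounds))],
        })
    return pd.DataFrame(
        rows, columns=["sample", "evaluator", "time_min", "descriptor",
                       "intensity", "compound"])
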