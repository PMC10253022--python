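"""Relative-content normalization and per-class summaries.

GC-MS reports each compound as a peak area; within a sample the areas are
converted to *relative contents*: content_i = 100 * area_i / sum_j area_j,
so per-sample contents total 100%.  Class summaries count compounds and sum
contents within each of the eight chemical classes; the presence matrix is
the boolean detected/absent view that the set-based flavor typing consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CHEM_CLASSES, CompoundTable, ValidationError, _sep_for

#: Stable reporting order for the eight chemical classes.
CLASS_ORDER = (
    "alcohol",
    "phenol",
    "aldehyde",
    "acid",
    "hydrocarbon",
    "ketone",
    "ester",
    "heterocycle",
)


def relative_content(table: CompoundTable) -> CompoundTable:
    """Convert an area-dialect table to relative contents (percent).

    Each compound's content is its share of the sample's total peak area,
    in percent; per-sample contents sum to 100 to floating precision.

    Raises
    ------
    ValidationError
        If the table is not in area dialect or a sample's total area is 0
        (the table validator already rejects nonpositive individual areas).
    """
    if table.dialect != "area":
        raise ValidationError("relative_content expects an area-dialect table")
    frame = table.frame.copy()
    totals = frame.groupby("sample")["value"].transform("sum")
    zero = frame.loc[totals <= 0, "sample"].unique()
    if len(zero):
        raise ValidationError(f"sample(s) with total peak area 0: {sorted(zero)}")
    frame["value"] = 100.0 * frame["value"] / totals
    out = CompoundTable(frame, dialect="percent")
    out.samples = list(table.samples)
    return out


def class_summary(table: CompoundTable) -> pd.DataFrame:
    """Count compounds and sum contents per (sample, chemical class).

    Returns a long DataFrame with columns ``sample``, ``chem_class``,
    ``n_compounds``, ``total_content``, covering the full sample x class
    grid; classes with no detected compound report (0, 0.0).  Contents are
    kept at full precision; round for display only.
    """
    if table.dialect != "percent":
        raise ValidationError("class_summary expects a percent-dialect table")
    rows = []
    grouped = table.frame.groupby(["sample", "chem_class"])["value"].agg(["size", "sum"])
    for sample in table.samples:
        for cls in CLASS_ORDER:
            if (sample, cls) in grouped.index:
                n, total = grouped.loc[(sample, cls)]
            else:
                n, total = 0, 0.0
            rows.append(
                {
                    "sample": sample,
                    "chem_class": cls,
                    "n_compounds": int(n),
                    "total_content": float(total),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "chem_class", "n_compounds", "total_content"])


@dataclass
class PresenceMatrix:
    """Boolean detected/absent matrix: rows = compounds, columns = samples.

    A cell is True iff a record exists with relative content strictly
    greater than ``min_content`` (percent).  Row order is the canonical
    name sort, so reports are reproducible.
    """

    matrix: pd.DataFrame
    min_content: float = 0.0

    @property
    def compounds(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def detected_in(self, sample: str) -> set[str]:
        if sample not in self.matrix.columns:
            raise ValidationError(f"unknown sample id: {sample!r}")
        col = self.matrix[sample]
        return set(col.index[col])


def presence_matrix(table: CompoundTable, min_content: float = 0.0) -> PresenceMatrix:
    """Build the detection matrix over the union of compounds x samples.

    The default threshold of 0 (strictly greater than) counts every
    recorded compound as detected, down to trace contents; absence of a
    record is the only way to be undetected.
    """
    if min_content < 0:
        raise ValidationError(f"min_content must be >= 0, got {min_content}")
    if table.dialect != "percent":
        raise ValidationError("presence_matrix expects a percent-dialect table")
    compounds = table.compounds
    samples = list(table.samples)
    mat = pd.DataFrame(False, index=compounds, columns=samples)
    hits = table.frame[table.frame["value"] > min_content]
    for row in hits.itertuples(index=False):
        mat.at[row.compound, row.sample] = True
    return PresenceMatrix(matrix=mat, min_content=float(min_content))


def write_class_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Write a class summary as TSV, contents rounded half-up to 2 decimals
    for display (the in-memory values stay full precision)."""
    from .core import round_half_up

    out = summary.copy()
    out["total_content"] = [round_half_up(v, 2) for v in out["total_content"]]
    out.to_csv(Path(path), sep=_sep_for(Path(path)), index=False)


def write_presence_matrix(pm: PresenceMatrix, path: str | Path) -> None:
    """Write the presence matrix as a wide 0/1 TSV."""
    pm.matrix.astype(int).to_csv(Path(path), sep=_sep_for(Path(path)), index_label="compound")
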