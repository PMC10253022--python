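"""Domain types and tabular IO for fragrant-rice flavor analysis.

The analysis works on three tables plus one mapping:

* a **compound table** — per-sample volatile compounds from GC-MS, each with
  a chemical class and either a raw peak area or a relative content
  (percentage of the sample's total peak area);
* a **GC-O event log** — timestamped records of what a sensory evaluator
  smelled at the sniffing port, with an ordinal intensity score 1-5;
* a **functional-component table** — per-sample resistant starch (%) and
  fat acidity (mg/100 g);
* a **flavor-type map** — each sample's panel-assigned flavor type
  (popcorn, corn, lotus root ...).

All files are plain CSV/TSV (UTF-8, "." decimal, header row); the reader
picks the separator from the extension. A "—" or empty cell in a compound
table means *not detected* and becomes the absence of a record, never a
zero-content record, so presence/absence logic downstream is unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: The eight chemical classes used to group rice volatiles.
CHEM_CLASSES: frozenset[str] = frozenset(
    {
        "alcohol",
        "phenol",
        "aldehyde",
        "acid",
        "ester",
        "hydrocarbon",
        "ketone",
        "heterocycle",
    }
)

#: Ordinal odor-intensity scale: 1 very weak ... 5 very strong.
INTENSITY_SCALE = (1, 2, 3, 4, 5)

#: Cell markers meaning "not detected" in printed/ingested tables.
MISSING_MARKERS = {"", "-", "—", "–", "nd", "n.d.", "na"}


class RiceFlavorError(Exception):
    """Base class for all package errors."""


class ValidationError(RiceFlavorError):
    """Raised when input data violates a documented invariant."""


# ---------------------------------------------------------------------------
# name canonicalization
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def canonicalize_name(raw: str) -> str:
    """Return the canonical form of a compound name.

    Leading/trailing whitespace is stripped, internal runs of whitespace
    collapse to a single space, and the name is lower-cased.  Lower-casing
    leaves locants, ring indices and stereochemistry prefixes such as
    ``cis-`` or ``4(14)`` intact, so the two printed spellings
    ``"cis-Muurola-4(14), 5-diene"`` and ``"cis-muurola-4(14), 5-diene"``
    map to the same canonical name.  The function is idempotent.

    Raises
    ------
    ValidationError
        If the name is empty after trimming.
    """
    if not isinstance(raw, str):
        raise ValidationError(f"compound name must be text, got {type(raw).__name__}")
    name = _WS.sub(" ", raw).strip().lower()
    if not name:
        raise ValidationError("compound name is empty after trimming")
    return name


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (so 4.75 -> 4.8 at one decimal)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# compound tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One detected volatile in one sample.

    ``value`` is a raw peak area (arbitrary units) or a relative content in
    percent, depending on the owning table's dialect.  A record only exists
    where the compound was detected: absence is encoded by not having a row.
    """

    sample_id: str
    compound: str
    chem_class: str
    value: float
    retention_time: float | None = None


class CompoundTable:
    """A validated per-sample volatile-compound table.

    Parameters
    ----------
    frame
        Long-format data with columns ``sample``, ``compound``,
        ``chem_class``, ``value`` and optionally ``retention_time``.
        Compound names are canonicalized on ingest.
    dialect
        ``"area"`` for raw peak areas, ``"percent"`` for relative contents.
    check_sums, sum_tol
        When ``check_sums`` is true and the dialect is percent, per-sample
        contents must total 100 within ``sum_tol`` (absolute).  Printed
        tables usually list only a subset of each sample's compounds, so the
        check is off by default; normalized tables produced by
        :func:`riceflavor.quantify.relative_content` satisfy it to 1e-9.
    """

    _COLUMNS = ("sample", "compound", "chem_class", "value")

    def __init__(
        self,
        frame: pd.DataFrame,
        dialect: str,
        *,
        check_sums: bool = False,
        sum_tol: float = 1.0,
    ) -> None:
        if dialect not in ("area", "percent"):
            raise ValidationError(f"dialect must be 'area' or 'percent', got {dialect!r}")
        frame = frame.copy()
        missing = [c for c in self._COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"compound table missing columns: {missing}")
        if "retention_time" not in frame.columns:
            frame["retention_time"] = np.nan

        frame["sample"] = frame["sample"].astype(str)
        frame["compound"] = [canonicalize_name(c) for c in frame["compound"]]
        frame["chem_class"] = frame["chem_class"].astype(str).str.strip().str.lower()
        frame["value"] = pd.to_numeric(frame["value"], errors="raise").astype(float)
        frame["retention_time"] = pd.to_numeric(frame["retention_time"], errors="coerce")

        bad_class = sorted(set(frame["chem_class"]) - CHEM_CLASSES)
        if bad_class:
            raise ValidationError(
                f"unknown chemical class(es) {bad_class}; allowed classes are "
                f"{sorted(CHEM_CLASSES)}"
            )
        neg = frame[frame["value"] < 0]
        if len(neg):
            r = neg.iloc[0]
            raise ValidationError(
                f"negative value {r['value']} for ({r['sample']}, {r['compound']})"
            )
        zero = frame[frame["value"] == 0]
        if len(zero):
            r = zero.iloc[0]
            raise ValidationError(
                f"zero value for ({r['sample']}, {r['compound']}): undetected "
                "compounds must be omitted, not listed with 0"
            )
        if dialect == "percent" and (frame["value"] > 100).any():
            r = frame[frame["value"] > 100].iloc[0]
            raise ValidationError(
                f"relative content {r['value']}% > 100 for ({r['sample']}, {r['compound']})"
            )
        if (frame["retention_time"].dropna() < 0).any():
            raise ValidationError("retention times must be >= 0")

        dup = frame.duplicated(subset=["sample", "compound"], keep=False)
        if dup.any():
            r = frame[dup].iloc[0]
            raise ValidationError(
                f"duplicate (sample, compound) pair: ({r['sample']}, {r['compound']})"
            )

        if check_sums and dialect == "percent":
            sums = frame.groupby("sample")["value"].sum()
            off = sums[(sums - 100.0).abs() > sum_tol]
            if len(off):
                raise ValidationError(
                    "per-sample relative contents must sum to 100 "
                    f"(±{sum_tol}); offending samples: "
                    + ", ".join(f"{s}={v:.2f}" for s, v in off.items())
                )

        self.frame = frame.reset_index(drop=True)
        self.dialect = dialect
        # first-appearance order of samples is preserved for reporting
        self.samples: list[str] = list(dict.fromkeys(frame["sample"]))

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompoundTable):
            return NotImplemented
        a = self.frame.sort_values(["sample", "compound"]).reset_index(drop=True)
        b = other.frame.sort_values(["sample", "compound"]).reset_index(drop=True)
        return self.dialect == other.dialect and a.equals(b)

    @property
    def compounds(self) -> list[str]:
        """Canonically sorted union of compound names."""
        return sorted(set(self.frame["compound"]))

    def records(self) -> Iterator[CompoundRecord]:
        for row in self.frame.itertuples(index=False):
            rt = None if pd.isna(row.retention_time) else float(row.retention_time)
            yield CompoundRecord(
                row.sample, row.compound, row.chem_class, float(row.value), rt
            )

    def subset(self, samples: Sequence[str]) -> "CompoundTable":
        """Restrict to the given samples (kept in the given order)."""
        unknown = [s for s in samples if s not in self.samples]
        if unknown:
            raise ValidationError(f"unknown sample id(s): {unknown}")
        sub = self.frame[self.frame["sample"].isin(samples)]
        out = CompoundTable(sub, self.dialect)
        out.samples = list(samples)
        return out


_COMPOUND_ALIASES = {
    "sample": "sample",
    "sample_id": "sample",
    "compound": "compound",
    "name": "compound",
    "class": "chem_class",
    "chem_class": "chem_class",
    "value": "value",
    "content": "value",
    "area": "value",
    "peak_area": "value",
    "relative_content": "value",
    "retention_time": "retention_time",
    "rt": "retention_time",
    "rt_min": "retention_time",
}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    return pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)


def _is_missing(cell: str) -> bool:
    return str(cell).strip().lower() in MISSING_MARKERS


def _to_float(series: pd.Series, what: str) -> pd.Series:
    """Parse a text column to float64 via Python's correctly-rounded float()
    (pandas' to_numeric can be off by one ulp, breaking exact round trips).
    Empty cells become NaN."""
    out = []
    for x in series:
        if isinstance(x, str) and x.strip() == "":
            out.append(np.nan)
            continue
        try:
            out.append(float(x))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric {what}: {x!r}") from exc
    return pd.Series(out, index=series.index, dtype=float)


def read_compound_table(path: str | Path, dialect: str) -> CompoundTable:
    """Read a long-format compound table from CSV/TSV.

    Header names are matched case-insensitively against the documented
    aliases (``sample``/``sample_id``, ``compound``/``name``,
    ``class``/``chem_class``, ``value``/``content``/``area``, optional
    ``retention_time``/``rt``).  Cells marked "—" or left empty are treated
    as *not detected* and produce no record.
    """
    raw = _read_frame(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    renames = {c: _COMPOUND_ALIASES[c] for c in raw.columns if c in _COMPOUND_ALIASES}
    raw = raw.rename(columns=renames)
    needed = {"sample", "compound", "chem_class", "value"}
    if not needed.issubset(raw.columns):
        raise ValidationError(
            f"{path}: expected columns {sorted(needed)} (or aliases), got {list(raw.columns)}"
        )
    keep = ~raw["value"].map(_is_missing).astype(bool)
    raw = raw.loc[keep]
    for col in ("value", "retention_time"):
        if col in raw.columns:
            raw[col] = _to_float(raw[col], col)
    return CompoundTable(raw, dialect)


def write_compound_table(table: CompoundTable, path: str | Path) -> None:
    """Write a compound table as CSV/TSV (round-trips with the reader)."""
    path = Path(path)
    out = table.frame.copy()
    out.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# GC-O panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GCOEvent:
    """One smelling event: an evaluator perceived an odor at a time point."""

    sample_id: str
    evaluator_id: str
    smell_time: float
    descriptor: str
    intensity: int


class GCOPanel:
    """A validated GC-O event log for a sensory panel.

    ``events`` is a DataFrame with columns ``sample``, ``evaluator``,
    ``time_min``, ``descriptor``, ``intensity``.  Intensities follow the
    ordinal 1-5 scale (1 very weak ... 5 very strong); ``n_evaluators`` is
    the panel size (4 in the study design) and must be at least the number
    of distinct evaluator ids seen.
    """

    _COLUMNS = ("sample", "evaluator", "time_min", "descriptor", "intensity")

    def __init__(self, events: pd.DataFrame, n_evaluators: int | None = None) -> None:
        events = events.copy()
        missing = [c for c in self._COLUMNS if c not in events.columns]
        if missing:
            raise ValidationError(f"GC-O event table missing columns: {missing}")
        events["sample"] = events["sample"].astype(str)
        events["evaluator"] = events["evaluator"].astype(str)
        events["descriptor"] = events["descriptor"].astype(str)
        events["time_min"] = _to_float(events["time_min"], "smelling time")
        try:
            intensity = pd.to_numeric(events["intensity"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-numeric intensity: {exc}") from exc
        if ((intensity % 1) != 0).any():
            raise ValidationError("intensity scores must be integers on the 1-5 scale")
        events["intensity"] = intensity.astype(int)
        bad = events[~events["intensity"].isin(INTENSITY_SCALE)]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"intensity {r['intensity']} outside the ordinal scale 1 (very weak) "
                f"... 5 (very strong) for ({r['sample']}, {r['evaluator']})"
            )
        if (events["time_min"] < 0).any():
            raise ValidationError("smelling times must be >= 0 minutes")

        seen = events["evaluator"].nunique()
        if n_evaluators is None:
            n_evaluators = max(seen, 1)
        if seen > n_evaluators:
            raise ValidationError(
                f"{seen} distinct evaluators exceed panel size n_evaluators={n_evaluators}"
            )
        self.events = events.reset_index(drop=True)
        self.n_evaluators = int(n_evaluators)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GCOPanel):
            return NotImplemented
        a = self.events.sort_values(list(self._COLUMNS)).reset_index(drop=True)
        b = other.events.sort_values(list(self._COLUMNS)).reset_index(drop=True)
        return self.n_evaluators == other.n_evaluators and a.equals(b)

    @property
    def evaluators(self) -> list[str]:
        return sorted(set(self.events["evaluator"]))

    def iter_events(self) -> Iterator[GCOEvent]:
        for r in self.events.itertuples(index=False):
            yield GCOEvent(r.sample, r.evaluator, float(r.time_min), r.descriptor, int(r.intensity))


def read_gco_events(path: str | Path, n_evaluators: int | None = None) -> GCOPanel:
    """Read a GC-O event log (columns sample, evaluator, time_min, descriptor,
    intensity).  Panel size defaults to the distinct evaluator count."""
    raw = _read_frame(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    aliases = {"sample_id": "sample", "evaluator_id": "evaluator", "time": "time_min",
               "smell_time": "time_min", "description": "descriptor", "score": "intensity"}
    raw = raw.rename(columns={c: aliases[c] for c in raw.columns if c in aliases})
    return GCOPanel(raw, n_evaluators=n_evaluators)


def write_gco_events(panel: GCOPanel, path: str | Path) -> None:
    path = Path(path)
    panel.events.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# flavor-type map
# ---------------------------------------------------------------------------


@dataclass
class FlavorTypeMap:
    """Mapping from sample id to its panel-assigned flavor type."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("flavor-type map is empty")
        self.assignments = {str(k): str(v) for k, v in self.assignments.items()}
        for s, t in self.assignments.items():
            if not t.strip():
                raise ValidationError(f"sample {s} has an empty flavor-type label")

    @property
    def types(self) -> list[str]:
        """Flavor types in first-appearance order."""
        return list(dict.fromkeys(self.assignments.values()))

    def samples_of(self, flavor_type: str) -> list[str]:
        return [s for s, t in self.assignments.items() if t == flavor_type]

    def type_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise ValidationError(f"sample {sample!r} has no flavor-type assignment") from None

    def counts(self) -> dict[str, int]:
        return {t: len(self.samples_of(t)) for t in self.types}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FlavorTypeMap):
            return NotImplemented
        return self.assignments == other.assignments


def read_flavor_map(path: str | Path) -> FlavorTypeMap:
    """Read a YAML flavor-type map ({sample: type})."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: expected a YAML mapping of sample -> flavor type")
    return FlavorTypeMap(dict(data))


def write_flavor_map(fmap: FlavorTypeMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(fmap.assignments, fh, sort_keys=True, allow_unicode=True)


# ---------------------------------------------------------------------------
# functional components
# ---------------------------------------------------------------------------

#: Functional-component column names: resistant starch in percent of dry
#: matter; fat acidity in mg KOH-equivalent per 100 g.
FUNCTIONAL_COMPONENTS = ("resistant_starch", "fat_acidity")


def validate_functional_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample functional-component table.

    Columns: ``sample``, ``resistant_starch`` (%), ``fat_acidity``
    (mg/100 g).  Values must be nonnegative and resistant starch below 100.
    """
    frame = frame.copy()
    missing = [c for c in ("sample", *FUNCTIONAL_COMPONENTS) if c not in frame.columns]
    if missing:
        raise ValidationError(f"functional table missing columns: {missing}")
    frame["sample"] = frame["sample"].astype(str)
    for col in FUNCTIONAL_COMPONENTS:
        frame[col] = pd.to_numeric(frame[col], errors="raise").astype(float)
        if (frame[col] < 0).any():
            raise ValidationError(f"{col} must be nonnegative")
    if (frame["resistant_starch"] >= 100).any():
        raise ValidationError("resistant starch is a percentage and must be < 100")
    if frame["sample"].duplicated().any():
        raise ValidationError("duplicate sample ids in functional table")
    return frame.reset_index(drop=True)


def read_functional_table(path: str | Path) -> pd.DataFrame:
    raw = _read_frame(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    raw = raw.rename(columns={"sample_id": "sample"})
    for col in FUNCTIONAL_COMPONENTS:
        if col in raw.columns:
            raw[col] = _to_float(raw[col], col)
    return validate_functional_table(raw)


def write_functional_table(frame: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# peak lists
# ---------------------------------------------------------------------------


def validate_peak_list(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample GC-MS peak list (sample, compound, retention_time).

    Compound names are canonicalized; retention times must be >= 0 minutes.
    """
    frame = frame.copy()
    missing = [c for c in ("sample", "compound", "retention_time") if c not in frame.columns]
    if missing:
        raise ValidationError(f"peak list missing columns: {missing}")
    frame["sample"] = frame["sample"].astype(str)
    frame["compound"] = [canonicalize_name(c) for c in frame["compound"]]
    frame["retention_time"] = pd.to_numeric(frame["retention_time"], errors="raise").astype(float)
    if (frame["retention_time"] < 0).any():
        raise ValidationError("retention times must be >= 0")
    if frame.duplicated(subset=["sample", "compound"]).any():
        raise ValidationError("duplicate (sample, compound) in peak list")
    return frame.reset_index(drop=True)


def read_peak_list(path: str | Path) -> pd.DataFrame:
    raw = _read_frame(path)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    raw = raw.rename(columns={"sample_id": "sample", "rt": "retention_time",
                              "rt_min": "retention_time", "name": "compound"})
    raw["retention_time"] = _to_float(raw["retention_time"], "retention_time")
    return validate_peak_list(raw)


def write_peak_list(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep=_sep_for(Path(path)), index=False)


def peaks_from_table(table: CompoundTable) -> pd.DataFrame:
    """Extract a peak list from a compound table that carries retention times."""
    f = table.frame.dropna(subset=["retention_time"])
    return validate_peak_list(f[["sample", "compound", "retention_time"]])
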