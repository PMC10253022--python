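"""GC-O computations: event assignment, FQ/AI spectrograms, and
characteristic-flavor-compound calls.

Evaluators at the sniffing port record *when* they smelled something, a
free-text descriptor and an ordinal intensity 1-5.  Each smelling event is
matched to the nearest same-sample GC-MS peak within a retention-time
tolerance, which names the compound behind the odor.  Per compound and
sample the panel's perception is summarized as

* **FQ** (identification frequency): the number of distinct evaluators,
  out of the panel of ``n_evaluators``, who perceived the compound
  (0 <= FQ <= n_evaluators);
* **AI** (average intensity): the mean intensity score over the evaluators
  who perceived it, reported half-up-rounded to one decimal
  (0 <= AI <= 5.0; FQ = 0 implies AI = 0).

A compound is a *characteristic flavor compound* of a flavor type when
FQ >= 3 or AI >= 3.0 in at least two samples of the type (one, for a
single-sample type).  The cross-type consensus lists compounds perceived
in two or more flavor types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    FlavorTypeMap,
    GCOPanel,
    ValidationError,
    round_half_up,
)

#: Default retention-time matching tolerance, minutes.  GC-O smelling times
#: lag/lead the MS peak apex by a few seconds; 0.2 min is a conservative
#: window for a ~40 min run.
DEFAULT_RT_TOLERANCE = 0.2


def assign_events(
    panel: GCOPanel, peaks: pd.DataFrame, tolerance: float = DEFAULT_RT_TOLERANCE
) -> pd.DataFrame:
    """Match each smelling event to the nearest same-sample peak.

    Returns the event table with an added ``compound`` column (NaN when no
    peak lies within ``tolerance`` minutes).  Ties are broken by smallest
    absolute time difference, then lexically smallest compound name, so the
    assignment is deterministic.  A sample with events but no peaks leaves
    all its events unassigned.
    """
    if tolerance <= 0:
        raise ValidationError(f"tolerance must be > 0 minutes, got {tolerance}")
    events = panel.events.copy()
    assigned: list[str | float] = []
    by_sample = {s: g for s, g in peaks.groupby("sample")}
    for row in events.itertuples(index=False):
        cand = by_sample.get(row.sample)
        if cand is None or cand.empty:
            assigned.append(np.nan)
            continue
        delta = (cand["retention_time"] - row.time_min).abs()
        within = cand.loc[delta <= tolerance].assign(delta=delta[delta <= tolerance])
        if within.empty:
            assigned.append(np.nan)
            continue
        best = within.sort_values(["delta", "compound"], kind="mergesort").iloc[0]
        assigned.append(best["compound"])
    events["compound"] = assigned
    return events


@dataclass
class Spectrogram:
    """Per-sample flavor spectrogram: one FQ/AI entry per compound.

    ``entries`` has columns ``compound``, ``retention_time``, ``FQ``,
    ``AI``, ``descriptors`` and is ordered by retention time.  Compounds
    from the sample's peak list that drew no smelling event appear with
    FQ = 0, AI = 0.
    """

    sample_id: str
    n_evaluators: int
    entries: pd.DataFrame

    def entry(self, compound: str) -> pd.Series:
        hit = self.entries[self.entries["compound"] == compound]
        if hit.empty:
            raise ValidationError(f"{compound!r} not in spectrogram of {self.sample_id}")
        return hit.iloc[0]


def spectrogram(
    assigned: pd.DataFrame,
    sample_id: str,
    n_evaluators: int,
    peaks: pd.DataFrame | None = None,
    intensity_agg: str = "max",
    roster: Sequence[str] | None = None,
) -> Spectrogram:
    """Aggregate assigned events of one sample into FQ/AI entries.

    An evaluator who logged several events for the same compound counts
    once in FQ and contributes a single score: their maximum by default
    (``intensity_agg="mean"`` averages instead).  AI is the mean score over
    the perceiving evaluators only, half-up-rounded to one decimal; this is
    the only reading under which a four-evaluator panel can report an AI of
    4.8.
    """
    if n_evaluators < 1:
        raise ValidationError("n_evaluators must be >= 1")
    if intensity_agg not in ("max", "mean"):
        raise ValidationError(f"intensity_agg must be 'max' or 'mean', got {intensity_agg!r}")
    ev = assigned[assigned["sample"] == sample_id]
    if roster is not None:
        stray = sorted(set(ev["evaluator"]) - set(map(str, roster)))
        if stray:
            raise ValidationError(f"evaluator id(s) outside panel roster: {stray}")
    if ev["evaluator"].nunique() > n_evaluators:
        raise ValidationError(
            f"sample {sample_id}: more distinct evaluators than n_evaluators={n_evaluators}"
        )
    hits = ev.dropna(subset=["compound"])

    rt_of: dict[str, float] = {}
    if peaks is not None:
        mine = peaks[peaks["sample"] == sample_id]
        rt_of = dict(zip(mine["compound"], mine["retention_time"]))

    rows = []
    for compound, grp in hits.groupby("compound"):
        per_eval = grp.groupby("evaluator")["intensity"]
        scores = per_eval.max() if intensity_agg == "max" else per_eval.mean()
        fq = int(len(scores))
        ai = round_half_up(float(scores.mean()), 1)
        descriptors = "; ".join(sorted(grp["descriptor"].astype(str)))
        rt = rt_of.get(compound, float(grp["time_min"].mean()))
        rows.append(
            {"compound": compound, "retention_time": rt, "FQ": fq, "AI": ai,
             "descriptors": descriptors}
        )
    covered = {r["compound"] for r in rows}
    for compound, rt in rt_of.items():
        if compound not in covered:
            rows.append(
                {"compound": compound, "retention_time": rt, "FQ": 0, "AI": 0.0,
                 "descriptors": ""}
            )
    entries = pd.DataFrame(
        rows, columns=["compound", "retention_time", "FQ", "AI", "descriptors"]
    ).sort_values(["retention_time", "compound"], kind="mergesort").reset_index(drop=True)
    return Spectrogram(sample_id=sample_id, n_evaluators=int(n_evaluators), entries=entries)


def build_spectrograms(
    panel: GCOPanel,
    peaks: pd.DataFrame,
    samples: Sequence[str] | None = None,
    tolerance: float = DEFAULT_RT_TOLERANCE,
    intensity_agg: str = "max",
) -> dict[str, Spectrogram]:
    """Assign events and build one spectrogram per sample."""
    assigned = assign_events(panel, peaks, tolerance=tolerance)
    if samples is None:
        samples = sorted(set(assigned["sample"]) | set(peaks["sample"]))
    return {
        s: spectrogram(assigned, s, panel.n_evaluators, peaks=peaks,
                       intensity_agg=intensity_agg, roster=panel.evaluators)
        for s in samples
    }


@dataclass
class CharacteristicCall:
    """Characteristic-flavor-compound calls with supporting evidence.

    ``calls`` maps flavor type -> {compound -> list of evidence dicts
    (sample, FQ, AI, criterion)}; ``thresholds`` echoes the rule used.
    """

    calls: dict[str, dict[str, list[dict]]]
    thresholds: dict[str, float]

    def compounds_of(self, flavor_type: str) -> frozenset[str]:
        return frozenset(self.calls.get(flavor_type, {}))


def characteristic_compounds(
    spectrograms: Mapping[str, Spectrogram],
    types: FlavorTypeMap,
    fq_min: int = 3,
    ai_min: float = 3.0,
    min_samples: int = 2,
) -> CharacteristicCall:
    """Call each flavor type's characteristic compounds.

    A compound is called for a type when FQ >= ``fq_min`` or
    AI >= ``ai_min`` in at least ``min(min_samples, n_samples_of_type)``
    samples of the type — the effective-minimum rule lets a single-sample
    type (lotus root in the study design) be callable at all.
    """
    calls: dict[str, dict[str, list[dict]]] = {}
    for flavor_type in types.types:
        samples = types.samples_of(flavor_type)
        if not samples:
            raise ValidationError(f"flavor type {flavor_type!r} has no samples")
        missing = [s for s in samples if s not in spectrograms]
        if missing:
            raise ValidationError(
                f"no spectrogram for sample(s) {missing} of type {flavor_type!r}"
            )
        need = min(min_samples, len(samples))
        support: dict[str, list[dict]] = {}
        for s in samples:
            for row in spectrograms[s].entries.itertuples(index=False):
                crit = []
                if row.FQ >= fq_min:
                    crit.append("FQ")
                if row.AI >= ai_min:
                    crit.append("AI")
                if crit:
                    support.setdefault(row.compound, []).append(
                        {"sample": s, "FQ": int(row.FQ), "AI": float(row.AI),
                         "criterion": "+".join(crit)}
                    )
        calls[flavor_type] = {
            c: ev for c, ev in sorted(support.items()) if len(ev) >= need
        }
    return CharacteristicCall(
        calls=calls,
        thresholds={"fq_min": float(fq_min), "ai_min": float(ai_min),
                    "min_samples": float(min_samples)},
    )


def consensus_table(
    spectrograms: Mapping[str, Spectrogram], types: FlavorTypeMap
) -> pd.DataFrame:
    """Compounds perceived (FQ >= 1 in some sample) in >= 2 flavor types.

    Returns columns ``compound``, ``retention_time`` (mean over detecting
    samples), ``description`` (pooled distinct descriptors), ``types``
    (comma-joined) and ``n_types``, ordered by retention time.
    """
    seen: dict[str, dict] = {}
    for sample, spec in spectrograms.items():
        flavor_type = types.type_of(sample)
        det = spec.entries[spec.entries["FQ"] >= 1]
        for row in det.itertuples(index=False):
            info = seen.setdefault(
                row.compound, {"types": set(), "rts": [], "descriptors": set()}
            )
            info["types"].add(flavor_type)
            info["rts"].append(float(row.retention_time))
            info["descriptors"].update(
                d.strip() for d in str(row.descriptors).split(";") if d.strip()
            )
    rows = [
        {
            "compound": compound,
            "retention_time": float(np.mean(info["rts"])),
            "description": "; ".join(sorted(info["descriptors"])),
            "types": ", ".join(sorted(info["types"])),
            "n_types": len(info["types"]),
        }
        for compound, info in seen.items()
        if len(info["types"]) >= 2
    ]
    out = pd.DataFrame(
        rows, columns=["compound", "retention_time", "description", "types", "n_types"]
    )
    return out.sort_values(["retention_time", "compound"], kind="mergesort").reset_index(drop=True)


def write_spectrograms(spectrograms: Mapping[str, Spectrogram], path: str | Path) -> None:
    """Write all spectrograms as one long TSV (sample, compound, rt, FQ, AI,
    descriptors)."""
    frames = []
    for sample in sorted(spectrograms):
        f = spectrograms[sample].entries.copy()
        f.insert(0, "sample", sample)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(Path(path), sep="\t", index=False)
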