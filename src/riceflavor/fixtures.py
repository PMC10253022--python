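"""Packaged study fixtures.

Four small text files ship with the package, transcribing the study's
printed results tables cell for cell:

* ``table1_class_summary.tsv`` — per-sample, per-class compound counts and
  total relative contents for the eight rice samples SY1-SY8;
* ``table2_shared_compounds.tsv`` — the 28 volatiles detected in both the
  Thai reference sample (SY1) and the Chinese popcorn-flavor samples
  (SY6-SY8), with relative contents and "—" where a compound was not
  detected;
* ``table3_consensus.tsv`` — the 19 odor-active compounds perceived by the
  sensory panel in two or more flavor types, with retention times and
  pooled descriptors;
* ``flavor_map.yaml`` — the panel's flavor-type assignment of the eight
  samples (popcorn: SY1, SY6-SY8; corn: SY2-SY4; lotus root: SY5).

The class labels are carried exactly as printed, including the placement of
2-decenal among the hydrocarbons; fidelity to the source table wins over
chemical systematics here.  Files are checksummed on load so silent
corruption of the packaged data is caught immediately.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import (
    CompoundTable,
    FlavorTypeMap,
    GCOPanel,
    RiceFlavorError,
    ValidationError,
    canonicalize_name,
    read_flavor_map,
    validate_peak_list,
)

_CHECKSUMS = {
    "table1_class_summary.tsv": "1ceae3f0c39096a61d486ac53a3b377d7b83e287488e9e15c738262f88714b5c",
    "table2_shared_compounds.tsv": "93b2fc55d82b9f00fe77676090a91eb4fe26728265ff9a182fb80233d303faf7",
    "table3_consensus.tsv": "d40a861bab932a673265e67331a634959a7cb7a118a4a747cd6fe5371719dfa4",
    "flavor_map.yaml": "7409295a9c87e1df0a163858c3a317705ec43744816f1d966342fc8c9d078345",
}

#: Samples of the reference comparison: Thai reference first, then the
#: Chinese popcorn-flavor samples.
TABLE2_SAMPLES = ("SY1", "SY6", "SY7", "SY8")


def fixture_path(name: str) -> Path:
    """Resolve a packaged fixture file, verifying its checksum."""
    if name not in _CHECKSUMS:
        raise RiceFlavorError(f"unknown fixture {name!r}; available: {sorted(_CHECKSUMS)}")
    path = Path(str(resources.files("riceflavor.data") / name))
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RiceFlavorError(
            f"packaged fixture {name} is corrupted (sha256 {digest} != expected)"
        )
    return path


def load_table1_summary() -> pd.DataFrame:
    """Per-sample, per-class counts and total contents (long format)."""
    df = pd.read_csv(fixture_path("table1_class_summary.tsv"), sep="\t")
    df["sample"] = df["sample"].astype(str)
    df["n_compounds"] = df["n_compounds"].astype(int)
    df["total_content"] = df["total_content"].astype(float)
    return df


def load_table2_table() -> CompoundTable:
    """The 28 shared compounds as a percent-dialect :class:`CompoundTable`.

    The printed table is wide (one column per sample); "—" cells become
    absent records.  Printed contents are partial per-sample listings, so
    sum-to-100 validation does not apply.
    """
    wide = pd.read_csv(
        fixture_path("table2_shared_compounds.tsv"), sep="\t", dtype=str, keep_default_na=False
    )
    long = wide.melt(
        id_vars=["compound", "chem_class"],
        value_vars=list(TABLE2_SAMPLES),
        var_name="sample",
        value_name="value",
    )
    long = long[long["value"].str.strip() != "—"]
    long["value"] = long["value"].astype(float)
    table = CompoundTable(long, dialect="percent")
    table.samples = list(TABLE2_SAMPLES)
    return table


def load_table3_consensus() -> pd.DataFrame:
    """The 19-compound GC-O consensus list (retention time, name, descriptors)."""
    df = pd.read_csv(fixture_path("table3_consensus.tsv"), sep="\t")
    df["compound"] = [canonicalize_name(c) for c in df["compound"]]
    df["retention_time"] = df["retention_time"].astype(float)
    return df


def load_flavor_map() -> FlavorTypeMap:
    """The study's sample → flavor-type assignment (8 samples, 3 types)."""
    return read_flavor_map(fixture_path("flavor_map.yaml"))


def load_paper_fixtures() -> dict:
    """Load all packaged fixtures at once.

    Returns a dict with keys ``table1_summary`` (DataFrame),
    ``table2_table`` (CompoundTable), ``table3_consensus`` (DataFrame) and
    ``flavor_map`` (FlavorTypeMap).
    """
    return {
        "table1_summary": load_table1_summary(),
        "table2_table": load_table2_table(),
        "table3_consensus": load_table3_consensus(),
        "flavor_map": load_flavor_map(),
    }


def consensus_demo_panel() -> tuple[GCOPanel, pd.DataFrame]:
    """Re-express the consensus fixture as a minimal GC-O panel + peak list.

    The printed consensus list is itself the *output* of the cross-type
    consensus computation: every listed compound was perceived in at least
    two flavor types.  To exercise the computation on packaged data, each
    compound is expanded into one smelling event in one popcorn sample and
    one in one corn sample (evaluator E1, intensity 3, at the printed
    retention time), with matching GC-MS peaks.  Running
    :func:`riceflavor.olfactometry.consensus_table` over the result must
    reproduce the 19 printed rows.
    """
    consensus = load_table3_consensus()
    events = []
    peaks = []
    for row in consensus.itertuples(index=False):
        for sample in ("SY1", "SY2"):  # one popcorn, one corn sample
            events.append(
                {
                    "sample": sample,
                    "evaluator": "E1",
                    "time_min": row.retention_time,
                    "descriptor": row.description,
                    "intensity": 3,
                }
            )
            peaks.append(
                {"sample": sample, "compound": row.compound, "retention_time": row.retention_time}
            )
    panel = GCOPanel(pd.DataFrame(events), n_evaluators=4)
    return panel, validate_peak_list(pd.DataFrame(peaks))
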