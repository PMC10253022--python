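"""End-to-end report assembly.

``run_pipeline`` sequences the stages — quantify → commonality →
olfactometry → association — over one of three input modes:

* ``synthetic``: generate a dataset from a :class:`SyntheticConfig`;
* ``fixtures``: the packaged study tables (class summaries, the 28-compound
  shared list, the 19-compound GC-O consensus);
* ``files``: user-supplied CSV/TSV paths.

Every artifact is written as deterministic text (TSV/JSON/YAML) under the
output directory, with a provenance block echoing the configuration and
seed, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    NetConfig,
    association_r,
    class_functional_correlation,
    fit_bpnn,
)
from .commonality import (
    common_compounds,
    key_compounds,
    shared_with_reference,
    venn_partition,
    write_venn_regions,
)
from .core import (
    CompoundTable,
    FlavorTypeMap,
    GCOPanel,
    ValidationError,
    read_compound_table,
    read_flavor_map,
    read_functional_table,
    read_gco_events,
    read_peak_list,
    write_flavor_map,
)
from .fixtures import (
    TABLE2_SAMPLES,
    consensus_demo_panel,
    load_paper_fixtures,
)
from .olfactometry import (
    build_spectrograms,
    characteristic_compounds,
    consensus_table,
    write_spectrograms,
)
from .quantify import (
    class_summary,
    presence_matrix,
    relative_content,
    write_class_summary,
    write_presence_matrix,
)
from .synthetic import SyntheticConfig, generate


@dataclass
class RunConfig:
    """Run configuration: one input mode plus thresholds and net settings."""

    mode: str = "synthetic"  # synthetic | fixtures | files
    compound_table: str | None = None
    compound_dialect: str = "area"
    gco_events: str | None = None
    peak_list: str | None = None
    functional_table: str | None = None
    flavor_map: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    min_content: float = 0.0
    rt_tolerance: float = 0.2
    fq_min: int = 3
    ai_min: float = 3.0
    min_samples: int = 2
    association_mode: str = "training"
    net: NetConfig | None = None
    outdir: str = "riceflavor-out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "fixtures", "files"):
            raise ValidationError(f"mode must be synthetic/fixtures/files, got {self.mode!r}")
        if self.mode == "files" and not (self.compound_table and self.flavor_map):
            raise ValidationError("files mode needs at least a compound table and flavor map")


@dataclass
class ReportBundle:
    """Everything the pipeline computed, plus provenance."""

    class_summary: pd.DataFrame
    shared_reference: dict[str, Any] | None
    commons: dict[str, frozenset[str]] | None
    venn_sizes: dict[str, int] | None
    key_compounds: dict[str, frozenset[str]] | None
    spectrograms: dict | None
    characteristic: dict | None
    consensus: pd.DataFrame | None
    association: dict | None
    provenance: dict


def _provenance(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return {"package": "riceflavor", "version": __version__, "config": enc(config)}


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write all artifacts under the output
    directory.  Deterministic for a fixed config."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel: GCOPanel | None = None
    peaks: pd.DataFrame | None = None
    functional: pd.DataFrame | None = None
    signal_features: list[str] | None = None

    if config.mode == "synthetic":
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        dataset = generate(syn)
        table = relative_content(dataset.areas)
        fmap = dataset.flavor_map
        panel, peaks = dataset.panel, dataset.peaks
        functional = dataset.functional
        signal_features = list(dataset.truth.signal_compounds)
    elif config.mode == "fixtures":
        fx = load_paper_fixtures()
        table = fx["table2_table"]
        fmap = fx["flavor_map"]
        panel, peaks = consensus_demo_panel()
    else:
        table = read_compound_table(config.compound_table, config.compound_dialect)
        if table.dialect == "area":
            table = relative_content(table)
        fmap = read_flavor_map(config.flavor_map)
        if config.gco_events and config.peak_list:
            panel = read_gco_events(config.gco_events)
            peaks = read_peak_list(config.peak_list)
        if config.functional_table:
            functional = read_functional_table(config.functional_table)

    # --- quantify ----------------------------------------------------------
    summary = class_summary(table)
    write_class_summary(summary, outdir / "class_summary.tsv")
    pm = presence_matrix(table, min_content=config.min_content)
    write_presence_matrix(pm, outdir / "presence_matrix.tsv")

    # --- commonality -------------------------------------------------------
    shared_info = None
    if set(TABLE2_SAMPLES).issubset(pm.samples):
        ref, *others = TABLE2_SAMPLES
        shared = shared_with_reference(pm, ref, others, rule="any")
        strict = shared_with_reference(pm, ref, others, rule="all")
        shared_info = {
            "reference": ref,
            "others": list(others),
            "n_any": len(shared),
            "n_all": len(strict),
            "members_any": sorted(shared.members),
        }

    commons = venn_sizes = keys = None
    typed = [t for t in fmap.types if all(s in pm.samples for s in fmap.samples_of(t))]
    if len(typed) >= 2:
        commons_sets = {
            t: common_compounds(pm, fmap.samples_of(t), rule="all", label=t) for t in typed
        }
        venn = venn_partition(commons_sets)
        write_venn_regions(venn, outdir / "venn_regions.tsv", outdir / "venn_sizes.json")
        keys_sets = key_compounds(venn)
        commons = {t: s.members for t, s in commons_sets.items()}
        venn_sizes = venn.sizes()
        keys = {t: s.members for t, s in keys_sets.items()}

    # --- olfactometry ------------------------------------------------------
    spectrograms = characteristic = None
    consensus = None
    if panel is not None and peaks is not None and len(panel):
        sample_scope = [s for s in fmap.assignments if s in set(peaks["sample"])]
        spectrograms = build_spectrograms(
            panel, peaks, samples=sample_scope, tolerance=config.rt_tolerance
        )
        write_spectrograms(spectrograms, outdir / "spectrograms.tsv")
        call = characteristic_compounds(
            {s: spectrograms[s] for s in sample_scope},
            FlavorTypeMap({s: fmap.assignments[s] for s in sample_scope}),
            fq_min=config.fq_min, ai_min=config.ai_min, min_samples=config.min_samples,
        )
        characteristic = call.calls
        with open(outdir / "characteristic_compounds.json", "w", encoding="utf-8") as fh:
            json.dump({"thresholds": call.thresholds, "calls": call.calls}, fh, indent=2,
                      sort_keys=True)
            fh.write("\n")
        consensus = consensus_table(
            spectrograms, FlavorTypeMap({s: fmap.assignments[s] for s in sample_scope})
        )
        consensus.to_csv(outdir / "consensus_table.tsv", sep="\t", index=False)

    # --- association -------------------------------------------------------
    association = None
    if functional is not None:
        pair = class_functional_correlation(summary, functional)
        pair.pairwise.to_csv(outdir / "class_correlations.tsv", sep="\t", index=False)
        features = signal_features
        if features is None and characteristic:
            features = sorted(set().union(*(set(v) for v in characteristic.values())))
        association = {"pairwise": pair.pairwise.to_dict(orient="records")}
        if features:
            X, y, used = _feature_matrix(table, functional, features)
            net_cfg = config.net or NetConfig(
                n_inputs=len(used), n_outputs=1, seed=config.seed
            )
            net = fit_bpnn(X, y, net_cfg)
            modes = ["training"]
            if config.association_mode == "both" and len(X) >= 3:
                modes.append("leave_one_out")
            elif config.association_mode == "leave_one_out":
                modes = ["leave_one_out"]
            for m in modes:
                res = association_r(net, X, y, mode=m, component_names=["fat_acidity"])
                association[m] = res.per_component
            association["features"] = used
        with open(outdir / "association.json", "w", encoding="utf-8") as fh:
            json.dump(association, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")

    provenance = _provenance(config)
    with open(outdir / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_flavor_map(fmap, outdir / "flavor_map.yaml")

    return ReportBundle(
        class_summary=summary,
        shared_reference=shared_info,
        commons=commons,
        venn_sizes=venn_sizes,
        key_compounds=keys,
        spectrograms=spectrograms,
        characteristic=characteristic,
        consensus=consensus,
        association=association,
        provenance=provenance,
    )


def _feature_matrix(
    table: CompoundTable, functional: pd.DataFrame, features: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sample x compound relative-content matrix restricted to the feature
    subset, aligned with the functional table (absent -> 0)."""
    wide = table.frame.pivot(index="sample", columns="compound", values="value").fillna(0.0)
    used = [f for f in features if f in wide.columns]
    if not used:
        raise ValidationError("none of the requested feature compounds are in the table")
    func = functional.set_index("sample")
    samples = [s for s in wide.index if s in func.index]
    X = wide.loc[samples, used].to_numpy(dtype=float)
    y = func.loc[samples, "fat_acidity"].to_numpy(dtype=float)
    return X, y, used
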