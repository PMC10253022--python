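"""Synthetic GC-MS / GC-O / functional-component datasets with ground truth.

The generator emulates the structure of the study data so every pipeline
stage is testable end to end:

* three flavor types with 4 + 3 + 1 samples (configurable);
* a roster of volatile compounds split into *shared* compounds (present in
  every sample), *type-specific* compounds (present only in their type's
  samples — the planted key compounds), and *background* compounds placed
  in a single sample each;
* lognormal peak areas, so relative contents follow the heavy-tailed
  pattern GC-MS produces, with chemical classes drawn in roughly the
  proportions seen in rice volatiles (hydrocarbons most numerous);
* a four-evaluator GC-O panel: planted *strong* (characteristic) compounds
  are perceived by every evaluator with latent intensity 4.5; every other
  present compound is *weak* — one randomly chosen evaluator perceives it
  with probability logistic(ln content) and latent intensity 2.0; ordinal
  scores are the latent value plus normal noise, rounded and clamped to
  1-5;
* functional components: resistant starch is a type-level mean (0.3-0.8%
  band) plus noise; fat acidity is a linear function of the *latent log
  peak areas* of three designated signal compounds plus calibrated noise,
  which keeps the population signal variance in closed form:
  Var(signal) = area_log_sd^2 * sum(beta^2), so
  R^2 = Var(signal) / (Var(signal) + noise_sd^2) is exactly invertible.

Detection dropout removes records from the *measured* compound table but
does not perturb fat acidity: the functional chemistry of the grain is not
an instrument artifact.  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CompoundTable,
    FlavorTypeMap,
    GCOPanel,
    ValidationError,
    validate_functional_table,
    validate_peak_list,
    write_compound_table,
    write_flavor_map,
    write_functional_table,
    write_gco_events,
    write_peak_list,
)

#: Class-draw weights proportional to the published 188-compound census
#: (hydrocarbons most numerous) — cosmetic realism for synthetic rosters.
CLASS_WEIGHTS = {
    "hydrocarbon": 66,
    "alcohol": 26,
    "ester": 25,
    "ketone": 23,
    "aldehyde": 22,
    "heterocycle": 17,
    "acid": 6,
    "phenol": 3,
}


@dataclass
class SyntheticConfig:
    """Study-shaped generator settings.

    Defaults mirror the study design: 3 flavor types with 4/3/1 samples, a
    4-evaluator panel, ~45 compounds per sample across the 8 classes,
    resistant-starch type means inside 0.3-0.8% and fat acidity centred in
    the 15.5-22.8 mg/100 g band with noise calibrated so the population
    correlation between fat acidity and its volatile signal is
    ``target_R`` (0.86).
    """

    type_names: tuple[str, ...] = ("popcorn", "corn", "lotus_root")
    samples_per_type: tuple[int, ...] = (4, 3, 1)
    n_shared_compounds: int = 30
    n_type_specific: int = 4
    n_background: int = 80
    area_log_mean: float = 1.0
    area_log_sd: float = 0.6
    dropout_p: float = 0.0
    n_evaluators: int = 4
    detection_slope: float = 1.5
    detection_mid: float = 0.0
    intensity_sd: float = 0.5
    strong_latent: float = 4.5
    weak_latent: float = 2.0
    n_strong_specific: int = 2
    include_global_strong: bool = True
    fat_acidity_beta: tuple[float, ...] = (3.0, 2.2, 1.5)
    fat_acidity_intercept: float = 19.0
    noise_sd: float | None = None  # None -> calibrated to target_R
    target_R: float = 0.86
    rs_type_means: tuple[float, ...] = (0.4, 0.65, 0.8)
    rs_noise_sd: float = 0.03
    rt_start: float = 5.0
    rt_step: float = 0.5
    rt_jitter_sd: float = 0.05
    event_time_sd: float = 0.05
    seed: int = 0

    @property
    def n_types(self) -> int:
        return len(self.type_names)

    def __post_init__(self) -> None:
        if len(self.samples_per_type) != self.n_types:
            raise ValidationError("samples_per_type length must equal the number of types")
        if any(n < 1 for n in self.samples_per_type):
            raise ValidationError("each type needs at least one sample")
        if len(self.rs_type_means) != self.n_types:
            raise ValidationError("rs_type_means length must equal the number of types")
        if not 0 <= self.dropout_p <= 1:
            raise ValidationError("dropout_p must be a probability in [0, 1]")
        for name in ("area_log_sd", "intensity_sd", "rs_noise_sd", "rt_jitter_sd",
                     "event_time_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_shared_compounds < len(self.fat_acidity_beta):
            raise ValidationError(
                "n_shared_compounds must cover the fat-acidity signal compounds"
            )
        if self.n_strong_specific > self.n_type_specific:
            raise ValidationError("n_strong_specific cannot exceed n_type_specific")
        if self.n_background > 0 and all(n == 1 for n in self.samples_per_type):
            raise ValidationError(
                "background compounds require at least one multi-sample type "
                "(they are never placed in single-sample types, so planted key "
                "sets stay identifiable)"
            )

    def no_noise(self) -> "SyntheticConfig":
        """The deterministic-recovery limit: no dropout, exact ordinal
        scores, smelling times exactly on the peaks."""
        return replace(self, dropout_p=0.0, intensity_sd=0.0, event_time_sd=0.0)


@dataclass
class GroundTruth:
    """What the generator planted; fully determined by (config, seed)."""

    key_compounds: dict[str, frozenset[str]]
    characteristic: dict[str, frozenset[str]]
    signal_compounds: tuple[str, ...]
    beta: dict[str, float]
    noise_sd: float
    population_R: float
    signal: dict[str, float]  # per-sample centred signal beta . (z - mu)


@dataclass
class SyntheticDataset:
    areas: CompoundTable
    panel: GCOPanel
    functional: pd.DataFrame
    peaks: pd.DataFrame
    flavor_map: FlavorTypeMap
    truth: GroundTruth
    config: SyntheticConfig


def signal_variance(config: SyntheticConfig) -> float:
    """Closed-form population variance of the fat-acidity signal."""
    return config.area_log_sd**2 * float(sum(b * b for b in config.fat_acidity_beta))


def calibrate_noise_for_R(config: SyntheticConfig, target_R: float) -> float:
    """Noise sd giving population correlation ``target_R`` between fat
    acidity and its volatile signal: R^2 = V / (V + sd^2) inverted."""
    if not 0 < target_R < 1:
        raise ValidationError(f"target_R must be in (0, 1), got {target_R}")
    v = signal_variance(config)
    if v <= 0:
        raise ValidationError("signal variance is zero; set fat_acidity_beta and area_log_sd")
    return math.sqrt(v * (1.0 / target_R**2 - 1.0))


def implied_R(config: SyntheticConfig, noise_sd: float) -> float:
    """Population R implied by a noise sd under the closed-form model."""
    v = signal_variance(config)
    return math.sqrt(v / (v + noise_sd**2))


def detection_probability(content: float, slope: float, mid: float) -> float:
    """Per-evaluator odds a weak compound is perceived, as a logistic
    function of log relative content (%)."""
    if content <= 0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-slope * (math.log(content) - mid)))


def _round_int(x: np.ndarray) -> np.ndarray:
    # half-up, matching the ordinal scoring convention
    return np.floor(x + 0.5)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one complete dataset (GC-MS areas, GC-O panel, functional
    components, peak list, flavor map) plus its ground truth."""
    rng = np.random.default_rng(config.seed)

    # --- roster -----------------------------------------------------------
    shared = [f"shared-{i + 1:02d}" for i in range(config.n_shared_compounds)]
    specific = {
        t: [f"{t}-key-{i + 1}" for i in range(config.n_type_specific)]
        for t in config.type_names
    }
    background = [f"bg-{i + 1:03d}" for i in range(config.n_background)]
    roster = shared + [c for t in config.type_names for c in specific[t]] + background

    classes = list(CLASS_WEIGHTS)
    weights = np.array([CLASS_WEIGHTS[c] for c in classes], dtype=float)
    weights /= weights.sum()
    chem_class = {c: rng.choice(classes, p=weights) for c in roster}

    order = rng.permutation(len(roster))
    base_rt = {roster[i]: config.rt_start + config.rt_step * rank
               for rank, i in enumerate(order)}

    # --- samples ----------------------------------------------------------
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for t, n in zip(config.type_names, config.samples_per_type):
        for i in range(n):
            sid = f"{t}-{i + 1}"
            samples.append(sid)
            assignments[sid] = t
    fmap = FlavorTypeMap(assignments)
    multi_samples = [s for s in samples if len(fmap.samples_of(assignments[s])) > 1]

    # --- presence ---------------------------------------------------------
    present: dict[str, list[str]] = {s: list(shared) for s in samples}
    for t in config.type_names:
        for s in fmap.samples_of(t):
            present[s].extend(specific[t])
    for c in background:
        present[rng.choice(multi_samples) if multi_samples else samples[0]].append(c)

    # --- areas and latent signal ------------------------------------------
    n_signal = len(config.fat_acidity_beta)
    signal_compounds = tuple(shared[:n_signal])
    rows = []
    latent_z: dict[str, dict[str, float]] = {}
    for s in samples:
        latent_z[s] = {}
        for c in present[s]:
            z = rng.normal(config.area_log_mean, config.area_log_sd)
            latent_z[s][c] = z
            rows.append(
                {
                    "sample": s,
                    "compound": c,
                    "chem_class": chem_class[c],
                    "value": math.exp(z),
                    "retention_time": base_rt[c] + rng.normal(0.0, config.rt_jitter_sd),
                }
            )
    frame = pd.DataFrame(rows)

    # --- dropout (measurement only; never empties a sample) ---------------
    if config.dropout_p > 0:
        keep = rng.random(len(frame)) >= config.dropout_p
        for s in samples:
            mine = frame.index[frame["sample"] == s]
            if not keep[mine].any():
                keep[mine[0]] = True
        frame = frame[keep]

    areas = CompoundTable(frame, dialect="area")
    areas.samples = list(samples)
    peaks = validate_peak_list(frame[["sample", "compound", "retention_time"]])

    # --- ground-truth strong/characteristic sets ---------------------------
    global_strong = shared[n_signal] if config.include_global_strong else None
    strong: dict[str, frozenset[str]] = {}
    for t in config.type_names:
        s_set = set(specific[t][: config.n_strong_specific])
        if global_strong:
            s_set.add(global_strong)
        strong[t] = frozenset(s_set)

    # --- GC-O events -------------------------------------------------------
    totals = frame.groupby("sample")["value"].sum()
    evaluators = [f"E{i + 1}" for i in range(config.n_evaluators)]
    events = []
    measured = {s: g for s, g in frame.groupby("sample")}
    for s in samples:
        t = assignments[s]
        mine = measured.get(s)
        if mine is None:
            continue
        for row in mine.itertuples(index=False):
            c = row.compound
            content = 100.0 * row.value / totals[s]
            if c in strong[t]:
                latent = config.strong_latent
                who = evaluators
                descriptor = f"{t.replace('_', ' ')} fragrance"
            else:
                p = detection_probability(
                    content, config.detection_slope, config.detection_mid
                )
                who = [evaluators[rng.integers(config.n_evaluators)]] if rng.random() < p else []
                latent = config.weak_latent
                descriptor = "faint note"
            for e in who:
                score = _round_int(
                    np.array([latent + rng.normal(0.0, config.intensity_sd)])
                )[0]
                events.append(
                    {
                        "sample": s,
                        "evaluator": e,
                        "time_min": max(
                            0.0, row.retention_time + rng.normal(0.0, config.event_time_sd)
                        ),
                        "descriptor": descriptor,
                        "intensity": int(min(5, max(1, score))),
                    }
                )
    panel = GCOPanel(pd.DataFrame(events, columns=["sample", "evaluator", "time_min",
                                                   "descriptor", "intensity"]),
                     n_evaluators=config.n_evaluators)

    # --- functional components ---------------------------------------------
    noise_sd = config.noise_sd
    if noise_sd is None:
        noise_sd = calibrate_noise_for_R(config, config.target_R)
    beta = dict(zip(signal_compounds, config.fat_acidity_beta))
    rs_mean = dict(zip(config.type_names, config.rs_type_means))
    func_rows = []
    signal: dict[str, float] = {}
    for s in samples:
        sig = sum(
            b * (latent_z[s][c] - config.area_log_mean) for c, b in beta.items()
        )
        signal[s] = float(sig)
        fat = config.fat_acidity_intercept + sig + rng.normal(0.0, noise_sd)
        rs = rs_mean[assignments[s]] + rng.normal(0.0, config.rs_noise_sd)
        func_rows.append(
            {
                "sample": s,
                "resistant_starch": max(0.01, rs),
                "fat_acidity": max(0.0, fat),
            }
        )
    functional = validate_functional_table(pd.DataFrame(func_rows))

    truth = GroundTruth(
        key_compounds={t: frozenset(specific[t]) for t in config.type_names},
        characteristic=strong,
        signal_compounds=signal_compounds,
        beta=beta,
        noise_sd=float(noise_sd),
        population_R=implied_R(config, noise_sd),
        signal=signal,
    )
    return SyntheticDataset(
        areas=areas, panel=panel, functional=functional, peaks=peaks,
        flavor_map=fmap, truth=truth, config=config,
    )


# ---------------------------------------------------------------------------
# recovery metrics (generator truth vs. pipeline output)
# ---------------------------------------------------------------------------


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard similarity; two empty sets count as identical (1.0)."""
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recovered_key_compounds(dataset: SyntheticDataset) -> dict[str, frozenset[str]]:
    """Run quantify → commonality on the dataset and return the key sets."""
    from .commonality import common_compounds, key_compounds, venn_partition
    from .quantify import presence_matrix, relative_content

    percent = relative_content(dataset.areas)
    pm = presence_matrix(percent)
    commons = {
        t: common_compounds(pm, dataset.flavor_map.samples_of(t), rule="all", label=t)
        for t in dataset.flavor_map.types
    }
    keys = key_compounds(venn_partition(commons))
    return {t: keys[t].members for t in commons}


def key_recovery_jaccard(dataset: SyntheticDataset) -> float:
    """Mean per-type Jaccard between recovered and planted key sets."""
    recovered = recovered_key_compounds(dataset)
    truth = dataset.truth.key_compounds
    return float(np.mean([jaccard(recovered[t], truth[t]) for t in truth]))


def recovered_characteristic(dataset: SyntheticDataset, **kwargs) -> dict[str, frozenset[str]]:
    """Run olfactometry on the dataset and return per-type called sets."""
    from .olfactometry import build_spectrograms, characteristic_compounds

    specs = build_spectrograms(dataset.panel, dataset.peaks,
                               samples=list(dataset.flavor_map.assignments))
    call = characteristic_compounds(specs, dataset.flavor_map, **kwargs)
    return {t: call.compounds_of(t) for t in dataset.flavor_map.types}


def characteristic_recovery_jaccard(dataset: SyntheticDataset) -> float:
    """Mean per-type Jaccard between called and planted characteristic sets."""
    called = recovered_characteristic(dataset)
    truth = dataset.truth.characteristic
    return float(np.mean([jaccard(called[t], truth[t]) for t in truth]))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write the dataset in the same text formats the readers ingest, plus
    the ground truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_compound_table(dataset.areas, outdir / "compound_areas.tsv")
    write_gco_events(dataset.panel, outdir / "gco_events.tsv")
    write_functional_table(dataset.functional, outdir / "functional.tsv")
    write_peak_list(dataset.peaks, outdir / "peaks.tsv")
    write_flavor_map(dataset.flavor_map, outdir / "flavor_map.yaml")
    truth = dataset.truth
    payload = {
        "key_compounds": {t: sorted(v) for t, v in truth.key_compounds.items()},
        "characteristic": {t: sorted(v) for t, v in truth.characteristic.items()},
        "signal_compounds": list(truth.signal_compounds),
        "beta": truth.beta,
        "noise_sd": truth.noise_sd,
        "population_R": truth.population_R,
        "signal": truth.signal,
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
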