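"""Set procedures for flavor typing.

A flavor type's *common compounds* are those detected in every sample of
the type.  Comparing the common sets of the flavor types in a coincidence
(Venn) partition, the compounds exclusive to one type's common set are that
type's *key compounds*.  A separate procedure lists compounds shared
between a reference sample and a comparison group (e.g. the Thai reference
versus the Chinese popcorn-flavor samples).

The Venn partition is computed exactly by enumerating each compound's
membership vector across the input sets, so it generalizes to any number
of flavor types and never relies on inclusion-exclusion arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import chain, combinations
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import ValidationError
from .quantify import PresenceMatrix


@dataclass(frozen=True)
class CompoundSet:
    """A labelled set of canonical compound names."""

    label: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("CompoundSet label must be nonempty")

    def __len__(self) -> int:
        return len(self.members)


def common_compounds(
    matrix: PresenceMatrix,
    samples: Sequence[str],
    rule: str = "all",
    k: int | None = None,
    label: str = "common",
) -> CompoundSet:
    """Compounds satisfying a detection rule over the listed samples.

    ``rule="all"`` (the default) is the common-compound definition: present
    in every listed sample.  ``"any"`` keeps compounds present in at least
    one; ``"at_least_k"`` requires presence in at least ``k`` of them.
    """
    if not samples:
        raise ValidationError("samples list must be nonempty")
    unknown = [s for s in samples if s not in matrix.samples]
    if unknown:
        raise ValidationError(f"unknown sample id(s): {unknown}")
    if rule not in ("all", "any", "at_least_k"):
        raise ValidationError(f"unknown rule {rule!r}")
    sub = matrix.matrix[list(samples)]
    if rule == "all":
        mask = sub.all(axis=1)
    elif rule == "any":
        mask = sub.any(axis=1)
    else:
        if k is None or k < 1:
            raise ValidationError("rule 'at_least_k' requires k >= 1")
        if k > len(samples):
            raise ValidationError(f"k={k} exceeds the {len(samples)} listed samples")
        mask = sub.sum(axis=1) >= k
    return CompoundSet(label=label, members=frozenset(mask.index[mask]))


def shared_with_reference(
    matrix: PresenceMatrix,
    reference: str,
    others: Sequence[str],
    rule: str = "any",
) -> CompoundSet:
    """Compounds shared between a reference sample and a comparison group.

    A compound qualifies when it is detected in the reference AND satisfies
    ``rule`` over the comparison samples.  The default ``"any"`` reading
    (reference plus at least one comparison sample) is the one consistent
    with the printed 28-compound shared list, whose rows include "—" cells;
    the strict ``"all"`` reading is selectable.
    """
    if reference in others:
        raise ValidationError(f"reference {reference!r} must not appear in others")
    if rule not in ("any", "all"):
        raise ValidationError(f"rule must be 'any' or 'all', got {rule!r}")
    ref = common_compounds(matrix, [reference], rule="all", label="reference")
    grp = common_compounds(matrix, list(others), rule=rule, label="group")
    return CompoundSet(
        label=f"shared({reference})", members=ref.members & grp.members
    )


@dataclass
class VennResult:
    """Exact disjoint partition of the union of labelled compound sets.

    ``regions`` maps each nonempty subset of labels (as a frozenset) to the
    compounds belonging to exactly those input sets.  Regions are pairwise
    disjoint and their union is ``universe``.
    """

    labels: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]
    universe: frozenset[str]

    def region(self, *labels: str) -> frozenset[str]:
        return self.regions.get(frozenset(labels), frozenset())

    def sizes(self) -> dict[str, int]:
        """Region sizes keyed by a 'A&B' style label, ordered by subset
        size descending then lexically (stable for reports)."""
        out = {}
        for key in _ordered_subsets(self.labels):
            out["&".join(sorted(key))] = len(self.regions.get(key, frozenset()))
        return out


def _ordered_subsets(labels: Sequence[str]):
    subs = chain.from_iterable(
        combinations(sorted(labels), r) for r in range(len(labels), 0, -1)
    )
    return [frozenset(s) for s in subs]


def venn_partition(sets: Mapping[str, CompoundSet | frozenset | set]) -> VennResult:
    """Partition the union of the input sets into exclusive Venn regions.

    Accepts a mapping from type label to a :class:`CompoundSet` or plain
    set.  Requires at least two input sets; duplicate labels cannot occur
    in a mapping, but empty labels are rejected.
    """
    if len(sets) < 2:
        raise ValidationError("venn_partition needs at least 2 input sets")
    members: dict[str, frozenset[str]] = {}
    for label, s in sets.items():
        if not str(label):
            raise ValidationError("set labels must be nonempty")
        members[str(label)] = frozenset(s.members if isinstance(s, CompoundSet) else s)
    universe = frozenset().union(*members.values())
    regions: dict[frozenset[str], set[str]] = {}
    for compound in universe:
        signature = frozenset(l for l, m in members.items() if compound in m)
        regions.setdefault(signature, set()).add(compound)
    return VennResult(
        labels=tuple(members),
        regions={k: frozenset(v) for k, v in regions.items()},
        universe=universe,
    )


def key_compounds(venn: VennResult) -> dict[str, CompoundSet]:
    """Each flavor type's exclusive Venn region: its key compounds."""
    return {
        label: CompoundSet(label=label, members=venn.region(label))
        for label in venn.labels
    }


def write_venn_regions(venn: VennResult, tsv_path: str | Path, json_path: str | Path) -> None:
    """Emit region membership as TSV (compound, region) and sizes as JSON."""
    rows = []
    for key in _ordered_subsets(venn.labels):
        for compound in sorted(venn.regions.get(key, frozenset())):
            rows.append({"compound": compound, "region": "&".join(sorted(key))})
    pd.DataFrame(rows, columns=["compound", "region"]).to_csv(
        Path(tsv_path), sep="\t", index=False
    )
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(venn.sizes(), fh, indent=2, sort_keys=False)
        fh.write("\n")
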