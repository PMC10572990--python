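"""Venn set algebra and exclusive-marker calling over the comparison lattice.

The study design compares each exposure group to every other within a sex:
three comparisons against control (CT), two against nicotine (NIC), and the
combined group against phencyclidine (PCPNIC vs PCP). Deregulated-protein
sets from these comparisons are partitioned with Venn set algebra, and a
group's "exclusive markers" are the proteins deregulated in every
comparison involving that group — refined, for families of comparisons that
share a reference group, to proteins deregulated *only* in that group's
comparison of the family. Membership ignores direction everywhere in the
set algebra; per-comparison directions are attached to the resulting
markers, with a consistency flag, but direction consistency is not required
for membership.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence, Set
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import pandas as pd

from .differential import ComparisonResult
from .errors import ConfigurationError, ValidationError

PLAIN_INTERSECTION = "plain_intersection"
EXCLUSIVITY_REFINED = "exclusivity_refined"


def venn_partition(
    family: Mapping[str, Set[str]],
) -> dict[frozenset[str], frozenset[str]]:
    """Partition the union of named sets into Venn regions.

    region(S) = intersection of the sets named in S minus the union of the
    others, for every non-empty membership signature S. Regions are pairwise
    disjoint and cover the union of the inputs; the empty signature is
    excluded.
    """
    if not family:
        raise ValidationError("empty set family")
    universe: set[str] = set()
    for s in family.values():
        universe |= set(s)
    regions: dict[frozenset[str], set[str]] = {}
    for item in universe:
        signature = frozenset(name for name, s in family.items() if item in s)
        regions.setdefault(signature, set()).add(item)
    return {sig: frozenset(items) for sig, items in regions.items()}


def exclusive_proteins(family: Mapping[str, Set[str]], name: str) -> frozenset[str]:
    """Proteins in the named set and in no other set of the family."""
    if name not in family:
        raise KeyError(name)
    others: set[str] = set()
    for other, s in family.items():
        if other != name:
            others |= set(s)
    return frozenset(set(family[name]) - others)


@dataclass
class MarkerSet:
    """Proteins surviving the marker set logic for one group and sex.

    ``directions`` maps protein -> {comparison label -> "Up"/"Down"}, one
    entry per comparison involving the group; ``consistent`` flags proteins
    whose direction agrees across all three comparisons.
    """

    sex: str
    group: str
    proteins: frozenset[str]
    directions: dict[str, dict[str, str]] = field(default_factory=dict)
    mode: str = EXCLUSIVITY_REFINED
    consistent: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        labels: list[str] = []
        for per_cmp in self.directions.values():
            for lab in per_cmp:
                if lab not in labels:
                    labels.append(lab)
        rows = []
        for p in sorted(self.proteins):
            row = {"protein_id": p}
            row.update(self.directions.get(p, {}))
            row["direction_consistent"] = self.consistent.get(p)
            rows.append(row)
        return pd.DataFrame(
            rows, columns=["protein_id", *labels, "direction_consistent"])


def _index_results(
    results: Sequence[ComparisonResult],
) -> dict[frozenset[str], ComparisonResult]:
    index: dict[frozenset[str], ComparisonResult] = {}
    for res in results:
        key = frozenset((res.focal, res.reference))
        if key in index:
            raise ConfigurationError(
                f"duplicate comparison for pair {sorted(key)}")
        index[key] = res
    return index


def _group_order(results: Sequence[ComparisonResult]) -> list[str]:
    """Recover the lattice hierarchy: each comparison's reference precedes
    its focal group. Topological order breaks remaining ties by first
    appearance."""
    ts = TopologicalSorter()
    seen: list[str] = []
    for res in results:
        ts.add(res.focal, res.reference)
        for g in (res.reference, res.focal):
            if g not in seen:
                seen.append(g)
    try:
        order = list(ts.static_order())
    except CycleError as err:
        raise ConfigurationError(
            f"comparison lattice is cyclic: {err}") from err
    return sorted(order, key=lambda g: (order.index(g)))


def group_markers(
    results: Sequence[ComparisonResult],
    group: str,
    mode: str = PLAIN_INTERSECTION,
) -> MarkerSet:
    """Markers of ``group``: proteins deregulated in every comparison
    involving the group.

    ``plain_intersection`` intersects the three DE sets directly.
    ``exclusivity_refined`` first replaces, within each family of
    comparisons sharing a reference group, the group's DE set by its
    exclusive region (proteins deregulated in no other comparison of that
    family), then intersects.
    """
    if mode not in (PLAIN_INTERSECTION, EXCLUSIVITY_REFINED):
        raise ConfigurationError(f"unknown marker mode {mode!r}")
    index = _index_results(results)
    order = _group_order(results)
    if group not in order:
        raise ConfigurationError(f"no comparison involves group {group!r}")
    rank = {g: i for i, g in enumerate(order)}

    missing = [
        f"{group} vs {other}" for other in order
        if other != group and frozenset((group, other)) not in index
    ]
    if missing:
        raise ConfigurationError(
            f"missing comparisons in lattice: {', '.join(missing)}")

    markers: set[str] | None = None
    sexes = {res.sex for res in results}
    if len(sexes) != 1:
        raise ConfigurationError(
            f"results mix sexes {sorted(sexes)}; call once per sex")

    for other in order:
        if other == group:
            continue
        pair = frozenset((group, other))
        own = set(index[pair].de_set)
        reference = other if rank[other] < rank[group] else group
        family = {
            key: index[key].de_set for key in index
            if reference in key
        }
        if (mode == EXCLUSIVITY_REFINED and rank[other] < rank[group]
                and len(family) > 1):
            named = {" vs ".join(sorted(k)): v for k, v in family.items()}
            contrib = set(
                exclusive_proteins(named, " vs ".join(sorted(pair))))
        else:
            contrib = own
        markers = contrib if markers is None else markers & contrib

    proteins = frozenset(markers or set())
    directions: dict[str, dict[str, str]] = {p: {} for p in proteins}
    consistent: dict[str, bool] = {}
    for other in order:
        if other == group:
            continue
        res = index[frozenset((group, other))]
        label = f"{group} vs {other}"
        for p in proteins:
            rec = next(r for r in res.records if r.protein_id == p)
            d = rec.direction
            if res.focal != group and d is not None:
                d = "up" if d == "down" else "down"
            directions[p][label] = {"up": "Up", "down": "Down"}.get(d, d)
    for p in proteins:
        vals = set(directions[p].values())
        consistent[p] = len(vals) == 1
    return MarkerSet(sex=next(iter(sexes)), group=group, proteins=proteins,
                     directions=directions, mode=mode, consistent=consistent)


def pcpnic_markers(
    results: Sequence[ComparisonResult],
    mode: str = EXCLUSIVITY_REFINED,
) -> MarkerSet:
    """Markers of the combined-insult (PCPNIC) group.

    Default mode is exclusivity-refined: proteins exclusively deregulated in
    PCPNIC vs CT (among the vs-CT comparisons) and in PCPNIC vs NIC (among
    the vs-NIC comparisons), intersected with the PCPNIC vs PCP DE set.
    """
    return group_markers(results, "PCPNIC", mode=mode)


def sex_exclusivity_fraction(
    male_results: Sequence[ComparisonResult],
    female_results: Sequence[ComparisonResult],
) -> float:
    """Share of deregulated proteins deregulated in exactly one sex.

    The denominator is the union of proteins deregulated in at least one
    comparison in at least one sex. Returns NaN (with a warning) when that
    union is empty.
    """
    male_union: set[str] = set()
    for res in male_results:
        male_union |= res.de_set
    female_union: set[str] = set()
    for res in female_results:
        female_union |= res.de_set
    universe = male_union | female_union
    if not universe:
        warnings.warn("no deregulated proteins in either sex; "
                      "sex-exclusivity fraction undefined", stacklevel=2)
        return float("nan")
    one_sex = male_union ^ female_union
    return len(one_sex) / len(universe)
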