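"""Pathway-frequency summaries of protein sets.

A protein set (typically a marker set or an exclusively-deregulated set) is
summarised against an offline pathway annotation by counting, for each
pathway, how many query proteins it contains, and reporting the ``k`` most
frequent pathways ("top 6" bar summaries). Ranking is by raw count — the
figures this reproduces plot protein counts per pathway, not an
overrepresentation statistic.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

DEFAULT_TOP_K = 6


class PathwayAnnotation:
    """Mapping of pathway id -> (description, protein set).

    Pathway ids are unique; protein sets are non-empty. A protein may belong
    to several pathways, as in Reactome.
    """

    def __init__(self, pathways: Mapping[str, tuple[str, Iterable[str]]]):
        self._pathways: dict[str, tuple[str, frozenset[str]]] = {}
        for pid, (desc, proteins) in pathways.items():
            members = frozenset(proteins)
            if not members:
                raise ValidationError(f"pathway {pid!r} has an empty protein set")
            self._pathways[str(pid)] = (str(desc), members)

    def __len__(self) -> int:
        return len(self._pathways)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._pathways

    def __getitem__(self, pathway_id: str) -> tuple[str, frozenset[str]]:
        return self._pathways[pathway_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PathwayAnnotation):
            return NotImplemented
        return self._pathways == other._pathways

    def ids(self) -> list[str]:
        return list(self._pathways)

    def items(self):
        return self._pathways.items()

    def proteins(self, pathway_id: str) -> frozenset[str]:
        return self._pathways[pathway_id][1]

    def description(self, pathway_id: str) -> str:
        return self._pathways[pathway_id][0]

    @property
    def protein_union(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self._pathways.values():
            out |= members
        return frozenset(out)


def pathway_frequency(
    query: Iterable[str],
    annotation: PathwayAnnotation,
    k: int = DEFAULT_TOP_K,
) -> pd.DataFrame:
    """Count query proteins per pathway and keep the top ``k`` pathways.

    Parameters
    ----------
    query
        Protein identifiers to summarise.
    annotation
        Offline pathway annotation (e.g. read from a GMT file).
    k
        Number of rows to keep, default 6.

    Returns
    -------
    DataFrame with columns ``pathway_id, description, count, proteins``
    (member proteins semicolon-joined, sorted), at most ``k`` rows, sorted by
    count descending then pathway id ascending. Pathways with count 0 are
    dropped. An empty query yields an empty table; an empty annotation is an
    error.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if len(annotation) == 0:
        raise ValidationError("empty pathway annotation")
    qset = frozenset(query)
    rows = []
    for pid, (desc, members) in annotation.items():
        hit = qset & members
        if hit:
            rows.append((pid, desc, len(hit), ";".join(sorted(hit))))
    table = pd.DataFrame(rows, columns=["pathway_id", "description", "count", "proteins"])
    table = table.sort_values(
        ["count", "pathway_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    table = table.reset_index(drop=True)
    table.attrs["query_size"] = len(qset)
    table.attrs["k"] = k
    return table
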