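"""Readers and writers for pipeline file formats, plus packaged fixtures.

Formats: CSV/TSV peptide and protein tables (delimiter from extension),
3-column interaction edge lists (STRING export dialect tolerated), GMT
pathway annotations, GraphML graph export, JSON Venn-region reports.

Packaged fixtures reproduce the published marker tables for the male and
female combined-insult interactome maps. The accompanying edge lists
(``*_edges_synthetic.tsv``) are synthetic reconstructions consistent with
the described map connectivity (the published figures are not
machine-readable); tests treat them as fixtures, not ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import PathwayAnnotation
from .errors import ValidationError
from .markers import MarkerSet
from .network import EDGE_COLUMNS, InteractionGraph
from .quantify import PEPTIDE_COLUMNS, validate_peptide_table

_STRING_HEADER = {"protein1": "protein_a", "protein2": "protein_b",
                  "combined_score": "confidence", "node1": "protein_a",
                  "node2": "protein_b", "score": "confidence"}
FIXTURE_NAMES = ("table1", "table2")


def _sep_for(path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def read_peptide_table(path) -> pd.DataFrame:
    """Load and validate a long-format peptide intensity table."""
    table = pd.read_csv(path, sep=_sep_for(path))
    validate_peptide_table(table)
    return table[list(PEPTIDE_COLUMNS)]


def write_peptide_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep=_sep_for(path), index=False)


def read_protein_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep=_sep_for(path))
    if "level" in table.columns:
        levels = table["level"].unique()
        if len(levels) == 1:
            table.attrs["level"] = levels[0]
        table = table.drop(columns="level")
    return table


def write_protein_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    if "level" in table.attrs:
        out["level"] = table.attrs["level"]
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_edge_list(path) -> pd.DataFrame:
    """Read a 3-column interaction edge list.

    Accepts the package's ``protein_a/protein_b/confidence`` header, the
    STRING export dialect (``protein1 protein2 combined_score``), or a
    headerless 3-column file.
    """
    frame = pd.read_csv(path, sep=None, engine="python", header=None)
    if frame.shape[1] < 3:
        raise ValidationError(
            f"edge list needs 3 columns, found {frame.shape[1]} in {path}")
    first = [str(v).strip().lower() for v in frame.iloc[0]]
    if any(v in _STRING_HEADER or v in EDGE_COLUMNS for v in first):
        names = [_STRING_HEADER.get(v, v) for v in first]
        frame = frame.iloc[1:].reset_index(drop=True)
        frame.columns = names
    else:
        frame.columns = list(EDGE_COLUMNS)[:frame.shape[1]]
    missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(
            f"edge list missing columns: {', '.join(missing)}")
    frame = frame[list(EDGE_COLUMNS)]
    frame["confidence"] = pd.to_numeric(frame["confidence"], errors="raise")
    return frame


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> PathwayAnnotation:
    """Read a GMT file: pathway id, description, then member proteins."""
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"{path}:{line_no}: GMT line needs id, description and "
                    f"at least one protein")
            pid, desc, proteins = parts[0], parts[1], [p for p in parts[2:] if p]
            if pid in pathways:
                raise ValidationError(f"{path}:{line_no}: duplicate pathway {pid!r}")
            pathways[pid] = (desc, frozenset(proteins))
    return PathwayAnnotation(pathways)


def write_gmt(annotation: PathwayAnnotation, path) -> None:
    with open(path, "w") as fh:
        for pid, (desc, members) in annotation.items():
            fh.write("\t".join([pid, desc, *sorted(members)]) + "\n")


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV/CSV: protein id -> functional label."""
    frame = pd.read_csv(path, sep=_sep_for(path))
    if frame.shape[1] < 2:
        raise ValidationError("category map needs two columns")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def write_venn_regions(regions, path) -> None:
    payload = {
        " & ".join(sorted(sig)): sorted(items)
        for sig, items in regions.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_graphml(graph: InteractionGraph, path) -> None:
    nx.write_graphml(graph.graph, path)


@dataclass
class PaperFixture:
    """A published marker table plus its synthetic-reconstruction edges.

    ``markers`` columns: subnetwork, protein_name, gene_name, vs_ct,
    vs_nic, vs_pcp. ``category_map`` maps gene name -> subnetwork label.
    """

    name: str
    sex: str
    markers: pd.DataFrame
    edges: pd.DataFrame
    category_map: dict[str, str]

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.markers["gene_name"])

    def marker_set(self) -> MarkerSet:
        directions = {
            row.gene_name: {
                "PCPNIC vs CT": row.vs_ct,
                "PCPNIC vs NIC": row.vs_nic,
                "PCPNIC vs PCP": row.vs_pcp,
            }
            for row in self.markers.itertuples(index=False)
        }
        consistent = {
            p: len(set(d.values())) == 1 for p, d in directions.items()
        }
        return MarkerSet(sex=self.sex, group="PCPNIC",
                         proteins=self.proteins, directions=directions,
                         consistent=consistent)


def load_fixture(name: str) -> PaperFixture:
    """Load a packaged marker-table fixture ("table1" males, "table2" females)."""
    if name not in FIXTURE_NAMES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    root = resources.files("lfqmarkers") / "fixtures"
    with resources.as_file(root / f"{name}_markers.tsv") as p:
        markers = pd.read_csv(p, sep="\t")
    with resources.as_file(root / f"{name}_edges_synthetic.tsv") as p:
        edges = read_edge_list(p)
    return PaperFixture(
        name=name,
        sex="M" if name == "table1" else "F",
        markers=markers,
        edges=edges,
        category_map=dict(zip(markers["gene_name"], markers["subnetwork"])),
    )


def export_fixture(name: str, out_dir) -> list[Path]:
    """Copy a packaged fixture's files into a directory; returns the paths."""
    fixture = load_fixture(name)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker_path = out / f"{name}_markers.tsv"
    edge_path = out / f"{name}_edges_synthetic.tsv"
    fixture.markers.to_csv(marker_path, sep="\t", index=False)
    write_edge_list(fixture.edges, edge_path)
    return [marker_path, edge_path]
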