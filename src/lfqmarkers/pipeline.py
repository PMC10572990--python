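"""End-to-end orchestration: quantify -> compare -> markers -> enrich -> network.

The stages follow the study's comparison scheme: each non-control group is
compared to control, the phencyclidine-exposed groups are compared to the
nicotine group, and the combined group is compared to phencyclidine alone;
exclusive markers per group are then extracted by Venn set algebra,
summarised by pathway frequency, and mapped onto the interactome.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as lio
from .differential import ComparisonResult, DEThresholds, pairwise_compare
from .enrichment import DEFAULT_TOP_K, pathway_frequency
from .errors import PipelineError
from .markers import (EXCLUSIVITY_REFINED, PLAIN_INTERSECTION, MarkerSet,
                      group_markers, sex_exclusivity_fraction, venn_partition)
from .network import (DEFAULT_MIN_CONFIDENCE, build_marker_graph,
                      decompose_subnetworks, node_table)
from .quantify import aggregate_technical, filter_identifications, hi3_quantify

LATTICE_ORDER = ("CT", "NIC", "PCP", "PCPNIC")
logger = logging.getLogger("lfqmarkers")


@dataclass
class PipelineConfig:
    """Paths, thresholds and options for a full pipeline run."""

    peptide_table: str
    out_dir: str
    edges: str | None = None
    annotation: str | None = None
    category_map: str | None = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    marker_mode: str = EXCLUSIVITY_REFINED
    top_k: int = DEFAULT_TOP_K
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    min_peptides: int = 2
    min_runs: int = 2
    use_log: bool = False
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).lower().endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = DEThresholds(**raw["thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


def comparison_lattice(groups) -> list[tuple[str, str]]:
    """(focal, reference) pairs for every unordered pair of groups.

    Groups are ordered canonically (CT, NIC, PCP, PCPNIC first, any extra
    labels after, in observed order); the earlier group of a pair is the
    reference.
    """
    canonical = [g for g in LATTICE_ORDER if g in groups]
    canonical += [g for g in groups if g not in canonical]
    return [
        (canonical[j], canonical[i])
        for i in range(len(canonical))
        for j in range(i + 1, len(canonical))
    ]


def run_comparisons(
    pools: pd.DataFrame,
    sex: str,
    thresholds: DEThresholds = DEThresholds(),
    use_log: bool = False,
) -> list[ComparisonResult]:
    groups = list(pools.loc[pools["sex"] == sex, "group"].unique())
    return [
        pairwise_compare(pools, sex, focal, reference, thresholds,
                         use_log=use_log)
        for focal, reference in comparison_lattice(groups)
    ]


def _summary_for_sex(results: list[ComparisonResult],
                     marker_sets: dict[str, MarkerSet]) -> dict:
    """Comparison-lattice summary: DE counts with up/down splits, exclusive
    counts per reference family, marker counts per group."""
    per_comparison = {}
    for res in results:
        ups = sum(1 for d in res.directions.values() if d == "up")
        per_comparison[res.name] = {
            "n_de": len(res.de_set),
            "n_up": ups,
            "n_down": len(res.de_set) - ups,
        }
    exclusive = {}
    references = {res.reference for res in results}
    for ref in references:
        family = {res.name: res.de_set for res in results if res.reference == ref}
        if len(family) > 1:
            regions = venn_partition(family) if any(family.values()) else {}
            for name in family:
                exclusive[f"{name} exclusive"] = len(
                    regions.get(frozenset((name,)), ()))
    marker_counts = {}
    for group, ms in marker_sets.items():
        ups = sum(
            1 for d in ms.directions.values()
            if list(d.values()) and list(d.values())[0] == "Up")
        marker_counts[group] = {
            "n_markers": len(ms.proteins),
            "n_up_vs_first_reference": ups,
            "n_down_vs_first_reference": len(ms.proteins) - ups,
        }
    return {
        "comparisons": per_comparison,
        "exclusive": exclusive,
        "markers": marker_counts,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write stage outputs and a run manifest.

    Returns the report bundle: pool-level abundances, per-sex comparison
    results, marker sets, enrichment tables, network node tables and the
    lattice summary. Outputs are confined to ``config.out_dir``.
    """
    logging.basicConfig(level=logging.INFO if config.verbosity else
                        logging.WARNING, format="%(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(name, str(err)) from err

    peptides = stage("read", lio.read_peptide_table, config.peptide_table)
    peptides = peptides.assign(group=peptides["group"].str.upper())

    filtered = stage("identification_filter", filter_identifications,
                     peptides, config.min_peptides, config.min_runs)
    run_level = stage("hi3", hi3_quantify, filtered)
    pools = stage("aggregate", aggregate_technical, run_level)
    lio.write_protein_table(pools, out / "protein_pools.csv")

    annotation = (stage("read_annotation", lio.read_gmt, config.annotation)
                  if config.annotation else None)
    edges = (stage("read_edges", lio.read_edge_list, config.edges)
             if config.edges else None)
    category_map = (stage("read_categories", lio.read_category_map,
                          config.category_map) if config.category_map else None)

    bundle: dict = {"pools": pools, "comparisons": {}, "markers": {},
                    "enrichment": {}, "network": {}, "summary": {}}
    for sex in sorted(pools["sex"].unique()):
        results = stage(f"compare[{sex}]", run_comparisons, pools, sex,
                        config.thresholds, config.use_log)
        bundle["comparisons"][sex] = results
        for res in results:
            safe = res.name.replace(" ", "_")
            res.to_frame().to_csv(out / f"comparison_{sex}_{safe}.csv",
                                  index=False)
        family = {res.name: res.de_set for res in results}
        if any(family.values()):
            lio.write_venn_regions(venn_partition(family),
                                   out / f"venn_{sex}.json")

        groups = [g for g in LATTICE_ORDER
                  if g in set(pools.loc[pools["sex"] == sex, "group"])]
        marker_sets: dict[str, MarkerSet] = {}
        for group in groups[1:]:
            mode = (config.marker_mode if group == "PCPNIC"
                    else PLAIN_INTERSECTION)
            ms = stage(f"markers[{sex},{group}]", group_markers, results,
                       group, mode)
            marker_sets[group] = ms
            ms.to_frame().to_csv(out / f"markers_{sex}_{group}.csv",
                                 index=False)
        bundle["markers"][sex] = marker_sets
        bundle["summary"][sex] = _summary_for_sex(results, marker_sets)

        if annotation is not None:
            enr = {}
            for group, ms in marker_sets.items():
                table = stage(f"enrich[{sex},{group}]", pathway_frequency,
                              ms.proteins, annotation, config.top_k)
                table.to_csv(out / f"enrichment_{sex}_{group}.csv", index=False)
                enr[group] = table
            bundle["enrichment"][sex] = enr

        if edges is not None and "PCPNIC" in marker_sets:
            graph = stage(f"network[{sex}]", build_marker_graph,
                          marker_sets["PCPNIC"], edges, config.min_confidence)
            subnets = None
            if category_map is not None and len(graph):
                subnets = stage(f"subnetworks[{sex}]", decompose_subnetworks,
                                graph, category_map)
            nodes = node_table(graph, subnets)
            nodes.to_csv(out / f"network_nodes_{sex}.csv", index=False)
            lio.write_graphml(graph, out / f"network_{sex}.graphml")
            bundle["network"][sex] = {
                "graph": graph, "subnetworks": subnets, "nodes": nodes,
                "unmapped": sorted(graph.unmapped),
            }

    sexes = sorted(bundle["comparisons"])
    if len(sexes) == 2:
        frac = sex_exclusivity_fraction(bundle["comparisons"][sexes[0]],
                                        bundle["comparisons"][sexes[1]])
        bundle["summary"]["sex_exclusivity_fraction"] = frac

    manifest = {"config": _jsonable(config.to_dict()),
                "summary": _jsonable(bundle["summary"])}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, allow_nan=True)
    bundle["manifest"] = manifest
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (int, float, str, bool)) or obj is None:
        return obj
    return str(obj)
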