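"""Synthetic peptide-level datasets with known ground truth.

Emulates the statistical structure of a pooled label-free (Hi3/MSE)
proteomics study of mouse medial prefrontal cortex: four exposure groups
(control, phencyclidine, nicotine, combined) x two sexes, four biological
pools per condition, three technical injections per pool, ~337 proteins
digested into ~3594 peptides. Group effects are planted multiplicatively
relative to the control group, so every downstream stage — Hi3
quantification, the CV/fold-change/ANOVA filter cascade, Venn marker logic,
enrichment and network analysis — can be tested against a known answer
without any external download.

Model
-----
Protein base abundances are log-normal. Each biological pool multiplies the
protein abundance by a mean-one log-normal factor (``bio_cv``); each peptide
carries a fixed log-normal ionization efficiency; each technical replicate
multiplies the peptide signal by a mean-one log-normal factor (``tech_cv``).
Observations are dropped with a logistic probability that decreases with
log-intensity, mimicking intensity-dependent missingness at the detection
limit. Peptide counts per protein follow a shifted Poisson with a floor of
two peptides so the identification filter is satisfiable by design (the
floor is configurable to create sub-threshold proteins for filter tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .enrichment import PathwayAnnotation
from .errors import ConfigurationError, ValidationError

DEFAULT_GROUPS = ("CT", "PCP", "NIC", "PCPNIC")
DEFAULT_SEXES = ("M", "F")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters for the generator.

    Defaults reproduce the emulated study: 337 proteins, ~3594 expected
    peptides, 4 groups x 2 sexes x 4 pools x 3 technical replicates.
    """

    n_proteins: int = 337
    mean_peptides_per_protein: float = 10.7
    min_peptides_per_protein: int = 2
    groups: tuple[str, ...] = DEFAULT_GROUPS
    sexes: tuple[str, ...] = DEFAULT_SEXES
    n_pools: int = 4
    n_tech: int = 3
    base_abundance_log_mean: float = 11.5
    base_abundance_log_sd: float = 1.0
    ionization_log_sd: float = 1.0
    tech_cv: float = 0.10
    bio_cv: float = 0.15
    dropout_midpoint: float = 6.9
    dropout_slope: float = 1.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_proteins", "n_pools", "n_tech"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.min_peptides_per_protein < 1:
            raise ValidationError("min_peptides_per_protein must be >= 1")
        if self.mean_peptides_per_protein < self.min_peptides_per_protein:
            raise ValidationError(
                "mean_peptides_per_protein must be >= min_peptides_per_protein"
            )
        for name in ("tech_cv", "bio_cv", "base_abundance_log_sd",
                     "ionization_log_sd", "dropout_slope"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise ValidationError("groups must be non-empty and unique")
        if len(set(self.sexes)) != len(self.sexes) or not self.sexes:
            raise ValidationError("sexes must be non-empty and unique")


@dataclass(frozen=True)
class PlantedEffect:
    """Multiplicative deregulation of one protein in one group/sex.

    ``fold_change`` multiplies the protein's abundance in that group and sex
    relative to the first (control) group; values < 1 encode downregulation.
    ``protein`` is the integer protein index (< ``n_proteins``).
    """

    protein: int
    sex: str
    group: str
    fold_change: float

    def __post_init__(self):
        if not self.fold_change > 0:
            raise ValidationError(
                f"fold_change must be > 0, got {self.fold_change}"
            )


def protein_label(index: int) -> str:
    return f"P{index:04d}"


@dataclass
class GroundTruth:
    """Planted truth for a generated dataset.

    ``expected_markers[sex][group]`` holds the marker sets obtained by
    applying the exclusivity-refined marker set logic directly to the
    planted effects (deregulation = planted fold ratio exceeding
    ``fc_min``), computed here independently of the analysis modules.
    """

    config: SyntheticConfig
    effects: tuple[PlantedEffect, ...]
    protein_ids: tuple[str, ...]
    peptide_to_protein: dict[str, str]
    ionization: dict[str, float]
    base_abundance: dict[str, float]
    expected_markers: dict[str, dict[str, frozenset[str]]]
    n_dropped: int = 0
    fc_min: float = 1.5

    def effect_factor(self, protein_id: str, sex: str, group: str) -> float:
        idx = self.protein_ids.index(protein_id)
        for eff in self.effects:
            if eff.protein == idx and eff.sex == sex and eff.group == group:
                return eff.fold_change
        return 1.0

    def expected_de(self, sex: str, group_a: str, group_b: str) -> frozenset[str]:
        """Proteins whose planted fold ratio between two groups exceeds fc_min."""
        out = []
        for pid in self.protein_ids:
            fa = self.effect_factor(pid, sex, group_a)
            fb = self.effect_factor(pid, sex, group_b)
            ratio = max(fa, fb) / min(fa, fb)
            if ratio > self.fc_min:
                out.append(pid)
        return frozenset(out)

    def to_json(self, path) -> None:
        payload = {
            "effects": [
                {"protein": e.protein, "sex": e.sex, "group": e.group,
                 "fold_change": e.fold_change}
                for e in self.effects
            ],
            "protein_ids": list(self.protein_ids),
            "peptide_to_protein": self.peptide_to_protein,
            "ionization": self.ionization,
            "base_abundance": self.base_abundance,
            "expected_markers": {
                sex: {g: sorted(s) for g, s in per_group.items()}
                for sex, per_group in self.expected_markers.items()
            },
            "n_dropped": self.n_dropped,
            "fc_min": self.fc_min,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _mean_one_lognormal(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with E[X] = 1 and SD[X]/E[X] = cv."""
    sigma2 = np.log1p(cv * cv)
    return np.exp(rng.normal(-sigma2 / 2.0, np.sqrt(sigma2), size=shape))


def _expected_truth_markers(
    config: SyntheticConfig,
    effect_factor: np.ndarray,
    protein_ids: Sequence[str],
    fc_min: float,
) -> dict[str, dict[str, frozenset[str]]]:
    """Apply the marker set logic directly to the planted effect matrix.

    For each non-reference group g, a marker must be deregulated (fold ratio
    > fc_min) in every comparison involving g and, within each family of
    comparisons sharing a reference, exclusively in g's comparison. This is
    deliberately a standalone re-derivation, independent of the analysis
    modules, so parameter-recovery tests compare two separate routes.
    """
    groups = list(config.groups)
    pairs = [(groups[i], groups[j])
             for i in range(len(groups)) for j in range(i + 1, len(groups))]

    out: dict[str, dict[str, frozenset[str]]] = {}
    for s_idx, sex in enumerate(config.sexes):
        de: dict[frozenset, set[str]] = {}
        for ref, focal in pairs:
            fa = effect_factor[:, s_idx, groups.index(ref)]
            fb = effect_factor[:, s_idx, groups.index(focal)]
            ratio = np.maximum(fa, fb) / np.minimum(fa, fb)
            de[frozenset((ref, focal))] = {
                protein_ids[i] for i in np.nonzero(ratio > fc_min)[0]
            }
        per_group: dict[str, frozenset[str]] = {}
        for g in groups[1:]:
            marker: set[str] | None = None
            for other in groups:
                if other == g:
                    continue
                ref = other if groups.index(other) < groups.index(g) else g
                family = [p for p in de if ref in p]
                own = de[frozenset((g, other))]
                if groups.index(other) < groups.index(g) and len(family) > 1:
                    others_union: set[str] = set()
                    for p in family:
                        if p != frozenset((g, other)):
                            others_union |= de[p]
                    contrib = own - others_union
                else:
                    contrib = set(own)
                marker = contrib if marker is None else marker & contrib
            per_group[g] = frozenset(marker or set())
        out[sex] = per_group
    return out


def generate_dataset(
    config: SyntheticConfig = SyntheticConfig(),
    effects: Sequence[PlantedEffect] = (),
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format peptide intensity table plus its ground truth.

    One row per (peptide, sex, group, pool, tech) unless removed by the
    missingness model. Identical ``(config, effects, seed)`` give identical
    tables. ``seed`` overrides ``config.seed`` when given.

    Returns
    -------
    (table, truth)
        ``table`` has columns ``peptide_id, protein_id, sex, group, pool,
        tech, intensity``; ``truth`` records the planted effects, the
        peptide map, per-peptide ionization factors, expected marker sets
        and the number of dropped observations.
    """
    for eff in effects:
        if eff.group not in config.groups:
            raise ConfigurationError(f"effect references unknown group {eff.group!r}")
        if eff.sex not in config.sexes:
            raise ConfigurationError(f"effect references unknown sex {eff.sex!r}")
        if not 0 <= eff.protein < config.n_proteins:
            raise ConfigurationError(
                f"effect references protein index {eff.protein} outside "
                f"[0, {config.n_proteins})"
            )
    keys = [(e.protein, e.sex, e.group) for e in effects]
    if len(set(keys)) != len(keys):
        raise ConfigurationError("duplicate (protein, sex, group) in effects")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_prot = config.n_proteins
    n_sex, n_grp = len(config.sexes), len(config.groups)
    n_pool, n_tech = config.n_pools, config.n_tech

    extra = config.mean_peptides_per_protein - config.min_peptides_per_protein
    n_pep_per_prot = config.min_peptides_per_protein + rng.poisson(extra, n_prot)
    base = np.exp(rng.normal(config.base_abundance_log_mean,
                             config.base_abundance_log_sd, n_prot))

    protein_ids = tuple(protein_label(i) for i in range(n_prot))
    pep_protein_idx = np.repeat(np.arange(n_prot), n_pep_per_prot)
    n_pep = int(pep_protein_idx.size)
    pep_ordinal = np.concatenate([np.arange(k) for k in n_pep_per_prot])
    peptide_ids = np.array([
        f"{protein_ids[p]}.pep{j:02d}"
        for p, j in zip(pep_protein_idx, pep_ordinal)
    ], dtype=object)
    ionization = np.exp(rng.normal(0.0, config.ionization_log_sd, n_pep))

    effect_factor = np.ones((n_prot, n_sex, n_grp))
    for eff in effects:
        effect_factor[eff.protein,
                      config.sexes.index(eff.sex),
                      config.groups.index(eff.group)] = eff.fold_change

    bio = _mean_one_lognormal(rng, config.bio_cv, (n_prot, n_sex, n_grp, n_pool))
    # pool-level protein abundance: base x planted effect x biological noise
    pool_abund = base[:, None, None, None] * effect_factor[..., None] * bio

    tech = _mean_one_lognormal(rng, config.tech_cv,
                               (n_pep, n_sex, n_grp, n_pool, n_tech))
    intensity = (pool_abund[pep_protein_idx][..., None]
                 * ionization[:, None, None, None, None] * tech)

    total = intensity.size
    if config.dropout_slope > 0:
        p_drop = expit(-(np.log(intensity) - config.dropout_midpoint)
                       * config.dropout_slope)
        keep = rng.random(intensity.shape) >= p_drop
    else:
        keep = np.ones(intensity.shape, dtype=bool)
    n_dropped = int(total - keep.sum())

    pep_axis, sex_axis, grp_axis, pool_axis, tech_axis = np.nonzero(keep)
    table = pd.DataFrame({
        "peptide_id": peptide_ids[pep_axis],
        "protein_id": np.array(protein_ids, dtype=object)[pep_protein_idx[pep_axis]],
        "sex": np.array(config.sexes, dtype=object)[sex_axis],
        "group": np.array(config.groups, dtype=object)[grp_axis],
        "pool": pool_axis + 1,
        "tech": tech_axis + 1,
        "intensity": intensity[keep],
    })

    truth = GroundTruth(
        config=config,
        effects=tuple(effects),
        protein_ids=protein_ids,
        peptide_to_protein={
            pid: protein_ids[p] for pid, p in zip(peptide_ids, pep_protein_idx)
        },
        ionization={pid: float(f) for pid, f in zip(peptide_ids, ionization)},
        base_abundance={protein_ids[i]: float(base[i]) for i in range(n_prot)},
        expected_markers=_expected_truth_markers(
            config, effect_factor, protein_ids, fc_min=1.5),
        n_dropped=n_dropped,
    )
    return table, truth


def generate_interaction_edges(
    truth: GroundTruth,
    p_within: float,
    p_between: float,
    confidence_range: tuple[float, float] = (0.4, 1.0),
    seed: int = 0,
    communities: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Random undirected weighted edges among the truth's proteins.

    ``communities`` maps protein id -> community label; pairs within one
    community connect with probability ``p_within``, across communities with
    ``p_between`` (offline stand-in for a STRING edge export). Confidences
    are uniform in ``confidence_range``. No self-loops, no duplicate
    unordered pairs; fixed seed gives a byte-identical edge file.
    """
    if not (0 <= p_between <= p_within <= 1):
        raise ValidationError(
            f"need 0 <= p_between <= p_within <= 1, got "
            f"p_between={p_between}, p_within={p_within}"
        )
    lo, hi = confidence_range
    if not (0 <= lo <= hi <= 1):
        raise ValidationError(f"confidence_range must be within [0, 1], got {confidence_range}")

    proteins = sorted(truth.protein_ids)
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in enumerate(proteins):
        for b in proteins[i + 1:]:
            if communities is None:
                same = True
            else:
                la, lb = communities.get(a), communities.get(b)
                same = la is not None and la == lb
            p = p_within if same else p_between
            u = rng.random()
            conf = lo + (hi - lo) * rng.random()
            if u < p:
                rows.append((a, b, round(float(conf), 3)))
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"])


def generate_pathway_annotation(
    truth: GroundTruth,
    n_pathways: int,
    density: float,
    seed: int = 0,
    ensure_nonempty: bool = True,
) -> PathwayAnnotation:
    """Random pathway membership over the truth's proteins.

    Each (pathway, protein) membership is Bernoulli(``density``); proteins
    may belong to several pathways. With ``ensure_nonempty`` a random member
    is added to otherwise-empty pathways; without it, empty pathways are
    dropped (so density 0 yields an empty annotation).
    """
    if n_pathways < 1:
        raise ValidationError("n_pathways must be >= 1")
    if not 0 <= density <= 1:
        raise ValidationError(f"density must be in [0, 1], got {density}")
    proteins = np.array(sorted(truth.protein_ids))
    rng = np.random.default_rng(seed)
    member = rng.random((n_pathways, proteins.size)) < density
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_pathways):
        members = set(proteins[member[i]])
        if not members and ensure_nonempty:
            members = {proteins[rng.integers(proteins.size)]}
        if members:
            pathways[f"PW{i:04d}"] = (f"synthetic pathway {i}", frozenset(members))
    return PathwayAnnotation(pathways)


def null_config(**overrides) -> SyntheticConfig:
    """Convenience: default design with no dropout (for null simulations)."""
    cfg = replace(SyntheticConfig(), dropout_slope=0.0)
    return replace(cfg, **overrides) if overrides else cfg
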