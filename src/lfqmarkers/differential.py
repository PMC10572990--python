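"""Pairwise differential expression with the CV / fold-change / ANOVA cascade.

Each comparison contrasts two exposure groups within one sex on pool-level
Hi3 abundances (n = 4 biological pools per condition by design). A protein
is called deregulated only if it passes, in order:

1. presence/coexistence — observed in at least ``presence_min`` of
   ``presence_of`` pools in *both* conditions (default 3 of 4);
2. reproducibility — coefficient of variation (sample SD / mean over pool
   values) at most ``cv_max`` in both conditions (default 30%);
3. effect size — fold change (larger condition mean / smaller condition
   mean) strictly greater than ``fc_min`` (default 1.5);
4. significance — one-way ANOVA on the pool values with p strictly below
   ``alpha`` (default 0.05).

No multiple-testing correction is applied to the calls; a Benjamini–
Hochberg column is reported for transparency in the exported table.
Statistics run on raw (untransformed) abundances by default, matching the
Progenesis-style procedure; a log-scale option is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

FILTER_ORDER = ("presence", "cv", "fold_change", "anova")


@dataclass(frozen=True)
class DEThresholds:
    """Filter-cascade thresholds (defaults are the standard cascade)."""

    cv_max: float = 0.30
    fc_min: float = 1.5
    alpha: float = 0.05
    presence_min: int = 3
    presence_of: int = 4

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_min < 1:
            raise ValidationError(f"fc_min must be >= 1, got {self.fc_min}")
        if not self.cv_max > 0:
            raise ValidationError(f"cv_max must be > 0, got {self.cv_max}")
        if self.presence_min > self.presence_of:
            raise ValidationError("presence_min must be <= presence_of")


@dataclass
class ProteinComparisonRecord:
    """Per-protein statistics for one pairwise comparison.

    ``direction`` is for the focal group ("up" iff focal mean > reference
    mean). ``stats_ok`` is False when either condition has fewer than two
    pools with values, in which case CV/ANOVA are undefined (None) rather
    than an error.
    """

    protein_id: str
    n_ref: int
    n_focal: int
    mean_ref: float | None
    mean_focal: float | None
    cv_ref: float | None
    cv_focal: float | None
    fold_change: float | None
    f_stat: float | None
    p_value: float | None
    direction: str | None
    stats_ok: bool
    filter_failed: str | None = None
    is_de: bool = False


@dataclass
class ComparisonResult:
    """One pairwise group comparison within one sex."""

    sex: str
    focal: str
    reference: str
    thresholds: DEThresholds
    records: list[ProteinComparisonRecord] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.focal} vs {self.reference}"

    @property
    def de_set(self) -> frozenset[str]:
        return frozenset(r.protein_id for r in self.records if r.is_de)

    @property
    def directions(self) -> dict[str, str]:
        """direction of the focal group for every DE protein."""
        return {r.protein_id: r.direction for r in self.records if r.is_de}

    def to_frame(self) -> pd.DataFrame:
        """Per-comparison export table, with a BH-adjusted p column
        (reported only; never used for the DE calls)."""
        frame = pd.DataFrame([
            {
                "protein_id": r.protein_id,
                "n_present_ref": r.n_ref,
                "n_present_focal": r.n_focal,
                "mean_ref": r.mean_ref,
                "mean_focal": r.mean_focal,
                "cv_ref": r.cv_ref,
                "cv_focal": r.cv_focal,
                "fold_change": r.fold_change,
                "F": r.f_stat,
                "p": r.p_value,
                "direction": r.direction,
                "filter_failed": r.filter_failed,
                "is_DE": r.is_de,
            }
            for r in self.records
        ])
        if len(frame):
            from statsmodels.stats.multitest import multipletests

            mask = frame["p"].notna()
            frame["p_bh"] = np.nan
            if mask.any():
                frame.loc[mask, "p_bh"] = multipletests(
                    frame.loc[mask, "p"], method="fdr_bh")[1]
        return frame


def _two_group_anova(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way ANOVA with two levels; F and p.

    Degenerate within-group variance is resolved explicitly: equal means
    give (F=0, p=1); unequal means with zero within-group variance give
    (F=inf, p=0).
    """
    n_a, n_b = a.size, b.size
    mean_a, mean_b = a.mean(), b.mean()
    grand = (a.sum() + b.sum()) / (n_a + n_b)
    ssb = n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    ssw = ((a - mean_a) ** 2).sum() + ((b - mean_b) ** 2).sum()
    df_w = n_a + n_b - 2
    if ssw == 0:
        if math.isclose(mean_a, mean_b, rel_tol=0, abs_tol=0):
            return 0.0, 1.0
        return math.inf, 0.0
    f = ssb / (ssw / df_w)
    return float(f), float(stats.f.sf(f, 1, df_w))


def _cv(values: np.ndarray) -> float | None:
    if values.size < 2:
        return None
    m = values.mean()
    if m == 0:
        return None
    return float(values.std(ddof=1) / m)


def protein_stats(
    pools: pd.DataFrame,
    sex: str,
    group_ref: str,
    group_focal: str,
    use_log: bool = False,
) -> list[ProteinComparisonRecord]:
    """Per-protein statistics for ``group_focal`` vs ``group_ref``.

    One record per protein observed in at least one pool of either
    condition. With ``use_log``, the ANOVA runs on natural-log abundances
    and the fold change is the ratio of geometric means; reported means and
    CVs stay on the raw scale either way.
    """
    present_groups = set(pools.loc[pools["sex"] == sex, "group"].unique())
    for g in (group_ref, group_focal):
        if g not in present_groups:
            raise ConfigurationError(
                f"group {g!r} has no pool-level data for sex {sex!r}"
            )
    if group_ref == group_focal:
        raise ConfigurationError("focal and reference groups must differ")

    sub = pools[(pools["sex"] == sex)
                & pools["group"].isin([group_ref, group_focal])]
    records: list[ProteinComparisonRecord] = []
    for protein_id, part in sub.groupby("protein_id", sort=True):
        ref = part.loc[part["group"] == group_ref, "abundance"].to_numpy(float)
        foc = part.loc[part["group"] == group_focal, "abundance"].to_numpy(float)
        mean_ref = float(ref.mean()) if ref.size else None
        mean_foc = float(foc.mean()) if foc.size else None
        stats_ok = ref.size >= 2 and foc.size >= 2

        fold = direction = f_stat = p_value = None
        if ref.size and foc.size:
            if use_log:
                gm_ref = float(np.exp(np.log(ref).mean()))
                gm_foc = float(np.exp(np.log(foc).mean()))
                fold = max(gm_ref, gm_foc) / min(gm_ref, gm_foc)
            else:
                fold = max(mean_ref, mean_foc) / min(mean_ref, mean_foc)
            direction = "up" if mean_foc > mean_ref else "down"
        if stats_ok:
            if use_log:
                f_stat, p_value = _two_group_anova(np.log(ref), np.log(foc))
            else:
                f_stat, p_value = _two_group_anova(ref, foc)

        records.append(ProteinComparisonRecord(
            protein_id=str(protein_id),
            n_ref=int(ref.size),
            n_focal=int(foc.size),
            mean_ref=mean_ref,
            mean_focal=mean_foc,
            cv_ref=_cv(ref),
            cv_focal=_cv(foc),
            fold_change=fold,
            f_stat=f_stat,
            p_value=p_value,
            direction=direction,
            stats_ok=stats_ok,
        ))
    return records


def pairwise_compare(
    pools: pd.DataFrame,
    sex: str,
    focal: str,
    reference: str,
    thresholds: DEThresholds = DEThresholds(),
    use_log: bool = False,
) -> ComparisonResult:
    """Apply the four-filter cascade to one pairwise comparison.

    Filters run in order (presence, CV, fold change, ANOVA); each record
    retains the first filter that eliminated it. The DE set is the records
    passing all four.
    """
    records = protein_stats(pools, sex, group_ref=reference,
                            group_focal=focal, use_log=use_log)
    t = thresholds
    for rec in records:
        if rec.n_ref < t.presence_min or rec.n_focal < t.presence_min:
            rec.filter_failed = "presence"
            continue
        if rec.cv_ref is None or rec.cv_focal is None:
            rec.filter_failed = "cv"
            continue
        if rec.cv_ref > t.cv_max or rec.cv_focal > t.cv_max:
            rec.filter_failed = "cv"
            continue
        if not (rec.fold_change is not None and rec.fold_change > t.fc_min):
            rec.filter_failed = "fold_change"
            continue
        if not (rec.p_value is not None and rec.p_value < t.alpha):
            rec.filter_failed = "anova"
            continue
        rec.is_de = True
    return ComparisonResult(sex=sex, focal=focal, reference=reference,
                            thresholds=thresholds, records=records)
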