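"""Identification filtering and Hi3 (Top3) protein quantification.

The entry point of the analysis is a long-format peptide intensity table
(one row per observed peptide per LC-MS run; missing observations are
absent rows, never zeros). Proteins are kept only if identified by at least
two distinct peptides and observed in at least two runs. A protein's
relative abundance in a run is the arithmetic mean of its three most
intense peptides in that run (Hi3/Top3); technical replicates are then
averaged to pool level, making the biological pool the unit of inference
for the downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

PEPTIDE_COLUMNS = ("peptide_id", "protein_id", "sex", "group", "pool", "tech",
                   "intensity")
RUN_COLUMNS = ("sex", "group", "pool", "tech")
HI3_TOP_N = 3


def validate_peptide_table(table: pd.DataFrame) -> None:
    """Schema checks; raises ValidationError naming the offending rows."""
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing columns: {', '.join(missing)}")
    if len(table) == 0:
        raise ValidationError("empty peptide table")
    bad = table.index[~(table["intensity"] >= 0) | ~np.isfinite(table["intensity"])]
    if len(bad):
        raise ValidationError(
            f"non-finite or negative intensity at rows {list(bad[:5])}"
        )
    n_prot = table.groupby("peptide_id")["protein_id"].nunique()
    multi = n_prot.index[n_prot > 1]
    if len(multi):
        raise ValidationError(
            f"peptides mapped to multiple proteins: {list(multi[:5])}"
        )
    dup = table.duplicated(subset=["peptide_id", *RUN_COLUMNS])
    if dup.any():
        raise ValidationError(
            f"duplicate (peptide, run) rows at {list(table.index[dup][:5])}"
        )


def filter_identifications(
    peptides: pd.DataFrame,
    min_peptides: int = 2,
    min_runs: int = 2,
) -> pd.DataFrame:
    """Keep proteins with >= ``min_peptides`` distinct peptides observed in
    >= ``min_runs`` distinct runs (any peptide).

    The run count is per protein, not per peptide. Idempotent; the output
    row set is a subset of the input's.
    """
    validate_peptide_table(peptides)
    run_code = peptides.groupby(list(RUN_COLUMNS), sort=False).ngroup()
    per_protein = peptides.assign(_run=run_code).groupby("protein_id").agg(
        n_peptides=("peptide_id", "nunique"),
        n_runs=("_run", "nunique"),
    )
    kept = per_protein.index[
        (per_protein["n_peptides"] >= min_peptides)
        & (per_protein["n_runs"] >= min_runs)
    ]
    return peptides[peptides["protein_id"].isin(kept)].reset_index(drop=True)


def hi3_quantify(peptides: pd.DataFrame, top_n: int = HI3_TOP_N) -> pd.DataFrame:
    """Run-level Hi3 abundances.

    For each (protein, run) with at least one observed peptide, abundance is
    the arithmetic mean of the ``min(top_n, available)`` highest peptide
    intensities in that run; cells with no observed peptide stay absent.

    Returns a run-level protein abundance table with columns
    ``protein_id, sex, group, pool, tech, abundance, n_peptides_used``.
    """
    keys = ["protein_id", *RUN_COLUMNS]
    if len(peptides) == 0:
        out = pd.DataFrame(columns=[*keys, "abundance", "n_peptides_used"])
        out.attrs["level"] = "run"
        return out
    validate_peptide_table(peptides)
    top = (
        peptides.sort_values("intensity", ascending=False, kind="mergesort")
        .groupby(keys, sort=False)
        .head(top_n)
    )
    out = (
        top.groupby(keys, sort=False)["intensity"]
        .agg(abundance="mean", n_peptides_used="count")
        .reset_index()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["level"] = "run"
    return out


def aggregate_technical(run_table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates to pool level.

    A pool is present if the protein was observed in at least one of its
    technical replicates; absent pools yield no row. Output columns:
    ``protein_id, sex, group, pool, abundance, n_tech_used,
    n_peptides_used`` (max over the contributing runs).
    """
    keys = ["protein_id", "sex", "group", "pool"]
    if len(run_table) == 0:
        out = pd.DataFrame(
            columns=[*keys, "abundance", "n_tech_used", "n_peptides_used"])
        out.attrs["level"] = "pool"
        return out
    out = (
        run_table.groupby(keys, sort=False)
        .agg(
            abundance=("abundance", "mean"),
            n_tech_used=("abundance", "count"),
            n_peptides_used=("n_peptides_used", "max"),
        )
        .reset_index()
        .sort_values(keys, kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["level"] = "pool"
    return out
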