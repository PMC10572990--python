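"""Shared fixtures: small peptide tables and fabricated comparison results."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lfqmarkers.differential import (ComparisonResult, DEThresholds,
                                     ProteinComparisonRecord)


def make_peptide_table(rows):
    """rows: (peptide_id, protein_id, sex, group, pool, tech, intensity)."""
    return pd.DataFrame(
        rows,
        columns=["peptide_id", "protein_id", "sex", "group", "pool", "tech",
                 "intensity"],
    )


def random_peptide_table(rng, n_proteins=10, n_peptides_each=4,
                         sexes=("M",), groups=("CT", "PCPNIC"),
                         n_pools=2, n_tech=2, p_missing=0.2):
    """Random long table with some observations missing at random."""
    rows = []
    for p in range(n_proteins):
        prot = f"P{p:03d}"
        for j in range(n_peptides_each):
            pep = f"{prot}.pep{j}"
            for sex in sexes:
                for group in groups:
                    for pool in range(1, n_pools + 1):
                        for tech in range(1, n_tech + 1):
                            if rng.random() < p_missing:
                                continue
                            rows.append((pep, prot, sex, group, pool, tech,
                                         float(rng.uniform(1, 1000))))
    return make_peptide_table(rows)


def make_result(sex, focal, reference, de, non_de=(),
                thresholds=None) -> ComparisonResult:
    """Fabricate a ComparisonResult: ``de`` maps protein -> 'up'/'down'."""
    records = []
    for protein, direction in de.items():
        records.append(ProteinComparisonRecord(
            protein_id=protein, n_ref=4, n_focal=4, mean_ref=100.0,
            mean_focal=300.0 if direction == "up" else 30.0,
            cv_ref=0.05, cv_focal=0.05, fold_change=3.0, f_stat=50.0,
            p_value=1e-4, direction=direction, stats_ok=True, is_de=True))
    for protein in non_de:
        records.append(ProteinComparisonRecord(
            protein_id=protein, n_ref=4, n_focal=4, mean_ref=100.0,
            mean_focal=101.0, cv_ref=0.05, cv_focal=0.05, fold_change=1.01,
            f_stat=0.1, p_value=0.8, direction="up", stats_ok=True,
            filter_failed="fold_change"))
    return ComparisonResult(sex=sex, focal=focal, reference=reference,
                            thresholds=thresholds or DEThresholds(),
                            records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-design synthetic dataset shared across tests."""
    from lfqmarkers import SyntheticConfig, generate_dataset

    return generate_dataset(SyntheticConfig(), seed=7)
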