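"""Shared fixtures: a 5-feature / 3-sample toy peak table with known answers.

Features F1-F3 and F5 have exactly proportional intensity profiles (pairwise
Pearson 1.0); F4 is exactly anti-proportional (-1.0).  F2 sits one 13C above
F1 and F3 one Na-for-H exchange above F1; F5 co-elutes but matches no
reference delta; F4 elutes far away.  With threshold 0.9, an RT window of
6 s and a mass tolerance of 0.005 Da the expected partition is
{F1, F2, F3}, {F4}, {F5} with F1 as the multi-member representative.
"""

from __future__ import annotations

import pandas as pd
import pytest

from acorf import DeltaEntry, DeltaList, FeatureTable, IntensityMatrix

TOY_IDS = ["F1", "F2", "F3", "F4", "F5"]
TOY_PROFILES = {
    "F1": [1000.0, 2000.0, 3000.0],
    "F2": [110.0, 220.0, 330.0],
    "F3": [500.0, 1000.0, 1500.0],
    "F4": [3000.0, 2000.0, 1000.0],
    "F5": [400.0, 800.0, 1200.0],
}
TOY_MZ = {"F1": 180.0634, "F2": 181.0667, "F3": 202.0453, "F4": 250.0500, "F5": 300.1000}
TOY_RT = {"F1": 120.0, "F2": 120.5, "F3": 121.0, "F4": 400.0, "F5": 119.0}


@pytest.fixture
def toy_matrix() -> IntensityMatrix:
    values = pd.DataFrame(
        [TOY_PROFILES[f] for f in TOY_IDS],
        index=TOY_IDS,
        columns=["S1", "S2", "S3"],
    )
    return IntensityMatrix(values)


@pytest.fixture
def toy_table() -> FeatureTable:
    meta = pd.DataFrame(
        {
            "name": TOY_IDS,
            "mz": [f"{TOY_MZ[f]:.4f}" for f in TOY_IDS],
            "rt": [f"{TOY_RT[f]:.1f}" for f in TOY_IDS],
            "note": [f"feature {f}" for f in TOY_IDS],
        }
    )
    return FeatureTable(meta, id_column="name", mz_column="mz", rt_column="rt")


@pytest.fixture
def toy_deltas() -> DeltaList:
    return DeltaList([DeltaEntry("isotope_13C", 1.00336), DeltaEntry("Na-H", 21.98194)])


@pytest.fixture
def toy_files(tmp_path, toy_matrix, toy_table, toy_deltas):
    """The toy dataset written out as the three input files + delta list."""
    dm = tmp_path / "dataMatrix.tsv"
    vm = tmp_path / "variableMetadata.tsv"
    dl = tmp_path / "deltas.tsv"
    toy_matrix.values.to_csv(dm, sep="\t", index_label="feature")
    toy_table.data.to_csv(vm, sep="\t", index=False)
    dl.write_text("".join(f"{e.label}\t{e.delta}\n" for e in toy_deltas))
    return {"data_matrix": dm, "variable_metadata": vm, "delta_list": dl, "dir": tmp_path}
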