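"""In-memory containers for the peak-table inputs and the mass-delta reference list.

The tool follows the two-file peak-table convention used by many metabolomics
workflows: a *data matrix* of intensities (features x samples) and a *variable
metadata* table of per-feature descriptors (m/z, retention time, anything else),
joined on a unique feature identifier.  Pairwise evidence for grouping comes from
a square *similarity matrix* over the same identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "IntensityMatrix",
    "SimilarityMatrix",
    "DeltaEntry",
    "DeltaList",
]


@dataclass
class FeatureTable:
    """Per-feature metadata with named m/z and retention-time bindings.

    ``data`` keeps every original column verbatim (as strings) so that a
    read -> write round trip is lossless; m/z and RT are parsed into float
    Series on demand via the bound column names.

    Parameters
    ----------
    data
        Original table, first column = feature identifier, all cells as read.
    id_column
        Name of the identifier column (the table's first column).
    mz_column, rt_column
        Resolved names of the m/z and RT columns, or ``None`` if unbound.
    """

    data: pd.DataFrame
    id_column: str
    mz_column: str | None = None
    rt_column: str | None = None

    def __post_init__(self) -> None:
        ids = self.data[self.id_column].astype(str)
        if (ids.str.len() == 0).any():
            raise ValueError("feature identifiers must be non-empty")
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate feature identifiers: {dup}")

    @property
    def feature_ids(self) -> list[str]:
        return self.data[self.id_column].astype(str).tolist()

    def _numeric(self, column: str | None, what: str) -> pd.Series:
        if column is None:
            raise ValueError(f"no {what} column bound to this table")
        values = pd.to_numeric(self.data[column], errors="coerce")
        values.index = self.feature_ids
        return values

    @property
    def mz(self) -> pd.Series:
        """m/z per feature (Da), indexed by feature id."""
        return self._numeric(self.mz_column, "m/z")

    @property
    def rt(self) -> pd.Series:
        """Retention time per feature, in the units of the stored column."""
        return self._numeric(self.rt_column, "retention time")


@dataclass
class IntensityMatrix:
    """Features x samples intensity matrix (non-negative or missing)."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def mean_intensity(self) -> pd.Series:
        """Arithmetic mean intensity per feature over non-missing samples."""
        return self.values.mean(axis=1, skipna=True)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity between features; diagonal is ignored."""

    values: pd.DataFrame  # square, index == columns == feature ids

    SYMMETRY_TOL = 1e-6

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1]:
            raise ValueError(f"similarity matrix is non-square: {v.shape[0]}x{v.shape[1]}")
        if list(v.index) != list(v.columns):
            raise ValueError("similarity matrix row and column identifiers differ")
        arr = v.to_numpy(dtype=float)
        asym = np.abs(arr - arr.T)
        asym = np.where(np.isnan(asym), 0.0, asym)
        worst = float(asym.max()) if asym.size else 0.0
        if worst > self.SYMMETRY_TOL:
            i, j = np.unravel_index(np.nanargmax(asym), asym.shape)
            raise ValueError(
                f"similarity matrix is asymmetric: worst cell "
                f"({v.index[i]}, {v.columns[j]}) differs by {worst:.3g}"
            )

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    def get(self, a: str, b: str) -> float:
        return float(self.values.at[a, b])


@dataclass(frozen=True)
class DeltaEntry:
    """One reference mass difference (label, delta in Da)."""

    label: str
    delta: float


@dataclass
class DeltaList:
    """Labelled reference mass differences for isotopes, adducts and fragments."""

    entries: list[DeltaEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate delta labels: {dup}")
        for e in self.entries:
            if not np.isfinite(e.delta) or e.delta <= 0:
                raise ValueError(f"delta for {e.label!r} must be strictly positive, got {e.delta}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def best_match(self, observed_delta: float, tol: float) -> DeltaEntry | None:
        """Closest entry within ``tol`` Da of an observed mass difference.

        Ties on the deviation are broken by list order.  Returns ``None``
        when no entry fits.
        """
        best: DeltaEntry | None = None
        best_dev = np.inf
        for e in self.entries:
            dev = abs(observed_delta - e.delta)
            if dev <= tol and dev < best_dev:
                best, best_dev = e, dev
        return best
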