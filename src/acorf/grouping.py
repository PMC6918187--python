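"""Analytical-correlation grouping: pair selection, RT and mass gates, groups.

The algorithm walks every unordered feature pair through up to three
criteria:

1. similarity strictly greater than a user threshold (mandatory);
2. retention times equal within ``rt_delta`` (optional, recommended);
3. absolute m/z difference matching a reference list of isotope/adduct/
   fragment mass deltas within ``mass_tol`` Da (optional, requires the RT
   gate — a mass match is only chemically meaningful for co-eluting ions).

Pairs surviving every enabled gate are edges of an undirected graph over the
features; the analytical-correlation groups are its connected components, so
A-B and B-C validated puts A, B and C together even when A-C fails a gate.
Features with no validated edge form singleton groups and count toward group
totals.  Group numbers are consecutive integers in order of first member
appearance in the feature table.

Thresholds: the similarity cut is strict (``>``); the RT and mass tolerances
are inclusive (``<=``).  Similarity is compared signed — anti-correlated
pairs never group unless ``absolute_similarity`` is set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .tables import DeltaList, FeatureTable, IntensityMatrix, SimilarityMatrix

__all__ = [
    "Parameters",
    "CandidatePair",
    "Grouping",
    "FiltrationResult",
    "REP_METHODS",
    "select_pairs",
    "rt_gate",
    "mass_gate",
    "build_groups",
    "run_filtration",
]

logger = logging.getLogger(__name__)

REP_METHODS = (
    "highest_intensity",
    "highest_mass",
    "mass2_x_intensity",
    "highest_mass_in_top_n",
)


@dataclass(frozen=True)
class Parameters:
    """Run parameters.

    Attributes
    ----------
    cor_threshold
        Similarity cutoff; pairs must exceed it strictly.
    rt_delta
        RT tolerance in the units of the RT column; ``None`` disables the
        RT gate (and with it the mass gate).
    mass_tol
        Tolerance in Da for matching an observed mass difference against
        the delta list; the mass gate is active when a delta list is given.
    rep_method
        One of ``REP_METHODS``.
    top_n
        Size of the intensity top-list for ``highest_mass_in_top_n``.
    absolute_similarity
        Compare the magnitude of s instead of signed s (default off).
    """

    cor_threshold: float
    rt_delta: float | None = None
    mass_tol: float | None = None
    rep_method: str = "highest_intensity"
    top_n: int | None = None
    absolute_similarity: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.cor_threshold):
            raise ValueError("cor_threshold must be finite")
        if self.rt_delta is not None and self.rt_delta < 0:
            raise ValueError("rt_delta must be >= 0")
        if self.mass_tol is not None:
            if self.mass_tol < 0:
                raise ValueError("mass_tol must be >= 0")
            if self.rt_delta is None:
                raise ValueError("the mass gate requires the RT gate (set rt_delta)")
        if self.rep_method not in REP_METHODS:
            raise ValueError(f"rep_method must be one of {REP_METHODS}, got {self.rep_method!r}")
        if self.rep_method == "highest_mass_in_top_n":
            if self.top_n is None:
                raise ValueError("top_n is required for rep_method='highest_mass_in_top_n'")
            if self.top_n < 1:
                raise ValueError("top_n must be >= 1")
        elif self.top_n is not None:
            raise ValueError("top_n is only meaningful for rep_method='highest_mass_in_top_n'")


@dataclass(frozen=True)
class CandidatePair:
    """An unordered feature pair that passed the similarity threshold."""

    id_a: str
    id_b: str
    similarity: float
    rt_pass: bool = False
    delta_label: str | None = None


@dataclass
class Grouping:
    """A total partition of the features into analytical-correlation groups."""

    assignment: dict[str, int]  # feature id -> group id (1-based, appearance order)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        """Group id -> member ids, members in input feature order."""
        out: dict[int, list[str]] = {}
        for fid, gid in self.assignment.items():
            out.setdefault(gid, []).append(fid)
        return out

    def group_sizes(self) -> dict[int, int]:
        return {g: len(m) for g, m in self.members().items()}


@dataclass
class FiltrationResult:
    """Pipeline output: the grouping plus the pair list after each gate."""

    grouping: Grouping
    selected_pairs: list[CandidatePair]
    rt_pairs: list[CandidatePair] | None = None
    mass_pairs: list[CandidatePair] | None = None
    validated_pairs: list[CandidatePair] = field(default_factory=list)


def select_pairs(
    similarity: SimilarityMatrix,
    threshold: float,
    absolute: bool = False,
) -> list[CandidatePair]:
    """All unordered pairs with similarity strictly above the threshold.

    Missing similarities are never selected.  Pair order follows the row
    order of the similarity matrix (upper triangle).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    ids = similarity.ids
    arr = similarity.values.to_numpy(dtype=float)
    cmp = np.abs(arr) if absolute else arr
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = cmp[iu, ju] > threshold  # NaN compares False
    return [
        CandidatePair(ids[i], ids[j], float(arr[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]


def _require(series: pd.Series, fid: str, what: str) -> float:
    try:
        v = float(series[fid])
    except KeyError:
        raise ValueError(f"feature {fid!r} missing from the metadata table") from None
    if np.isnan(v):
        raise ValueError(f"feature {fid!r} has no {what} value")
    return v


def rt_gate(
    pairs: list[CandidatePair],
    table: FeatureTable,
    rt_delta: float,
) -> list[CandidatePair]:
    """Keep pairs whose retention times agree within ``rt_delta`` (inclusive)."""
    rt = table.rt
    kept: list[CandidatePair] = []
    for p in pairs:
        rt_a = _require(rt, p.id_a, "retention time")
        rt_b = _require(rt, p.id_b, "retention time")
        if abs(rt_a - rt_b) <= rt_delta:
            kept.append(replace(p, rt_pass=True))
    logger.info("RT gate: %d of %d pairs kept (rt_delta=%g)", len(kept), len(pairs), rt_delta)
    return kept


def mass_gate(
    pairs: list[CandidatePair],
    table: FeatureTable,
    deltas: DeltaList,
    mass_tol: float,
) -> list[CandidatePair]:
    """Keep RT-validated pairs whose m/z difference matches a reference delta.

    A pair is kept iff ``| |mz_a - mz_b| - delta | <= mass_tol`` for some
    entry; the closest entry labels the pair (list order breaks exact ties).
    """
    if len(deltas) == 0:
        raise ValueError("the mass gate needs a non-empty delta list")
    mz = table.mz
    kept: list[CandidatePair] = []
    for p in pairs:
        mz_a = _require(mz, p.id_a, "m/z")
        mz_b = _require(mz, p.id_b, "m/z")
        entry = deltas.best_match(abs(mz_a - mz_b), mass_tol)
        if entry is not None:
            kept.append(replace(p, delta_label=entry.label))
    logger.info("mass gate: %d of %d pairs kept (mass_tol=%g Da)", len(kept), len(pairs), mass_tol)
    return kept


def build_groups(validated: list[CandidatePair], all_ids: list[str]) -> Grouping:
    """Connected components of the validated-pair graph over ``all_ids``.

    Features without any validated edge become singleton groups.  Group ids
    are consecutive integers assigned in order of first member appearance
    in ``all_ids``.
    """
    known = set(all_ids)
    for p in validated:
        missing = {p.id_a, p.id_b} - known
        if missing:
            raise ValueError(f"pair references unknown feature(s): {sorted(missing)}")
    graph = nx.Graph()
    graph.add_nodes_from(all_ids)
    graph.add_edges_from((p.id_a, p.id_b) for p in validated)
    component_of: dict[str, int] = {}
    for k, comp in enumerate(nx.connected_components(graph)):
        for fid in comp:
            component_of[fid] = k
    assignment: dict[str, int] = {}
    relabel: dict[int, int] = {}
    for fid in all_ids:
        comp = component_of[fid]
        if comp not in relabel:
            relabel[comp] = len(relabel) + 1
        assignment[fid] = relabel[comp]
    return Grouping(assignment)


def run_filtration(
    table: FeatureTable,
    intensities: IntensityMatrix | None,
    similarity: SimilarityMatrix,
    params: Parameters,
    deltas: DeltaList | None = None,
) -> FiltrationResult:
    """Execute the full gate cascade and form the groups.

    ``intensities`` is only needed downstream (representative choice) and may
    be ``None`` here; when given, its feature ids are cross-checked.  The RT
    gate runs when ``params.rt_delta`` is set; the mass gate when ``deltas``
    is given (which requires ``params.mass_tol`` and the RT gate).
    """
    ids = table.feature_ids
    _check_id_cover("similarity matrix", similarity.ids, ids)
    if intensities is not None:
        _check_id_cover("data matrix", intensities.feature_ids, ids)
    if deltas is not None and params.mass_tol is None:
        raise ValueError("a delta list was given but mass_tol is unset")
    if deltas is not None and params.rt_delta is None:
        raise ValueError("the mass gate requires the RT gate (set rt_delta)")

    selected = select_pairs(similarity, params.cor_threshold, params.absolute_similarity)
    logger.info(
        "similarity threshold %g: %d pair(s) selected", params.cor_threshold, len(selected)
    )
    current = selected
    rt_pairs = None
    mass_pairs = None
    if params.rt_delta is not None:
        rt_pairs = rt_gate(current, table, params.rt_delta)
        current = rt_pairs
    if deltas is not None:
        mass_pairs = mass_gate(current, table, deltas, params.mass_tol)
        current = mass_pairs
    grouping = build_groups(current, ids)
    logger.info("formed %d group(s) over %d feature(s)", grouping.n_groups, len(ids))
    return FiltrationResult(
        grouping=grouping,
        selected_pairs=selected,
        rt_pairs=rt_pairs,
        mass_pairs=mass_pairs,
        validated_pairs=current,
    )


def _check_id_cover(what: str, available: list[str], needed: list[str]) -> None:
    missing = [fid for fid in needed if fid not in set(available)]
    if missing:
        shown = missing[:10]
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise ValueError(f"{what} is missing feature id(s): {shown}{more}")
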