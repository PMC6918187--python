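"""Representative-ion choice, keep/delete flags and annotation columns.

One feature per group is promoted to *representative* (the quantifier used
downstream instead of the whole group), chosen by one of four methods:

1. ``highest_intensity`` — argmax of the mean intensity across samples;
2. ``highest_mass`` — argmax m/z;
3. ``mass2_x_intensity`` — argmax of m/z^2 x mean intensity, a compromise
   favouring heavy, well-detected species;
4. ``highest_mass_in_top_n`` — argmax m/z among the ``top_n`` members with
   highest mean intensity (useful for GC-MS fragment-rich spectra).

Ties inside any argmax break toward higher m/z, then lexicographically
smaller feature id, so results are deterministic.

Five result columns are appended to the metadata table: the group number,
the within-group isotope/adduct/fragment annotations, the keep flag
(``ACorF_filter``: 1 = conserve, 0 = delete), the representative id (column
named after the method) and the annotation of each member relative to its
group's representative.  Singleton rows keep their group number and flag 1
but show ``-`` in the annotation cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grouping import REP_METHODS, CandidatePair, Grouping
from .tables import DeltaList, FeatureTable, IntensityMatrix

__all__ = [
    "choose_representative",
    "assign_filter_flags",
    "annotate_within_group",
    "annotate_vs_representative",
    "assemble_output",
    "annotate",
]

logger = logging.getLogger(__name__)

EMPTY_CELL = "-"
REPRESENTATIVE_SELF = "M (representative)"
UNMATCHED = "unmatched"


def _sort_key_mass_then_id(mz: dict[str, float]):
    # deterministic argmax tie-break: higher m/z first, then smaller id
    return lambda fid: (-mz[fid], fid)


def choose_representative(
    member_ids: list[str],
    mean_intensity: dict[str, float],
    mz: dict[str, float],
    method: str,
    top_n: int | None = None,
) -> str:
    """Pick the representative feature of one group."""
    if not member_ids:
        raise ValueError("empty group")
    if method not in REP_METHODS:
        raise ValueError(f"unknown representative method {method!r}")

    def argmax(candidates: list[str], score) -> str:
        best = max(score(f) for f in candidates)
        tied = [f for f in candidates if score(f) == best]
        return min(tied, key=_sort_key_mass_then_id(mz))

    if method == "highest_intensity":
        return argmax(member_ids, lambda f: mean_intensity[f])
    if method == "highest_mass":
        return argmax(member_ids, lambda f: mz[f])
    if method == "mass2_x_intensity":
        return argmax(member_ids, lambda f: mz[f] ** 2 * mean_intensity[f])
    # highest_mass_in_top_n
    if top_n is None:
        raise ValueError("top_n is required for method 'highest_mass_in_top_n'")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_intensity = sorted(
        member_ids,
        key=lambda f: (-mean_intensity[f],) + tuple(_sort_key_mass_then_id(mz)(f)),
    )
    top = by_intensity[: min(top_n, len(by_intensity))]
    return argmax(top, lambda f: mz[f])


def assign_filter_flags(grouping: Grouping, representatives: dict[int, str]) -> dict[str, int]:
    """Keep flag per feature: 1 for representatives and singletons, else 0.

    The number of kept features always equals the number of groups.
    """
    flags: dict[str, int] = {}
    for gid, members in grouping.members().items():
        if len(members) == 1:
            flags[members[0]] = 1
            continue
        rep = representatives[gid]
        for fid in members:
            flags[fid] = 1 if fid == rep else 0
    return flags


def annotate_within_group(
    grouping: Grouping,
    validated_pairs: list[CandidatePair],
) -> dict[str, str]:
    """Per-feature annotation from its labelled in-group edges.

    Each member lists every validated edge that carries a mass-delta label as
    ``<label>@<partner>``, semicolon-joined with partners in ascending id
    order.  Features without labelled edges (singletons, or runs with the
    mass gate off) get ``-``.
    """
    edges: dict[str, list[tuple[str, str]]] = {}
    for p in validated_pairs:
        if p.delta_label is None:
            continue
        edges.setdefault(p.id_a, []).append((p.id_b, p.delta_label))
        edges.setdefault(p.id_b, []).append((p.id_a, p.delta_label))
    out: dict[str, str] = {}
    for fid in grouping.assignment:
        partners = sorted(edges.get(fid, []))
        out[fid] = (
            ";".join(f"{label}@{partner}" for partner, label in partners)
            if partners
            else EMPTY_CELL
        )
    return out


def annotate_vs_representative(
    member_ids: list[str],
    representative: str,
    mz: dict[str, float],
    deltas: DeltaList,
    mass_tol: float,
) -> dict[str, str]:
    """Annotate each group member against the representative's m/z.

    The representative row reads ``M (representative)``; other members get
    the matching delta label prefixed ``+``/``-`` by the sign of
    ``mz_member - mz_rep``, or ``unmatched`` when nothing fits.
    """
    out: dict[str, str] = {}
    rep_mz = mz[representative]
    for fid in member_ids:
        if fid == representative:
            out[fid] = REPRESENTATIVE_SELF
            continue
        diff = mz[fid] - rep_mz
        entry = deltas.best_match(abs(diff), mass_tol)
        if entry is None:
            out[fid] = UNMATCHED
        else:
            sign = "+" if diff > 0 else "-"
            out[fid] = f"{sign}{entry.label}"
    return out


def annotate(
    table: FeatureTable,
    intensities: IntensityMatrix,
    grouping: Grouping,
    validated_pairs: list[CandidatePair],
    method: str,
    top_n: int | None = None,
    deltas: DeltaList | None = None,
    mass_tol: float | None = None,
) -> tuple[dict[int, str], dict[str, int], dict[str, str], dict[str, str]]:
    """Compute representatives, flags and both annotation columns.

    Returns ``(representatives, flags, within_group, vs_representative)``;
    the two annotation maps are keyed by feature id.
    """
    mean_int = intensities.mean_intensity().to_dict()
    mz = table.mz.to_dict() if table.mz_column is not None else {}
    representatives: dict[int, str] = {}
    for gid, members in grouping.members().items():
        if len(members) == 1:
            continue
        representatives[gid] = choose_representative(members, mean_int, mz, method, top_n)
    flags = assign_filter_flags(grouping, representatives)
    within = annotate_within_group(grouping, validated_pairs)
    vs_rep: dict[str, str] = {}
    for gid, members in grouping.members().items():
        if len(members) == 1:
            vs_rep[members[0]] = EMPTY_CELL
        elif deltas is not None and mass_tol is not None:
            vs_rep.update(
                annotate_vs_representative(members, representatives[gid], mz, deltas, mass_tol)
            )
        else:
            for fid in members:
                vs_rep[fid] = (
                    REPRESENTATIVE_SELF if fid == representatives[gid] else EMPTY_CELL
                )
    return representatives, flags, within, vs_rep


def assemble_output(
    table: FeatureTable,
    grouping: Grouping,
    representatives: dict[int, str],
    flags: dict[str, int],
    within_group: dict[str, str],
    vs_representative: dict[str, str],
    method: str,
) -> pd.DataFrame:
    """Append the five result columns to the original metadata table.

    Column order: original columns unchanged, then ``ACorF_groups``,
    ``isotopes_adducts_fragments``, ``ACorF_filter``,
    ``representative_<method>``, ``annotation_relative_to_representative``.
    """
    out = table.data.copy()
    ids = table.feature_ids
    sizes = grouping.group_sizes()

    def rep_cell(fid: str) -> str:
        gid = grouping.assignment[fid]
        return representatives[gid] if sizes[gid] > 1 else EMPTY_CELL

    out["ACorF_groups"] = [str(grouping.assignment[f]) for f in ids]
    out["isotopes_adducts_fragments"] = [within_group.get(f, EMPTY_CELL) for f in ids]
    out["ACorF_filter"] = [flags[f] for f in ids]
    out[f"representative_{method}"] = [rep_cell(f) for f in ids]
    out["annotation_relative_to_representative"] = [
        vs_representative.get(f, EMPTY_CELL) for f in ids
    ]
    n_kept = int(np.sum([flags[f] for f in ids]))
    logger.info(
        "annotated %d features: %d groups, %d kept, %d flagged for deletion",
        len(ids), grouping.n_groups, n_kept, len(ids) - n_kept,
    )
    return out
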