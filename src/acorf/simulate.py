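"""Synthetic LC-/GC-MS peak tables with known ground-truth analyte groups.

The generator emulates the level of data the filtration tool consumes —
post-processing peak tables, not raw spectra.  Each simulated analyte
contributes a *parent* feature (random m/z, RT and a base intensity profile
across samples) plus 0..``max_derived`` derived features (isotopologues,
adducts, in-source fragments): their m/z is the parent's shifted by a
reference mass delta, their RT is the parent's plus jitter, and their
intensity profile is a fixed fraction of the parent's with multiplicative
noise — so derived features are near-perfectly correlated with their parent
across samples, the signature the filtration algorithm keys on.  Background
*noise* features get independent random profiles.

Default conditions (documented in the methods note): intensities log-uniform
over three decades (1e3..1e6), derived/parent abundance ratio uniform in
[0.05, 0.8], multiplicative Gaussian noise with CV ``cv_noise``, RT in
minutes over a 0.5-12 min gradient with within-analyte jitter
``rt_jitter`` (default 0.02 min), m/z uniform in 150-850 Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .deltas import default_delta_list
from .grouping import Grouping
from .tables import DeltaList, FeatureTable, IntensityMatrix

__all__ = ["GroundTruth", "simulate_dataset", "score_recovery"]

MZ_RANGE = (150.0, 850.0)
RT_RANGE_MIN = (0.5, 12.0)
LOG10_INTENSITY_RANGE = (3.0, 6.0)
RATIO_RANGE = (0.05, 0.8)

# role of each derived feature follows the label of the delta applied
_ROLE_OF_PREFIX = (("isotope", "isotope"), ("loss_", "fragment"))


def _role_for_label(label: str) -> str:
    for prefix, role in _ROLE_OF_PREFIX:
        if label.startswith(prefix):
            return role
    return "adduct"


@dataclass
class GroundTruth:
    """True partition of the simulated features into analyte groups."""

    analyte_of: dict[str, str]  # feature id -> analyte id (noise features own ids)
    role_of: dict[str, str]  # feature id -> parent / isotope / adduct / fragment / noise
    seed: int

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fid, aid in self.analyte_of.items():
            out.setdefault(aid, []).append(fid)
        return out

    @property
    def labels(self) -> pd.Series:
        return pd.Series(self.analyte_of)


def _unique_id(mz: float, rt_min: float, taken: set[str]) -> str:
    # W4M-style id: M<mz>T<rt in seconds>
    base = f"M{mz:.4f}T{rt_min * 60:.0f}"
    fid = base
    k = 1
    while fid in taken:
        k += 1
        fid = f"{base}_{k}"
    taken.add(fid)
    return fid


def simulate_dataset(
    n_analytes: int = 50,
    max_derived: int = 4,
    n_samples: int = 50,
    n_noise_features: int = 100,
    deltas: DeltaList | None = None,
    cv_noise: float = 0.05,
    rt_jitter: float = 0.02,
    seed: int = 0,
    fixed_n_derived: int | None = None,
) -> tuple[IntensityMatrix, FeatureTable, GroundTruth]:
    """Simulate a peak table with known analyte groups.

    Parameters
    ----------
    n_analytes
        Number of true analytes, each spawning a parent feature.
    max_derived
        Per-analyte cap on derived features (count drawn uniformly in
        0..max_derived unless ``fixed_n_derived`` pins it).
    n_samples
        Number of samples (columns of the intensity matrix).
    n_noise_features
        Uncorrelated background features.
    deltas
        Mass-delta list the derived features draw from; defaults to the
        builtin reference list.
    cv_noise
        Coefficient of variation of the multiplicative intensity noise on
        derived features (0 gives exactly proportional profiles).
    rt_jitter
        Half-width (same units as RT, minutes) of the uniform RT scatter of
        derived features around their parent.
    seed
        Deterministic generator seed; identical seeds give identical output.
    fixed_n_derived
        When set, every analyte gets exactly this many derived features.

    Returns
    -------
    (IntensityMatrix, FeatureTable, GroundTruth)
    """
    if min(n_analytes, n_samples, n_noise_features) < 0 or max_derived < 0:
        raise ValueError("counts must be >= 0")
    if cv_noise < 0:
        raise ValueError("cv_noise must be >= 0")
    if deltas is None:
        deltas = default_delta_list()
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    taken: set[str] = set()
    mzs: list[float] = []
    rts: list[float] = []
    profiles: list[np.ndarray] = []
    analyte_of: dict[str, str] = {}
    role_of: dict[str, str] = {}

    entries = list(deltas)
    for a in range(n_analytes):
        aid = f"A{a + 1}"
        parent_mz = float(rng.uniform(*MZ_RANGE))
        parent_rt = float(rng.uniform(*RT_RANGE_MIN))
        base = 10.0 ** rng.uniform(*LOG10_INTENSITY_RANGE, size=n_samples)
        fid = _unique_id(parent_mz, parent_rt, taken)
        ids.append(fid)
        mzs.append(parent_mz)
        rts.append(parent_rt)
        profiles.append(base)
        analyte_of[fid] = aid
        role_of[fid] = "parent"

        n_derived = (
            fixed_n_derived
            if fixed_n_derived is not None
            else int(rng.integers(0, max_derived + 1))
        )
        # sample deltas without replacement so sibling m/z values stay distinct
        picks = rng.choice(len(entries), size=min(n_derived, len(entries)), replace=False)
        for k in picks:
            entry = entries[int(k)]
            role = _role_for_label(entry.label)
            sign = -1.0 if role == "fragment" else 1.0
            d_mz = parent_mz + sign * entry.delta
            if d_mz <= 0:
                d_mz = parent_mz + entry.delta
            d_rt = parent_rt + float(rng.uniform(-rt_jitter, rt_jitter))
            ratio = float(rng.uniform(*RATIO_RANGE))
            noise = 1.0 + cv_noise * rng.standard_normal(n_samples)
            profile = np.clip(ratio * base * noise, 0.0, None)
            dfid = _unique_id(d_mz, d_rt, taken)
            ids.append(dfid)
            mzs.append(d_mz)
            rts.append(d_rt)
            profiles.append(profile)
            analyte_of[dfid] = aid
            role_of[dfid] = role

    for b in range(n_noise_features):
        mz = float(rng.uniform(*MZ_RANGE))
        rt = float(rng.uniform(*RT_RANGE_MIN))
        profile = 10.0 ** rng.uniform(*LOG10_INTENSITY_RANGE, size=n_samples)
        fid = _unique_id(mz, rt, taken)
        ids.append(fid)
        mzs.append(mz)
        rts.append(rt)
        profiles.append(profile)
        analyte_of[fid] = f"noise_{b + 1}"
        role_of[fid] = "noise"

    sample_ids = [f"S{s + 1}" for s in range(n_samples)]
    values = pd.DataFrame(np.array(profiles), index=ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "name": ids,
            "mz": [f"{v:.4f}" for v in mzs],
            "rt": [f"{v:.4f}" for v in rts],
        }
    )
    table = FeatureTable(meta, id_column="name", mz_column="mz", rt_column="rt")
    truth = GroundTruth(analyte_of=analyte_of, role_of=role_of, seed=seed)
    return IntensityMatrix(values), table, truth


def score_recovery(predicted: Grouping, truth: GroundTruth) -> tuple[float, float]:
    """Compare a predicted grouping against the simulation ground truth.

    Returns ``(exact_match_fraction, adjusted_rand_index)``: the fraction of
    true groups whose member set is recovered exactly as one predicted
    group, and the ARI over all features.  Both are label-invariant.
    """
    pred_ids = set(predicted.assignment)
    true_ids = set(truth.analyte_of)
    if pred_ids != true_ids:
        raise ValueError("predicted grouping and ground truth cover different features")
    order = sorted(pred_ids)
    true_labels = [truth.analyte_of[f] for f in order]
    pred_labels = [predicted.assignment[f] for f in order]
    ari = float(adjusted_rand_score(true_labels, pred_labels))

    pred_groups = {frozenset(m) for m in predicted.members().values()}
    true_groups = [frozenset(m) for m in truth.groups().values()]
    exact = sum(1 for g in true_groups if g in pred_groups) / len(true_groups)
    return exact, ari
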