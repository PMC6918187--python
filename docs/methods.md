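# Methods

## Problem and model

Processed MS-metabolomics peak tables contain many features per metabolite:
the parent ion plus isotopologues, adducts and in-source fragments produced
during ionisation.  Such features are analytically — not biologically —
correlated: their intensity profiles across samples are close to proportional
(each derived species is produced at a roughly constant rate from the same
analyte pool), they share a retention time, and their m/z offsets take
characteristic values.  The filtration algorithm treats these three
signatures as independent evidence and only groups features supported by all
enabled criteria.

Formally: let s(i,j) be a user-supplied similarity (any measure; Pearson or
Spearman correlation are built in), RT_i the retention time and m_i the m/z
of feature i, and D = {(label_k, δ_k)} a reference list of positive mass
deltas.  A pair is *validated* when

* s(i,j) > t (strict, signed — anti-correlated pairs never group unless the
  explicit absolute-value mode is enabled), and, when enabled,
* |RT_i − RT_j| ≤ ΔRT (inclusive), and, when enabled,
* min_k | |m_i − m_j| − δ_k | ≤ tol (inclusive; the minimising entry labels
  the pair, list order breaking exact ties).

Groups are the connected components of the validated-pair graph over all
features.  Transitivity is deliberate: if A–B and B–C are validated, A and C
are analytically linked through B even when the A–C mass offset matches no
single list entry (e.g. an isotopologue and an adduct of the same parent).
Singletons are groups too and count toward group totals.  Group numbers are
consecutive integers in order of first member appearance in the metadata
table, so output is deterministic and invariant to similarity-matrix row
order.

The mass gate cannot be enabled without the RT gate: a mass-delta match
between features that do not co-elute carries no evidence of a shared
analyte, so the parameter validator rejects that combination.

## Representative choice

One member of each multi-member group is kept (`ACorF_filter = 1`), the rest
flagged for deletion.  Four methods: (1) highest mean intensity, (2) highest
m/z, (3) highest m/z² × mean intensity, (4) highest m/z among the top-n
members by mean intensity.  "Intensity" is always the arithmetic mean over
non-missing samples, which makes the choice invariant to sample order and
consistent across the four methods.  All argmax operations break ties toward
higher m/z and then lexicographically smaller feature id, so two methods that
coincide mathematically (method 4 with n = group size vs method 2; n = 1 vs
method 1) select identical features.

## Parameters

| parameter | meaning | unit | default/preset |
|---|---|---|---|
| `cor_threshold` | strict similarity cut | — | 0.90 (LC/GC presets), 0.75 (CAMERA-compatible) |
| `rt_delta` | RT window half-width | RT-column units | 0.1 min in presets; off when unset |
| `mass_tol` | delta-match tolerance | Da | 0.005 (LC-HRMS), 0.2 (quadrupole GC-MS), 0.002 (CAMERA-compatible) |
| `rep_method` | representative rule | — | highest intensity (LC), highest mass in top-3 (GC) |
| `top_n` | top-list size for method 4 | — | 3 in the GC preset (the published recipes leave it to the user) |

RT units are whatever the RT column stores; presets state their window in
minutes and the CLI's `--rt-units s` flag converts it for seconds-based
columns.

The shipped default delta list (16 entries, version 1.0, in
`acorf/deltas.py`) is this package's own compilation from standard atomic
masses: ¹³C/²×¹³C/³⁴S/¹⁸O/³⁷Cl isotopologue spacings, Na/K/NH₄-for-H
exchanges, chloride/formate/acetate adducts, H₂O and CO₂ neutral losses, and
SO₃/HPO₃ conjugate moieties.  It is a pragmatic electrospray-oriented list,
not a reproduction of any other tool's list; users should supply their own
for other chemistries.

## Numerical and I/O choices

* Similarity: pandas pairwise-complete correlation; a pair sharing fewer
  than 3 samples, or any pair involving a zero-variance feature, gets a
  missing similarity, which no threshold selects (NaN comparisons are false).
  Internal Pearson agrees with a two-pass textbook implementation to 1e-12.
* Delimiters are auto-detected per file (tab beats comma); metadata cells are
  kept as strings so original columns round-trip byte-identically.
* The SIF output contains the pairs passing the similarity threshold only —
  before the RT/mass gates — because the network view is meant to show all
  above-threshold correlation structure; each unordered pair appears once,
  with the coefficient rendered to 4 decimal places as the interaction token.
* Annotation grammar is this package's convention: within-group edges as
  `label@partner` joined by `;` with partners in ascending id order;
  representative-relative annotations signed `+`/`-` by the member-minus-
  representative mass difference, `unmatched` when nothing fits, `M
  (representative)` on the representative row, `-` in all annotation cells of
  singleton rows (singletons keep a unique group number and flag 1).
* Asymmetry beyond 1e-6 in a supplied similarity matrix is a hard error (the
  worst cell is reported); duplicated feature ids and id mismatches between
  the three inputs are hard errors listing the offenders.

## Synthetic data generator

`simulate_dataset` emulates the peak-table level the tool consumes, not raw
spectra.  Per analyte: a parent feature with m/z ~ U(150, 850) Da,
RT ~ U(0.5, 12) min, and a per-sample base intensity profile drawn
log-uniformly over three decades (10³–10⁶, typical electrospray dynamic
range); 0..`max_derived` derived features whose m/z is the parent's shifted
by a delta drawn without replacement from the reference list (sign − for
neutral-loss entries, + otherwise), RT jittered by U(−`rt_jitter`,
`rt_jitter`) (default 0.02 min), and intensities = ratio × parent ×
(1 + `cv_noise`·N(0,1)) with ratio ~ U(0.05, 0.8) and `cv_noise` = 0.05 by
default.  Noise features get independent profiles.  Identical seeds give
identical output.

What this does and does not show: derived features are *exactly*
proportional to their parent up to multiplicative noise, analytes are
mutually independent, and every derived m/z offset is on the reference list.
Real data have correlated biology, chimeric peaks, drifting RT and deltas
missing from any list, so perfect recovery on simulations (ARI 1.0 at 50
samples under the LC preset) bounds the algorithmic, not the real-world,
error.  The small-cohort refinement experiment (8 samples, threshold 0.75)
exists precisely because few samples leave spurious correlations above the
cut, making the RT and mass gates' contribution visible as a strictly
increasing group count.

## Problem sizes

The test suite and the reproduction script use 5-feature worked examples,
200 random graphs of ≤ 50 nodes against a BFS oracle, 100 simulated datasets
of ~100 features for the monotone-refinement property, and one 242-feature /
50-sample simulation for recovery scoring — sizes at which every expected
value is independently recomputable while the whole suite runs in seconds.

## Known limitations

* Grouping quality is bounded by the supplied similarity matrix; no
  chromatographic peak-shape evidence is used (by design — only table-level
  inputs).
* Transitive closure can chain distinct co-eluting analytes through a shared
  neighbour if every link individually passes all gates.
* The default delta list is electrospray-oriented; GC-MS users should
  pre-filter derivatisation fragments and supply a suitable list.
* Row deletion is delegated downstream: the tool only sets flags (plus the
  optional `--apply-filter` convenience output).
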