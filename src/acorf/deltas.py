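"""Builtin reference list of isotope, adduct and neutral-loss mass differences.

The values are exact mass differences (Da) computed from standard atomic
masses (CODATA/AME): e.g. one 13C-for-12C substitution adds 1.003355 Da, a
sodium-for-proton exchange adds 21.981944 Da, loss of water removes
18.010565 Da.  The list covers the species most commonly responsible for
analytical redundancy in electrospray LC-MS peak tables (isotopologues,
alkali adducts, acid adducts/clusters, small neutral losses, sulfate and
phosphate moieties).  Users with instrument-specific chemistry should supply
their own two-column (label, delta) file instead.
"""

from __future__ import annotations

from .tables import DeltaEntry, DeltaList

__all__ = ["DEFAULT_DELTA_LIST", "BUILTIN_TOKEN", "default_delta_list"]

BUILTIN_TOKEN = "default"

#: version tag of the shipped list (bump when entries change)
DEFAULT_LIST_VERSION = "1.0"

_DEFAULT_ENTRIES: list[tuple[str, float]] = [
    # isotopologues
    ("isotope_13C", 1.003355),      # 13C - 12C
    ("isotope_13C2", 2.006710),     # two 13C substitutions
    ("isotope_34S", 1.995796),      # 34S - 32S
    ("isotope_18O", 2.004246),      # 18O - 16O
    ("isotope_37Cl", 1.997050),     # 37Cl - 35Cl
    # adduct exchanges (relative to the protonated/deprotonated species)
    ("Na-H", 21.981944),            # sodium replaces a proton
    ("K-H", 37.955882),             # potassium replaces a proton
    ("NH4-H", 17.026549),           # ammonium replaces a proton (= NH3 gain)
    ("HCl_Cl_adduct", 35.976678),   # chloride adduct vs neutral (HCl)
    # acid adducts / clusters
    ("HCOOH_formic", 46.005480),    # formic acid
    ("CH3COOH_acetic", 60.021129),  # acetic acid
    ("NaCOOH_formate", 67.987424),  # sodium formate cluster
    # common neutral losses (in-source fragments)
    ("loss_H2O", 18.010565),
    ("loss_CO2", 43.989829),
    # moieties seen on conjugated urinary metabolites
    ("SO3_sulfate", 79.956815),
    ("HPO3_phosphate", 79.966331),
]


def default_delta_list() -> DeltaList:
    """The shipped default mass-difference list (labels must stay unique)."""
    seen: dict[str, float] = {}
    entries: list[DeltaEntry] = []
    for label, delta in _DEFAULT_ENTRIES:
        if label in seen:
            continue
        seen[label] = delta
        entries.append(DeltaEntry(label, delta))
    return DeltaList(entries)


DEFAULT_DELTA_LIST = default_delta_list()
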