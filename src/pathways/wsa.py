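"""Hull Wetted Surface Area (WSA) estimation per vessel.

WSA (m^2), the submerged hull area, is the proxy for a hull's capacity
to carry biofouling.  Large commercial classes use a power-law
regression on a hull dimension, WSA = a * dim^b, with dead weight
tonnage (DWT) as the primary predictor and class-specific fallbacks
when DWT is missing (breadth overall for fishing vessels, tugs-and-
supply and passenger ships; length overall for the "Other" category).
Small pleasure craft (< 26 m length overall) use the Denny-Mumford
small-craft formula WSA = 1.7 * L_OA * T + V/T (L_OA length overall m,
T draft m, V gross tonnage); larger pleasure vessels follow the fishing
category.  Ship's tenders are assigned a flat 9.9 m^2 regardless of
recorded length (based on small-craft values for 4-6 m hulls).

The regression coefficients ship as an editable CSV
(``data/wsa_coefficients.csv``); its default values are illustrative,
not fitted estimates, and every computation records which method and
category produced it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .types import VesselProfile

TENDER_WSA_M2 = 9.9
PLEASURE_DM_MAX_LOA_M = 26.0

#: AIS vessel class -> power-law coefficient category.
CATEGORY_OF_CLASS = {
    "Bulk": "Bulk carrier",
    "Cargo": "Cargo",
    "Fishing": "Fishing",
    "Offshore": "Other",       # offshore research vessels follow "Other"
    "Passenger": "Passenger",
    "Pilot": "Tugs and supply",  # service craft
    "Tanker": "Tanker",
}

#: Categories allowed to fall back to breadth overall when DWT is missing.
BOA_FALLBACK_CATEGORIES = {"Fishing", "Tugs and supply", "Passenger"}


class MissingDimensionError(ValueError):
    """No usable hull dimension for the dispatched method."""


class UnknownClassError(ValueError):
    """Vessel class outside the nine supported categories."""


@dataclass(frozen=True)
class WSACoefficients:
    category: str
    input_dim: str  # DWT | BOA | LOA
    a: float
    b: float

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("regression coefficient a must be positive")
        if self.input_dim not in ("DWT", "BOA", "LOA"):
            raise ValueError(f"unknown input_dim {self.input_dim!r}")


@dataclass(frozen=True)
class WSAResult:
    mmsi: int
    wsa_m2: float
    method: str        # power_law_DWT | power_law_BOA | power_law_LOA | denny_mumford | tender_constant
    category_used: str


def load_coefficients(path=None) -> dict:
    """Load a coefficients CSV into a ``{(category, input_dim): WSACoefficients}`` map."""
    if path is None:
        path = resources.files("pathways.data") / "wsa_coefficients.csv"
    df = pd.read_csv(path, comment="#")
    table = {}
    for row in df.itertuples(index=False):
        c = WSACoefficients(category=str(row.category), input_dim=str(row.input_dim),
                            a=float(row.a), b=float(row.b))
        table[(c.category, c.input_dim)] = c
    return table


def map_category(profile: VesselProfile):
    """Resolve a vessel's coefficient category and dispatch hint.

    Returns ``(category, hint)`` where hint is one of ``power_law``,
    ``denny_mumford`` or ``tender_constant``.
    """
    vt = profile.vessel_type
    if vt == "Tender":
        return "Tender", "tender_constant"
    if vt == "Pleasure":
        if math.isnan(profile.loa_m):
            raise MissingDimensionError(
                f"mmsi {profile.mmsi}: pleasure vessel needs L_OA to choose a WSA method")
        if profile.loa_m < PLEASURE_DM_MAX_LOA_M:
            return "Pleasure (small craft)", "denny_mumford"
        return "Fishing", "power_law"   # larger pleasure craft follow fishing values
    try:
        return CATEGORY_OF_CLASS[vt], "power_law"
    except KeyError:
        raise UnknownClassError(f"unknown vessel class {vt!r}") from None


def wsa_power_law(dim_value: float, coeff: WSACoefficients) -> float:
    """WSA = a * dim^b."""
    if not dim_value > 0:
        raise MissingDimensionError(f"power-law dimension must be positive, got {dim_value}")
    return coeff.a * dim_value ** coeff.b


def wsa_denny_mumford(loa_m: float, draft_m: float, gross_tonnage: float) -> float:
    """Denny-Mumford small-craft estimate: 1.7 * L_OA * T + V / T."""
    if not loa_m > 0:
        raise MissingDimensionError("Denny-Mumford needs a positive length overall")
    if not draft_m > 0:
        raise MissingDimensionError("Denny-Mumford needs a positive draft")
    if gross_tonnage < 0 or math.isnan(gross_tonnage):
        raise MissingDimensionError("Denny-Mumford needs a non-negative gross tonnage")
    return 1.7 * loa_m * draft_m + gross_tonnage / draft_m


def vessel_wsa(profile: VesselProfile, table: dict | None = None) -> WSAResult:
    """Dispatch the appropriate WSA method for one vessel.

    Order: tender constant; Denny-Mumford where mapped; power law on
    DWT; breadth-overall coefficients when DWT is missing and the
    category allows it; length-overall coefficients for "Other".  A
    profile with no usable dimension raises ``MissingDimensionError``
    naming what was absent -- dispatch is total, with no silent default.
    """
    table = table if table is not None else load_coefficients()
    category, hint = map_category(profile)
    if hint == "tender_constant":
        return WSAResult(profile.mmsi, TENDER_WSA_M2, "tender_constant", category)
    if hint == "denny_mumford":
        return WSAResult(
            profile.mmsi,
            wsa_denny_mumford(profile.loa_m, profile.draft_m, profile.gross_tonnage),
            "denny_mumford", category)

    if not math.isnan(profile.dwt_t):
        coeff = table[(category, "DWT")]
        return WSAResult(profile.mmsi, wsa_power_law(profile.dwt_t, coeff),
                         "power_law_DWT", category)
    if category in BOA_FALLBACK_CATEGORIES and not math.isnan(profile.boa_m):
        coeff = table[(category, "BOA")]
        return WSAResult(profile.mmsi, wsa_power_law(profile.boa_m, coeff),
                         "power_law_BOA", category)
    if category == "Other" and not math.isnan(profile.loa_m):
        coeff = table[(category, "LOA")]
        return WSAResult(profile.mmsi, wsa_power_law(profile.loa_m, coeff),
                         "power_law_LOA", category)
    missing = [d for d, v in (("DWT", profile.dwt_t), ("B_OA", profile.boa_m),
                              ("L_OA", profile.loa_m)) if math.isnan(v)]
    raise MissingDimensionError(
        f"mmsi {profile.mmsi} ({profile.vessel_type}, category {category}): "
        f"no usable dimension; missing {', '.join(missing)}")


def fleet_wsa(profiles, table: dict | None = None) -> pd.DataFrame:
    """WSA for every vessel, as a DataFrame keyed by mmsi."""
    table = table if table is not None else load_coefficients()
    rows = []
    for p in profiles:
        r = vessel_wsa(p, table)
        rows.append({"mmsi": r.mmsi, "vessel_type": p.vessel_type,
                     "category_used": r.category_used, "method": r.method,
                     "wsa_m2": r.wsa_m2})
    return pd.DataFrame(rows, columns=["mmsi", "vessel_type", "category_used",
                                       "method", "wsa_m2"])
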