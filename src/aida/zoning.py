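"""Traffic-light zoning of the four geometric parameters and AIDA classes.

Each parameter is mapped onto GREEN (low risk), YELLOW (cut-off zone) or RED
(high risk) intervals. The AIDA class of a patient is the number of
parameters outside the green zone, from 0 (all green) to 4 (none green).

The default thresholds are the published decision-tree cut-offs:

* AD: green below 65.5 mm, yellow in [65.5, 70.5) mm, red at >= 70.5 mm;
* AoP: red below 101.5 deg, green in [101.5, 144.5) deg, red at >= 144.5 deg;
* HSD: green below 19.5 mm, red at >= 19.5 mm;
* MLA: green below a configurable red threshold (default 65.5 deg).

Intervals are half-open [lo, hi); a red band is therefore closed at its
lower threshold, matching the ">= threshold -> red" convention.

No red threshold for MLA is published in this cut-off family; the 65.5 deg
default was chosen near the cohort's mean MLA so both zones are populated,
and should be overridden when a clinically validated value is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import yaml

from .records import PatientRecord, Zone

log = logging.getLogger(__name__)

#: Observed ranges of the study cohort; zoning outside them is allowed but
#: logged as extrapolation beyond the evidence base.
OBSERVED_RANGES = {
    "ad_mm": (4.0, 95.0),
    "aop_deg": (72.0, 192.0),
    "hsd_mm": (10.0, 51.0),
    "mla_deg": (26.0, 90.0),
}

PARAMETERS = ("ad_mm", "aop_deg", "hsd_mm", "mla_deg")


@dataclass(frozen=True)
class ZoneInterval:
    """Half-open interval [lo, hi) carrying a zone label."""

    label: Zone
    lo: float
    hi: float

    def __contains__(self, value: float) -> bool:
        return self.lo <= value < self.hi


@dataclass(frozen=True)
class ZoneScheme:
    """Per-parameter ordered, disjoint zone intervals covering [0, inf)."""

    intervals: dict[str, tuple[ZoneInterval, ...]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for param, ivs in self.intervals.items():
            lo = 0.0
            for iv in ivs:
                if not math.isclose(iv.lo, lo) or iv.hi <= iv.lo:
                    raise ValueError(
                        f"{param}: intervals must be contiguous, disjoint and "
                        f"increasing (got [{iv.lo}, {iv.hi}) after {lo})"
                    )
                lo = iv.hi
            if not math.isinf(lo):
                raise ValueError(f"{param}: intervals must cover up to infinity")

    def to_yaml(self) -> str:
        doc = {
            param: [
                {"label": iv.label.value, "lo": iv.lo,
                 "hi": None if math.isinf(iv.hi) else iv.hi}
                for iv in ivs
            ]
            for param, ivs in self.intervals.items()
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ZoneScheme":
        doc = yaml.safe_load(text)
        intervals = {
            param: tuple(
                ZoneInterval(
                    Zone(iv["label"]), float(iv["lo"]),
                    math.inf if iv["hi"] is None else float(iv["hi"]),
                )
                for iv in ivs
            )
            for param, ivs in doc.items()
        }
        return cls(intervals=intervals)


@dataclass(frozen=True)
class ZoneProfile:
    """Zone quadruple plus the AIDA class it implies."""

    zone_ad: Zone
    zone_aop: Zone
    zone_hsd: Zone
    zone_mla: Zone

    @property
    def aida_class(self) -> int:
        return sum(z is not Zone.GREEN for z in self.zones())

    def zones(self) -> tuple[Zone, Zone, Zone, Zone]:
        return (self.zone_ad, self.zone_aop, self.zone_hsd, self.zone_mla)


def default_zone_scheme(
    mla_red_threshold: float = 65.5,
    ad_yellow_band: tuple[float, float] = (65.5, 70.5),
    aop_green_band: tuple[float, float] = (101.5, 144.5),
    hsd_red_threshold: float = 19.5,
) -> ZoneScheme:
    """Published cut-offs as a :class:`ZoneScheme`; every threshold overridable."""
    inf = math.inf
    intervals = {
        "ad_mm": (
            ZoneInterval(Zone.GREEN, 0.0, ad_yellow_band[0]),
            ZoneInterval(Zone.YELLOW, ad_yellow_band[0], ad_yellow_band[1]),
            ZoneInterval(Zone.RED, ad_yellow_band[1], inf),
        ),
        "aop_deg": (
            ZoneInterval(Zone.RED, 0.0, aop_green_band[0]),
            ZoneInterval(Zone.GREEN, aop_green_band[0], aop_green_band[1]),
            ZoneInterval(Zone.RED, aop_green_band[1], inf),
        ),
        "hsd_mm": (
            ZoneInterval(Zone.GREEN, 0.0, hsd_red_threshold),
            ZoneInterval(Zone.RED, hsd_red_threshold, inf),
        ),
        "mla_deg": (
            ZoneInterval(Zone.GREEN, 0.0, mla_red_threshold),
            ZoneInterval(Zone.RED, mla_red_threshold, inf),
        ),
    }
    provenance = {
        "ad_mm": "decision-tree cut-offs 65.5 / 70.5 mm (yellow band between)",
        "aop_deg": "decision-tree cut-offs 101.5 / 144.5 deg (green between)",
        "hsd_mm": "decision-tree cut-off 19.5 mm",
        "mla_deg": "no published threshold in this cut-off family; "
                   "package default, override via configuration",
    }
    return ZoneScheme(intervals=intervals, provenance=provenance)


def zone_of(value: float, parameter: str, scheme: ZoneScheme) -> Zone:
    """Zone label of a measurement under the half-open interval convention."""
    if parameter not in scheme.intervals:
        raise KeyError(f"no zone intervals for parameter {parameter!r}")
    rng = OBSERVED_RANGES.get(parameter)
    if rng is not None and not rng[0] <= value <= rng[1]:
        log.warning(
            "%s = %g lies outside the observed range [%g, %g]; zoning "
            "extrapolates beyond the evidence base", parameter, value, *rng
        )
    for iv in scheme.intervals[parameter]:
        if value in iv:
            return iv.label
    raise ValueError(f"{parameter} = {value} falls outside all zone intervals")


def profile(record: PatientRecord, scheme: ZoneScheme | None = None) -> ZoneProfile:
    """Zone the four parameters of a patient and derive the AIDA class."""
    scheme = scheme if scheme is not None else default_zone_scheme()
    return ZoneProfile(
        zone_ad=zone_of(record.ad_mm, "ad_mm", scheme),
        zone_aop=zone_of(record.aop_deg, "aop_deg", scheme),
        zone_hsd=zone_of(record.hsd_mm, "hsd_mm", scheme),
        zone_mla=zone_of(record.mla_deg, "mla_deg", scheme),
    )
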