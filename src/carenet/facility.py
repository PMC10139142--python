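"""Facility model: zones, residents, and the five-factor bedroom-privacy instrument.

A long-term care (LTC) facility is described as a set of *zones* (bedrooms,
common areas, transitional spaces such as corridor alcoves, and other rooms)
plus a roster of *residents*, each assigned to one shared bedroom.  Bedroom
privacy is scored with a five-factor architectural audit:

======================  =====================================================
factor                  coding
======================  =====================================================
bedroom occupancy       five or more beds = 0; four = 1; three = 2; two or
                        fewer = 3
bedroom adjacency       public = 0; semi-public = 1; semi-private = 2;
                        private = 3
transitional spaces     number of transitional spaces between the bedroom and
                        the common area, capped at 3
visibility              whether residents can see the common areas from the
                        bedroom (0/1; coding direction configurable, see
                        :func:`score_visibility`)
visual privacy          whether residents' beds can be seen from the common
                        areas (visible = 0, screened = 1)
======================  =====================================================

The total (0-11) is the sum of the five factors; higher totals mean more
privacy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ZoneClass",
    "AdjacencyClass",
    "BedroomType",
    "Zone",
    "Resident",
    "Facility",
    "PrivacyAssessment",
    "score_occupancy",
    "score_adjacency",
    "score_transitional",
    "score_visibility",
    "score_visual_privacy",
    "assess_bedroom",
    "assess_facility",
]


class FacilityError(ValueError):
    """Invalid facility description or scoring input."""


class ZoneClass(str, Enum):
    BEDROOM = "bedroom"
    COMMON = "common_area"
    TRANSITIONAL = "transitional"
    OTHER = "other"


class AdjacencyClass(str, Enum):
    PRIVATE = "private"
    SEMI_PRIVATE = "semi_private"
    SEMI_PUBLIC = "semi_public"
    PUBLIC = "public"


class BedroomType(str, Enum):
    THREE_BED = "three_bed"
    FOUR_BED_CORRIDOR = "four_bed_corridor"
    FOUR_BED_COMMON = "four_bed_common"
    FIVE_BED = "five_bed"


#: nominal number of beds per bedroom type
BEDROOM_CAPACITY: dict[BedroomType, int] = {
    BedroomType.THREE_BED: 3,
    BedroomType.FOUR_BED_CORRIDOR: 4,
    BedroomType.FOUR_BED_COMMON: 4,
    BedroomType.FIVE_BED: 5,
}


@dataclass(frozen=True)
class Zone:
    """One room or space in the facility.

    Bedroom zones carry the architectural attributes the privacy instrument
    needs (adjacency class, transitional-space count, sight lines); other
    zone classes may leave them unset.  ``neighbors`` lists physically
    adjacent zones and is used by the sensor-noise model (cross-talk
    duplicates land in a neighboring zone).
    """

    zone_id: str
    zone_class: ZoneClass
    adjacency_class: AdjacencyClass | None = None
    n_transitional_to_common: int | None = None
    sees_common: bool | None = None
    beds_visible_from_common: bool | None = None
    capacity: int | None = None
    neighbors: tuple[str, ...] = ()

    @property
    def is_bedroom(self) -> bool:
        return self.zone_class is ZoneClass.BEDROOM


@dataclass(frozen=True)
class Resident:
    resident_id: str
    bedroom_zone: str
    bedroom_type: BedroomType
    sex: str | None = None


@dataclass(frozen=True)
class PrivacyAssessment:
    """Five factor scores plus total for one shared bedroom."""

    bedroom_zone: str
    occupancy_score: int
    adjacency_score: int
    transitional_score: int
    visibility_score: int
    visual_privacy_score: int

    @property
    def total(self) -> int:
        return (
            self.occupancy_score
            + self.adjacency_score
            + self.transitional_score
            + self.visibility_score
            + self.visual_privacy_score
        )


class Facility:
    """Validated container of zones and residents.

    The structured facility description (YAML or dict) is the single source
    of truth for zone classes, adjacency and sight lines; nothing is inferred
    from geometry.
    """

    def __init__(self, zones: Iterable[Zone], residents: Iterable[Resident]):
        self.zones: dict[str, Zone] = {}
        for z in zones:
            if z.zone_id in self.zones:
                raise FacilityError(f"duplicate zone_id {z.zone_id!r}")
            self.zones[z.zone_id] = z
        self.residents: dict[str, Resident] = {}
        for r in residents:
            if r.resident_id in self.residents:
                raise FacilityError(f"duplicate resident_id {r.resident_id!r}")
            if r.resident_id in self.zones:
                raise FacilityError(
                    f"resident_id {r.resident_id!r} collides with a zone_id"
                )
            self.residents[r.resident_id] = r
        self._validate()

    def _validate(self) -> None:
        for r in self.residents.values():
            z = self.zones.get(r.bedroom_zone)
            if z is None:
                raise FacilityError(
                    f"resident {r.resident_id!r}: bedroom zone "
                    f"{r.bedroom_zone!r} not defined"
                )
            if not z.is_bedroom:
                raise FacilityError(
                    f"resident {r.resident_id!r}: zone {z.zone_id!r} is not a bedroom"
                )
        for z in self.zones.values():
            if z.is_bedroom:
                missing = [
                    name
                    for name in (
                        "adjacency_class",
                        "n_transitional_to_common",
                        "sees_common",
                        "beds_visible_from_common",
                    )
                    if getattr(z, name) is None
                ]
                if missing:
                    raise FacilityError(
                        f"bedroom zone {z.zone_id!r} missing attributes: {missing}"
                    )
            for n in z.neighbors:
                if n not in {zz.zone_id for zz in self.zones.values()} | set():
                    raise FacilityError(
                        f"zone {z.zone_id!r}: unknown neighbor {n!r}"
                    )

    # --- roster helpers -------------------------------------------------
    def roommates(self, resident_id: str) -> list[str]:
        r = self.residents[resident_id]
        return sorted(
            other.resident_id
            for other in self.residents.values()
            if other.bedroom_zone == r.bedroom_zone
            and other.resident_id != resident_id
        )

    def are_roommates(self, a: str, b: str) -> bool:
        if a == b:
            return False
        return self.residents[a].bedroom_zone == self.residents[b].bedroom_zone

    def occupants(self, zone_id: str) -> list[str]:
        return sorted(
            r.resident_id
            for r in self.residents.values()
            if r.bedroom_zone == zone_id
        )

    def bedrooms(self) -> list[Zone]:
        return [z for z in self.zones.values() if z.is_bedroom]

    def zones_of_class(self, zone_class: ZoneClass) -> list[Zone]:
        return [z for z in self.zones.values() if z.zone_class is zone_class]

    def roster(self) -> list[str]:
        return sorted(self.residents)

    def bedroom_type_counts(self) -> dict[BedroomType, int]:
        counts: dict[BedroomType, int] = {t: 0 for t in BedroomType}
        for r in self.residents.values():
            counts[r.bedroom_type] += 1
        return counts

    # --- serialization --------------------------------------------------
    @classmethod
    def from_dict(cls, data: Mapping) -> "Facility":
        try:
            zone_specs = data["zones"]
            resident_specs = data["residents"]
        except (KeyError, TypeError) as exc:
            raise FacilityError(
                "facility description must contain 'zones' and 'residents'"
            ) from exc
        zones = []
        for spec in zone_specs:
            try:
                zones.append(
                    Zone(
                        zone_id=str(spec["zone_id"]),
                        zone_class=ZoneClass(spec["zone_class"]),
                        adjacency_class=(
                            AdjacencyClass(spec["adjacency_class"])
                            if spec.get("adjacency_class") is not None
                            else None
                        ),
                        n_transitional_to_common=spec.get("n_transitional_to_common"),
                        sees_common=spec.get("sees_common"),
                        beds_visible_from_common=spec.get("beds_visible_from_common"),
                        capacity=spec.get("capacity"),
                        neighbors=tuple(spec.get("neighbors", ())),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FacilityError(f"invalid zone spec {spec!r}: {exc}") from exc
        residents = []
        for spec in resident_specs:
            try:
                residents.append(
                    Resident(
                        resident_id=str(spec["resident_id"]),
                        bedroom_zone=str(spec["bedroom_zone"]),
                        bedroom_type=BedroomType(spec["bedroom_type"]),
                        sex=spec.get("sex"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FacilityError(f"invalid resident spec {spec!r}: {exc}") from exc
        return cls(zones, residents)

    def to_dict(self) -> dict:
        return {
            "zones": [
                {
                    "zone_id": z.zone_id,
                    "zone_class": z.zone_class.value,
                    "adjacency_class": (
                        z.adjacency_class.value if z.adjacency_class else None
                    ),
                    "n_transitional_to_common": z.n_transitional_to_common,
                    "sees_common": z.sees_common,
                    "beds_visible_from_common": z.beds_visible_from_common,
                    "capacity": z.capacity,
                    "neighbors": list(z.neighbors),
                }
                for z in self.zones.values()
            ],
            "residents": [
                {
                    "resident_id": r.resident_id,
                    "bedroom_zone": r.bedroom_zone,
                    "bedroom_type": r.bedroom_type.value,
                    "sex": r.sex,
                }
                for r in self.residents.values()
            ],
        }

    @classmethod
    def from_yaml(cls, path) -> "Facility":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Privacy instrument
# ---------------------------------------------------------------------------

_ADJACENCY_SCORES = {
    AdjacencyClass.PUBLIC: 0,
    AdjacencyClass.SEMI_PUBLIC: 1,
    AdjacencyClass.SEMI_PRIVATE: 2,
    AdjacencyClass.PRIVATE: 3,
}

#: visibility coding conventions.  Published audit instruments disagree on the
#: direction of the "can residents see the common areas?" item: the scale
#: definition codes seeing as 0 (less privacy), while the applied per-bedroom
#: scores code seeing as 1.  Both are supported; the default reproduces the
#: applied scores.
VISIBILITY_CODINGS = ("sees_scores_one", "sees_scores_zero")
DEFAULT_VISIBILITY_CODING = "sees_scores_one"


def score_occupancy(n_occupants: int) -> int:
    """Occupancy factor: fewer beds, more privacy (5+ -> 0 ... <=2 -> 3)."""
    if not isinstance(n_occupants, (int,)) or isinstance(n_occupants, bool):
        raise FacilityError(f"occupancy must be an integer, got {n_occupants!r}")
    if n_occupants < 1:
        raise FacilityError(f"occupancy must be positive, got {n_occupants}")
    if n_occupants >= 5:
        return 0
    if n_occupants == 4:
        return 1
    if n_occupants == 3:
        return 2
    return 3


def score_adjacency(adjacency_class: AdjacencyClass | str) -> int:
    """Adjacency factor: the more private the neighboring space, the higher."""
    try:
        adjacency_class = AdjacencyClass(adjacency_class)
    except ValueError as exc:
        raise FacilityError(f"unknown adjacency class {adjacency_class!r}") from exc
    return _ADJACENCY_SCORES[adjacency_class]


def score_transitional(n_transitional: int) -> int:
    """Transitional-space factor: count of buffer spaces, capped at 3."""
    if n_transitional < 0:
        raise FacilityError(f"transitional count must be >= 0, got {n_transitional}")
    return min(int(n_transitional), 3)


def score_visibility(
    sees_common: bool, coding: str = DEFAULT_VISIBILITY_CODING
) -> int:
    """Visibility factor: can residents see the common areas from the bedroom?"""
    if coding not in VISIBILITY_CODINGS:
        raise FacilityError(f"unknown visibility coding {coding!r}")
    if coding == "sees_scores_one":
        return 1 if sees_common else 0
    return 0 if sees_common else 1


def score_visual_privacy(beds_visible_from_common: bool) -> int:
    """Visual-privacy factor: beds visible from common areas = 0, screened = 1."""
    return 0 if beds_visible_from_common else 1


def assess_bedroom(
    zone: Zone,
    n_occupants: int,
    visibility_coding: str = DEFAULT_VISIBILITY_CODING,
) -> PrivacyAssessment:
    """Score one bedroom on all five factors.

    ``n_occupants`` is the number of beds in the room (nominal occupancy),
    not the number of study participants sleeping there.
    """
    if not zone.is_bedroom:
        raise FacilityError(f"zone {zone.zone_id!r} is not a bedroom")
    return PrivacyAssessment(
        bedroom_zone=zone.zone_id,
        occupancy_score=score_occupancy(n_occupants),
        adjacency_score=score_adjacency(zone.adjacency_class),
        transitional_score=score_transitional(zone.n_transitional_to_common),
        visibility_score=score_visibility(zone.sees_common, visibility_coding),
        visual_privacy_score=score_visual_privacy(zone.beds_visible_from_common),
    )


def assess_facility(
    facility: Facility,
    visibility_coding: str = DEFAULT_VISIBILITY_CODING,
) -> dict[str, PrivacyAssessment]:
    """Assess every bedroom, keyed by zone id (deterministic, zone-order free)."""
    out: dict[str, PrivacyAssessment] = {}
    for z in sorted(facility.bedrooms(), key=lambda z: z.zone_id):
        n = z.capacity
        if n is None:
            n = len(facility.occupants(z.zone_id))
        out[z.zone_id] = assess_bedroom(z, n, visibility_coding)
    return out
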