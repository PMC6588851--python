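"""Body surface area and clothing-dependent sun-exposed area.

Total body surface area (TBSA) is estimated from height and weight with the
Mosteller formula, ``sqrt(height_cm * weight_kg / 3600)``.  The fraction of
skin left uncovered by a clothing ensemble is scored with an adult
rule-of-nines (Wallace) segment table: each exposed body segment carries a
fixed percentage of TBSA and an ensemble's exposed percentage is the sum
over its exposed segments.

Five canonical ensembles are supported in strict mode (three without hijab,
two with), exposing 18, 48, 25, 13.5 and 8 percent of TBSA respectively.
Compositional mode assembles the exposed-segment list for arbitrary
top/bottom/hijab/socks combinations from the same segment table.

Note one quirk inherited from the source scoring scheme: the face counts
4.5% for a hijab ensemble without socks but 3% for the hijab-with-socks
ensemble (a tighter hijab style leaving less of the face uncovered).  Both
values are kept as distinct named segments so each canonical ensemble
reproduces its published percentage exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

__all__ = [
    "BodyMeasurements",
    "BodySegmentTable",
    "ClothingEnsemble",
    "ExposureProfile",
    "SegmentTableError",
    "UnsupportedEnsembleError",
    "CANONICAL_ENSEMBLES",
    "WALLACE_RULE_OF_NINES",
    "mosteller_tbsa",
    "exposed_segments",
    "exposed_percentage",
    "exposed_area",
    "holick_reference_percentage",
]


class SegmentTableError(KeyError):
    """A required body segment is missing from the segment table."""


class UnsupportedEnsembleError(ValueError):
    """The clothing ensemble is not one of the canonical rows (strict mode)."""


# Full-body Wallace (rule of nines) partition; sums to exactly 100.
WALLACE_RULE_OF_NINES: Mapping[str, float] = {
    "head-and-neck": 9.0,
    "arm-left": 9.0,
    "arm-right": 9.0,
    "leg-left": 18.0,
    "leg-right": 18.0,
    "trunk-front": 18.0,
    "trunk-back": 18.0,
    "perineum": 1.0,
}

#: Default per-segment percentages of TBSA used for exposure scoring.
#: ``arm-exposed-short-sleeve`` is the skin a short sleeve uncovers on one
#: arm (part of upper arm, lower arm, hand); ``leg-exposed-short-bottom``
#: likewise for one leg including the foot.  ``full-arm`` is a whole arm
#: including the hand (used for the reference-area computation).
DEFAULT_SEGMENT_PERCENTAGES: Mapping[str, float] = {
    "head-and-neck": 9.0,
    "face": 4.5,
    "face-tight-hijab": 3.0,
    "hand": 2.5,
    "foot": 2.0,
    "arm-exposed-short-sleeve": 6.0,
    "leg-exposed-short-bottom": 13.5,
    "full-arm": 9.0,
}


@dataclass(frozen=True)
class BodyMeasurements:
    """Height (cm) and weight (kg); both strictly positive."""

    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if not self.height_cm > 0:
            raise ValueError(f"height_cm must be > 0, got {self.height_cm}")
        if not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")


class BodySegmentTable:
    """Mapping from body-segment name to percentage of TBSA in (0, 100]."""

    def __init__(self, percentages: Mapping[str, float] | None = None) -> None:
        pct = dict(DEFAULT_SEGMENT_PERCENTAGES if percentages is None else percentages)
        for name, value in pct.items():
            if not 0 < value <= 100:
                raise ValueError(
                    f"segment {name!r} percentage must be in (0, 100], got {value}"
                )
        self._pct = pct

    def __getitem__(self, name: str) -> float:
        try:
            return self._pct[name]
        except KeyError:
            raise SegmentTableError(
                f"segment table has no entry for {name!r}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._pct

    def items(self):
        return self._pct.items()

    def sum_segments(self, segments: Iterable[str]) -> float:
        return sum(self[name] for name in segments)


@dataclass(frozen=True)
class ClothingEnsemble:
    """Top/bottom length, hijab and socks; determines the exposed segments."""

    top: Literal["long", "short"]
    bottom: Literal["long", "short"]
    hijab: bool = False
    socks: bool = False

    def __post_init__(self) -> None:
        if self.top not in ("long", "short"):
            raise ValueError(f"top must be 'long' or 'short', got {self.top!r}")
        if self.bottom not in ("long", "short"):
            raise ValueError(f"bottom must be 'long' or 'short', got {self.bottom!r}")


#: The five canonical ensembles, keyed by a short id.
CANONICAL_ENSEMBLES: Mapping[str, ClothingEnsemble] = {
    "long-long": ClothingEnsemble("long", "long", hijab=False, socks=False),
    "short-short": ClothingEnsemble("short", "short", hijab=False, socks=False),
    "short-long": ClothingEnsemble("short", "long", hijab=False, socks=False),
    "hijab": ClothingEnsemble("long", "long", hijab=True, socks=False),
    "hijab-socks": ClothingEnsemble("long", "long", hijab=True, socks=True),
}


def mosteller_tbsa(measurements: BodyMeasurements) -> float:
    """Total body surface area in m² by the Mosteller formula.

    TBSA = sqrt(height_cm × weight_kg / 3600); strictly increasing in both
    arguments.
    """
    return math.sqrt(measurements.height_cm * measurements.weight_kg / 3600.0)


def exposed_segments(ensemble: ClothingEnsemble) -> list[str]:
    """Exposed body segments for an ensemble, assembled compositionally.

    Head: hijab leaves only the face (the tight, with-socks style 3% face
    variant; otherwise 4.5%), no hijab exposes head and neck.  Arms: short
    sleeves expose part of each arm including the hand; long sleeves leave
    only the hands.  Legs: a short bottom exposes part of each leg including
    the foot; a long bottom leaves the feet, which socks then cover.
    """
    segments: list[str] = []
    if ensemble.hijab:
        segments.append("face-tight-hijab" if ensemble.socks else "face")
    else:
        segments.append("head-and-neck")
    if ensemble.top == "short":
        segments += ["arm-exposed-short-sleeve"] * 2
    else:
        segments += ["hand"] * 2
    if ensemble.bottom == "short":
        segments += ["leg-exposed-short-bottom"] * 2
    elif not ensemble.socks:
        segments += ["foot"] * 2
    return segments


def exposed_percentage(
    ensemble: ClothingEnsemble,
    table: BodySegmentTable | None = None,
    *,
    mode: Literal["strict", "compositional"] = "strict",
) -> float:
    """Percentage of TBSA exposed to sun for a clothing ensemble.

    In strict mode (default) only the five canonical ensembles are accepted,
    guaranteeing the published percentages (18, 48, 25, 13.5, 8).
    Compositional mode scores any ensemble by summing its exposed segments.
    """
    if table is None:
        table = BodySegmentTable()
    if mode == "strict" and not any(
        ensemble == canonical for canonical in CANONICAL_ENSEMBLES.values()
    ):
        raise UnsupportedEnsembleError(
            f"{ensemble} is not one of the canonical ensembles; "
            "use mode='compositional' for arbitrary combinations"
        )
    return table.sum_segments(exposed_segments(ensemble))


@dataclass(frozen=True)
class ExposureProfile:
    """Exposed percentage of TBSA, exposed area (m²) and TBSA (m²)."""

    exposed_percentage: float
    exposed_area_m2: float
    tbsa_m2: float


def exposed_area(
    measurements: BodyMeasurements,
    ensemble: ClothingEnsemble,
    table: BodySegmentTable | None = None,
    *,
    mode: Literal["strict", "compositional"] = "strict",
) -> ExposureProfile:
    """Absolute sun-exposed body surface area for given measurements and clothing."""
    tbsa = mosteller_tbsa(measurements)
    pct = exposed_percentage(ensemble, table, mode=mode)
    return ExposureProfile(
        exposed_percentage=pct, exposed_area_m2=tbsa * pct / 100.0, tbsa_m2=tbsa
    )


def holick_reference_percentage(table: BodySegmentTable | None = None) -> float:
    """Reference exposed area — face plus both full arms (hands included).

    Exposing this much skin (22.5% of TBSA with the default table) for a
    quarter of the time needed to reach one minimal erythema dose is the
    conventional benchmark for adequate cutaneous vitamin D synthesis.
    """
    if table is None:
        table = BodySegmentTable()
    return table["face"] + 2.0 * table["full-arm"]
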