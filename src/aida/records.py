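"""Domain types for labor cases and per-patient outcome predictions.

A :class:`PatientRecord` holds one labor case: the four intrapartum-ultrasound
geometric parameters (asynclitism degree AD, angle of progression AoP,
head-symphysis distance HSD, midline angle MLA), the asynclitism type, the
physician-determined delivery outcome and the neonatal Apgar scores.

A :class:`PredictionRecord` holds one row of a per-patient prediction table:
the traffic-light zone of each parameter, the AIDA class (number of
parameters outside the green zone), the actual binary outcome, the label
predicted by each of the three learners, and the number of times the patient
was drawn into a test sample.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields


class Zone(str, enum.Enum):
    """Traffic-light risk zone of a single geometric parameter."""

    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"


class AsynclitismType(str, enum.Enum):
    ANTERIOR = "anterior"
    POSTERIOR = "posterior"


class DeliveryOutcome(str, enum.Enum):
    """Four-category delivery outcome recorded by the physician."""

    ICD = "ICD"
    ICD_AFTER_FAILURE = "ICD_after_failure"
    OVD = "OVD"
    SPONTANEOUS = "spontaneous"


class BinaryOutcome(str, enum.Enum):
    """Binary prediction target: intrapartum cesarean delivery or not.

    Cesarean after a failed attempt at vaginal delivery counts as ICD;
    operative vaginal and spontaneous deliveries form the negative class.
    """

    ICD = "ICD"
    NOICD = "NOICD"


#: Collapse of the four-category outcome onto the binary target.
BINARY_OF_OUTCOME = {
    DeliveryOutcome.ICD: BinaryOutcome.ICD,
    DeliveryOutcome.ICD_AFTER_FAILURE: BinaryOutcome.ICD,
    DeliveryOutcome.OVD: BinaryOutcome.NOICD,
    DeliveryOutcome.SPONTANEOUS: BinaryOutcome.NOICD,
}

#: The four geometric parameters, in the canonical column order.
GEOMETRY_COLUMNS = ("ad_mm", "aop_deg", "hsd_mm", "mla_deg")


class ValidationError(ValueError):
    """A field value violates a record invariant."""


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    ad_mm: float
    aop_deg: float
    hsd_mm: float
    mla_deg: float
    asynclitism_type: AsynclitismType
    delivery_outcome: DeliveryOutcome
    apgar1: int
    apgar5: int
    age_years: float | None = None
    gestational_age_weeks: float | None = None
    bmi: float | None = None
    neonatal_weight_g: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "asynclitism_type", AsynclitismType(self.asynclitism_type)
        )
        object.__setattr__(
            self, "delivery_outcome", DeliveryOutcome(self.delivery_outcome)
        )
        if self.ad_mm < 0:
            raise ValidationError(f"ad_mm must be >= 0, got {self.ad_mm}")
        if self.hsd_mm < 0:
            raise ValidationError(f"hsd_mm must be >= 0, got {self.hsd_mm}")
        for name in ("aop_deg", "mla_deg"):
            v = getattr(self, name)
            if not 0 < v < 360:
                raise ValidationError(f"{name} must lie in (0, 360), got {v}")
        for name in ("apgar1", "apgar5"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValidationError(f"{name} must lie in [0, 10], got {v}")

    @property
    def binary_outcome(self) -> BinaryOutcome:
        return BINARY_OF_OUTCOME[self.delivery_outcome]

    def geometry(self) -> tuple[float, float, float, float]:
        """(AD, AoP, HSD, MLA) in the canonical order."""
        return (self.ad_mm, self.aop_deg, self.hsd_mm, self.mla_deg)


@dataclass(frozen=True)
class PredictionRecord:
    patient_id: str
    aida_class: int
    zone_ad: Zone
    zone_aop: Zone
    zone_mla: Zone
    zone_hsd: Zone
    asynclitism_type: AsynclitismType
    actual_outcome: BinaryOutcome
    predicted_svm: BinaryOutcome
    predicted_rf: BinaryOutcome
    predicted_mlp: BinaryOutcome
    n_predictions: int = 1

    def __post_init__(self) -> None:
        for name in ("zone_ad", "zone_aop", "zone_mla", "zone_hsd"):
            object.__setattr__(self, name, Zone(getattr(self, name)))
        object.__setattr__(
            self, "asynclitism_type", AsynclitismType(self.asynclitism_type)
        )
        for name in ("actual_outcome", "predicted_svm", "predicted_rf", "predicted_mlp"):
            object.__setattr__(self, name, BinaryOutcome(getattr(self, name)))
        if self.n_predictions < 1:
            raise ValidationError(
                f"n_predictions must be >= 1, got {self.n_predictions}"
            )
        n_off_green = sum(z is not Zone.GREEN for z in self.zones())
        if self.aida_class != n_off_green:
            raise ValidationError(
                f"aida_class {self.aida_class} does not equal the number of "
                f"non-green zones ({n_off_green}) for patient {self.patient_id}"
            )

    def zones(self) -> tuple[Zone, Zone, Zone, Zone]:
        return (self.zone_ad, self.zone_aop, self.zone_mla, self.zone_hsd)

    def predicted(self, algorithm: str) -> BinaryOutcome:
        """Predicted label for one of the learners ('SVM', 'RF', 'MLP')."""
        try:
            return getattr(self, f"predicted_{algorithm.lower()}")
        except AttributeError:
            raise KeyError(f"unknown algorithm {algorithm!r}") from None
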