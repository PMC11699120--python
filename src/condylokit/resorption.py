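"""Three-criterion radiological classification of condylar resorption.

A condyle is called resorbed when, between the 1-week and 1-year
postoperative timepoints, all three of the following hold:

1. condylar volume loss strictly greater than the segmentation-error margin
   (default 30 mm^3),
2. posterior displacement of the distal segment of at least 2 mm
   (inclusive), and
3. ramal height loss of at least 2 mm (inclusive).

Posterior displacement is read from the distal segment's T1->T2 six-DOF
anteroposterior component with the sign flipped (posterior positive); it is
evaluated once per patient and shared across both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import SixDOF
from .morphometry import CondyleMetrics

__all__ = [
    "Criteria",
    "ResorptionCall",
    "classify_condyle",
    "patient_status",
    "cohort_incidence",
]


@dataclass(frozen=True)
class Criteria:
    """Thresholds of the three-part resorption definition.

    ``volume_loss_threshold`` is strict (loss must exceed it); the
    displacement and height thresholds are inclusive ("at least 2 mm").
    """

    volume_loss_threshold: float = 30.0
    posterior_displacement_threshold: float = 2.0
    ramal_height_loss_threshold: float = 2.0

    def __post_init__(self):
        if min(
            self.volume_loss_threshold,
            self.posterior_displacement_threshold,
            self.ramal_height_loss_threshold,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class ResorptionCall:
    left: bool
    right: bool

    @property
    def status(self) -> str:
        return patient_status(self.left, self.right)

    @property
    def any(self) -> bool:
        return self.left or self.right


def classify_condyle(
    metrics: CondyleMetrics,
    relapse: SixDOF,
    criteria: Criteria = Criteria(),
) -> bool:
    """True iff volume loss (strict), posterior displacement and ramal
    height loss (both inclusive) all cross their thresholds."""
    volume_loss = -metrics.delta_volume
    posterior_displacement = -relapse.t_ap
    height_loss = -metrics.delta_ramal_height
    return bool(
        volume_loss > criteria.volume_loss_threshold
        and posterior_displacement >= criteria.posterior_displacement_threshold
        and height_loss >= criteria.ramal_height_loss_threshold
    )


def patient_status(left: bool, right: bool) -> str:
    if left and right:
        return "bilateral"
    if left:
        return "unilateral_left"
    if right:
        return "unilateral_right"
    return "none"


def cohort_incidence(calls: list[ResorptionCall]) -> dict:
    """Patient- and condyle-level resorption percentages with exact counts."""
    n = len(calls)
    if n == 0:
        raise ValueError("empty cohort")
    statuses = [c.status for c in calls]
    n_bilateral = statuses.count("bilateral")
    n_unilateral = statuses.count("unilateral_left") + statuses.count("unilateral_right")
    n_any = n_bilateral + n_unilateral
    n_condyles = int(np.sum([c.left + c.right for c in calls]))
    return {
        "n_patients": n,
        "n_any": n_any,
        "n_unilateral": n_unilateral,
        "n_bilateral": n_bilateral,
        "n_condyles_flagged": n_condyles,
        "any_pct": 100.0 * n_any / n,
        "unilateral_pct": 100.0 * n_unilateral / n,
        "bilateral_pct": 100.0 * n_bilateral / n,
        "condyle_level_pct": 100.0 * n_condyles / (2 * n),
    }
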