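"""Disease-history parameters: stage mix, survival, recurrence, pathology.

Transitions between preclinical stages are not modelled explicitly; the
stage distribution at diagnosis captures the stage-shift effect of
screening.  After diagnosis, women move through years-since-diagnosis
tunnels (1..20) with stage-specific annual breast-cancer death and
recurrence probabilities, which differ by diagnosis context:

* ``screened``  — diagnosed inside the screening arm's active window;
* ``general``   — diagnosed outside any screening window;
* ``post_rrm``  — diagnosed after risk-reducing mastectomy.

Women alive and recurrence-free 20 years after diagnosis become
long-term survivors facing general-population mortality only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

STAGES = ("DCIS", "STAGE1", "STAGE2", "STAGE3", "STAGE4")
N_STAGES = len(STAGES)
SURVIVOR_CUTOFF = 20  # years since diagnosis


@dataclass(frozen=True)
class StageDistribution:
    """Probabilities over stage at diagnosis; must sum to 1."""

    probabilities: np.ndarray  # length 5, ordered as STAGES

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if p.shape != (N_STAGES,):
            raise ValidationError(f"expected {N_STAGES} stage probabilities")
        if np.any(p < 0):
            raise ValidationError("stage probabilities must be non-negative")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValidationError(
                f"stage probabilities sum to {p.sum():.15g}, not 1"
            )

    def __eq__(self, other):
        if not isinstance(other, StageDistribution):
            return NotImplemented
        return np.array_equal(self.probabilities, other.probabilities)

    def __hash__(self):
        return hash(self.probabilities.tobytes())


def annual_death_prob_from_survival(survival_20yr: float) -> float:
    """Constant annual cause-specific death probability over 20 years.

    Derived from a 20-year survival proportion via a constant annual
    hazard: d = 1 - S^(1/20).
    """
    if not 0.0 < survival_20yr <= 1.0:
        raise ValidationError("20-year survival must lie in (0, 1]")
    return 1.0 - survival_20yr ** (1.0 / SURVIVOR_CUTOFF)


@dataclass(frozen=True)
class ContextParams:
    """Per-diagnosis-context disease history.

    Arrays are (stage, years-since-diagnosis) = (5, 20) annual
    probabilities; entry ``[s, y-1]`` applies during year ``y`` after
    diagnosis.
    """

    stage_distribution: StageDistribution
    bc_death: np.ndarray
    distant_recurrence: np.ndarray
    local_recurrence: np.ndarray

    def __post_init__(self) -> None:
        shape = (N_STAGES, SURVIVOR_CUTOFF)
        for name in ("bc_death", "distant_recurrence", "local_recurrence"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise ValidationError(f"{name} must have shape {shape}")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        if np.any(self.bc_death + self.distant_recurrence > 1.0 + 1e-12):
            raise ValidationError(
                "per-cycle stage exit probabilities (death + distant "
                "recurrence) must sum to at most 1"
            )

    def __eq__(self, other):
        if not isinstance(other, ContextParams):
            return NotImplemented
        return (
            self.stage_distribution == other.stage_distribution
            and np.array_equal(self.bc_death, other.bc_death)
            and np.array_equal(self.distant_recurrence, other.distant_recurrence)
            and np.array_equal(self.local_recurrence, other.local_recurrence)
        )

    def __hash__(self):
        return hash((self.stage_distribution, self.bc_death.tobytes()))


@dataclass(frozen=True)
class PathologyMix:
    """Marginal tumour-pathology proportions used to weight treatment costs."""

    er_positive: float
    erbb2_positive: float
    node_positive: float
    premenopausal: float

    def __post_init__(self) -> None:
        for name in ("er_positive", "erbb2_positive", "node_positive", "premenopausal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "er_positive": self.er_positive,
            "erbb2_positive": self.erbb2_positive,
            "node_positive": self.node_positive,
            "premenopausal": self.premenopausal,
        }


@dataclass(frozen=True)
class ScreeningPerformance:
    """False-positive recall rates and biopsy fractions per modality."""

    fp_recall_mammography: float
    fp_recall_mri: float
    biopsy_fraction_mammography: float
    biopsy_fraction_mri: float

    def __post_init__(self) -> None:
        for name in (
            "fp_recall_mammography",
            "fp_recall_mri",
            "biopsy_fraction_mammography",
            "biopsy_fraction_mri",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class DiseaseHistoryParams:
    screened: ContextParams
    general: ContextParams
    post_rrm: ContextParams
    pathology_screened: PathologyMix
    pathology_general: PathologyMix
    screening_performance: ScreeningPerformance
    recurrence_death: float  # annual BC-death probability in distant recurrence
    survivor_cutoff: int = SURVIVOR_CUTOFF

    def __post_init__(self) -> None:
        if not 0.0 <= self.recurrence_death <= 1.0:
            raise ValidationError("recurrence_death must lie in [0, 1]")
        if self.survivor_cutoff != SURVIVOR_CUTOFF:
            raise ValidationError("survivor cutoff is fixed at 20 years")

    def context(self, name: str) -> ContextParams:
        return {"screened": self.screened, "general": self.general,
                "post_rrm": self.post_rrm}[name]
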