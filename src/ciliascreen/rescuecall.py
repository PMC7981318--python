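"""BS3/PS3 functional-evidence calls from rescue scores.

Validation controls of known classification define the assay's decision
band: the lower cutoff is the mean robust z of the pathogenic controls, the
upper cutoff the mean of the benign controls (optionally pooled with the
wild-type experimental control). A test construct whose mean robust z falls
strictly below the lower cutoff earns PS3 (functional evidence of a
deleterious effect), strictly above the upper cutoff BS3 (no deleterious
effect); anything in between, including values exactly on a cutoff, is
indeterminate. The achievable evidence strength is capped by the number of
validation controls in the relevant class (with three of each, supporting).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .platestats import ConstructSummary


class Call(str, Enum):
    BS3 = "BS3"
    PS3 = "PS3"
    INDETERMINATE = "indeterminate"


class EvidenceStrength(str, Enum):
    SUPPORTING = "supporting"
    MODERATE = "moderate"
    STRONG = "strong"
    VERY_STRONG = "very_strong"
    NOT_APPLICABLE = "not_applicable"


class NonDiscriminatingAssayError(RuntimeError):
    """Pathogenic-control mean does not sit below the benign-control mean."""


@dataclass(frozen=True)
class ControlThresholds:
    lower: float  # mean z of pathogenic validation controls
    upper: float  # mean z of benign validation controls (optionally + WT)
    n_benign: int
    n_pathogenic: int


@dataclass(frozen=True)
class FunctionalCall:
    construct_id: str
    mean_z: float
    call: Call
    strength: EvidenceStrength


def derive_thresholds(
    benign_z,
    pathogenic_z,
    wild_type_z: float | None = None,
    pool_wt: bool = False,
) -> ControlThresholds:
    """Cutoffs from validation-control means. With pool_wt, the wild-type
    experimental control joins the benign pool for the upper cutoff."""
    benign = [float(z) for z in benign_z]
    pathogenic = [float(z) for z in pathogenic_z]
    if not benign:
        raise ValueError("at least one benign validation control is required")
    if not pathogenic:
        raise ValueError("at least one pathogenic validation control is required")
    upper_pool = list(benign)
    if pool_wt:
        if wild_type_z is None:
            raise ValueError("pool_wt requires a wild-type control score")
        upper_pool.append(float(wild_type_z))
    lower = sum(pathogenic) / len(pathogenic)
    upper = sum(upper_pool) / len(upper_pool)
    if lower >= upper:
        raise NonDiscriminatingAssayError(
            f"pathogenic-control mean ({lower:.3g}) is not below the "
            f"benign-control mean ({upper:.3g}); assay cannot discriminate"
        )
    return ControlThresholds(
        lower=lower,
        upper=upper,
        n_benign=len(benign),
        n_pathogenic=len(pathogenic),
    )


def evidence_strength(
    n_benign: int,
    n_pathogenic: int,
    direction: Call,
    moderate_floor: int = 11,
) -> EvidenceStrength:
    """Strength cap keyed on the count of validation controls in the class
    relevant to the call direction: 0 -> not applicable, 1-10 -> supporting,
    >= moderate_floor -> moderate. A deliberately simple, configurable
    stand-in for the full odds-of-pathogenicity tables; with 3+3 controls it
    yields 'supporting', matching the assay's published ceiling."""
    if n_benign < 0 or n_pathogenic < 0:
        raise ValueError("control counts must be non-negative")
    if direction is Call.BS3:
        n = n_benign
    elif direction is Call.PS3:
        n = n_pathogenic
    else:
        return EvidenceStrength.NOT_APPLICABLE
    if n == 0:
        return EvidenceStrength.NOT_APPLICABLE
    if n >= moderate_floor:
        return EvidenceStrength.MODERATE
    return EvidenceStrength.SUPPORTING


def call_variant(
    summary: ConstructSummary | float,
    thresholds: ControlThresholds,
    construct_id: str | None = None,
) -> FunctionalCall:
    """Trichotomize a construct's mean robust z against the control cutoffs."""
    if isinstance(summary, ConstructSummary):
        mean_z = summary.mean_z
        cid = summary.construct_id
    else:
        mean_z = float(summary)
        cid = construct_id or ""
    if thresholds.lower >= thresholds.upper:
        raise NonDiscriminatingAssayError("thresholds do not discriminate")
    if mean_z > thresholds.upper:
        call = Call.BS3
    elif mean_z < thresholds.lower:
        call = Call.PS3
    else:
        call = Call.INDETERMINATE
    return FunctionalCall(
        construct_id=cid,
        mean_z=mean_z,
        call=call,
        strength=evidence_strength(
            thresholds.n_benign, thresholds.n_pathogenic, call
        ),
    )
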