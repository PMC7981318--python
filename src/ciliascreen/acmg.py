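"""ACMG/AMP variant annotation and 5-tier classification.

Implements the gene-specific minor-allele-frequency cutoff used for
autosomal dominant retinitis pigmentosa caused by PRPF31 variants, assembly
of coded evidence criteria (population frequency, in-silico predictions
consumed as input annotations, assay-derived PS3/BS3 at modified strength,
plus user-supplied codes for evidence types that cannot be computed), and
the published combining rules mapping a criteria set to one of pathogenic /
likely pathogenic / VUS / likely benign / benign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .rescuecall import Call, EvidenceStrength, FunctionalCall

# ---------------------------------------------------------------------------
# MAF cutoff


@dataclass(frozen=True)
class MafCutoffParams:
    """Disease-model factors behind the allele-frequency cutoff.

    cutoff = prevalence * prop_inheritance * gene_fraction / allelic_divisor
             * penetrance_factor

    Defaults encode autosomal dominant RP due to PRPF31: disease prevalence
    1/3000, a quarter of RP autosomal dominant, 5.5% of adRP attributable to
    this gene, one causal allele (divide by 2), and a tenfold allowance for
    incomplete penetrance.
    """

    prevalence: float = 1.0 / 3000.0
    prop_inheritance: float = 0.25
    gene_fraction: float = 0.055
    allelic_divisor: float = 2.0
    penetrance_factor: float = 10.0


def maf_cutoff(params: MafCutoffParams = MafCutoffParams()) -> float:
    for name in (
        "prevalence",
        "prop_inheritance",
        "gene_fraction",
        "allelic_divisor",
        "penetrance_factor",
    ):
        if getattr(params, name) <= 0:
            raise ValueError(f"{name} must be positive")
    return (
        params.prevalence
        * params.prop_inheritance
        * params.gene_fraction
        / params.allelic_divisor
        * params.penetrance_factor
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (reporting helper)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# criteria model


class Code(str, Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STANDALONE = "standalone"


def default_strength(code: Code) -> Strength:
    name = code.value
    if name == "PVS1":
        return Strength.VERY_STRONG
    if name.startswith("PS") or name.startswith("BS"):
        return Strength.STRONG
    if name.startswith("PM"):
        return Strength.MODERATE
    if name == "BA1":
        return Strength.STANDALONE
    return Strength.SUPPORTING  # PP*, BP*


def is_pathogenic_code(code: Code) -> bool:
    return code.value[0] == "P"


_FUNCTIONAL_STRENGTH = {
    EvidenceStrength.SUPPORTING: Strength.SUPPORTING,
    EvidenceStrength.MODERATE: Strength.MODERATE,
    EvidenceStrength.STRONG: Strength.STRONG,
    EvidenceStrength.VERY_STRONG: Strength.VERY_STRONG,
}


@dataclass(frozen=True)
class Criterion:
    code: Code
    strength: Strength

    @classmethod
    def default(cls, code: Code) -> "Criterion":
        return cls(code, default_strength(code))


@dataclass
class CriteriaSet:
    applied: list[Criterion] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.applied]
        if len(codes) != len(set(codes)):
            raise ValueError("a criteria code may appear only once")

    @property
    def codes(self) -> set[Code]:
        return {c.code for c in self.applied}


class Verdict(str, Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    UNAVAILABLE = "unavailable"


class SpliceImpact(str, Enum):
    PREDICTED_CHANGE = "predicted_change"
    NO_CHANGE = "no_change"
    UNAVAILABLE = "unavailable"


PROTEIN_PREDICTORS = ("align_gvgd", "sift", "polyphen2")


@dataclass
class VariantRecord:
    gene: str
    transcript: str = ""
    cdna_change: str = ""
    protein_change: str = ""
    n_reported_cases: int = 0
    insilico_verdicts: dict[str, Verdict] = field(default_factory=dict)
    splice_impact: SpliceImpact = SpliceImpact.UNAVAILABLE
    domain_location: str = ""
    maf: float | None = None
    same_codon_known_variant: bool = False

    def __post_init__(self) -> None:
        self.insilico_verdicts = {
            k: Verdict(v) for k, v in self.insilico_verdicts.items()
        }
        self.splice_impact = SpliceImpact(self.splice_impact)
        if self.maf is not None and not 0 <= self.maf <= 1:
            raise ValueError(f"maf must be in [0,1], got {self.maf}")
        if self.n_reported_cases < 0:
            raise ValueError("n_reported_cases must be >= 0")


# ---------------------------------------------------------------------------
# criteria assembly


def frequency_evidence(
    maf: float | None,
    cutoff: float,
    ba1_threshold: float = 0.05,
) -> Criterion:
    """Exactly one frequency code: PM2 when the allele is absent or rarer
    than the disease-model cutoff, BA1 when common enough to stand alone as
    benign, BS1 in between."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if maf is None:
        return Criterion.default(Code.PM2)
    if not 0 <= maf <= 1:
        raise ValueError(f"maf must be in [0,1], got {maf}")
    if maf < cutoff:
        return Criterion.default(Code.PM2)
    if maf >= ba1_threshold:
        return Criterion.default(Code.BA1)
    return Criterion.default(Code.BS1)


def assemble_criteria(
    variant: VariantRecord,
    functional: FunctionalCall | None = None,
    *,
    cutoff: float | None = None,
    ba1_threshold: float = 0.05,
    pp3_min_damaging: int = 2,
    overrides: list[Criterion] | None = None,
) -> CriteriaSet:
    """Merge computed evidence with user-supplied overrides.

    Computed: the frequency code; PP3 when at least `pp3_min_damaging` of the
    three protein predictors call the variant damaging and the splice
    consensus does not predict a change; BP4 when every available predictor
    calls it tolerated; PS3/BS3 at the functional call's strength when the
    assay result is not indeterminate. Evidence that cannot be computed
    (segregation, de novo, case counts, ...) enters via overrides; an
    override replaces a computed code, but the same code twice among the
    overrides is an error.
    """
    if cutoff is None:
        cutoff = maf_cutoff()
    crits: dict[Code, Criterion] = {}

    freq = frequency_evidence(variant.maf, cutoff, ba1_threshold)
    crits[freq.code] = freq

    verdicts = [
        variant.insilico_verdicts.get(tool, Verdict.UNAVAILABLE)
        for tool in PROTEIN_PREDICTORS
    ]
    n_damaging = sum(v is Verdict.DAMAGING for v in verdicts)
    available = [v for v in verdicts if v is not Verdict.UNAVAILABLE]
    if (
        n_damaging >= pp3_min_damaging
        and variant.splice_impact is not SpliceImpact.PREDICTED_CHANGE
    ):
        crits[Code.PP3] = Criterion.default(Code.PP3)
    elif available and all(v is Verdict.TOLERATED for v in available):
        crits[Code.BP4] = Criterion.default(Code.BP4)

    if functional is not None and functional.call is not Call.INDETERMINATE:
        strength = _FUNCTIONAL_STRENGTH.get(functional.strength)
        if strength is not None:
            code = Code.PS3 if functional.call is Call.PS3 else Code.BS3
            crits[code] = Criterion(code, strength)

    if overrides:
        seen: set[Code] = set()
        for ov in overrides:
            if ov.code in seen:
                raise ValueError(f"contradictory overrides: {ov.code.value} twice")
            seen.add(ov.code)
            crits[ov.code] = ov

    return CriteriaSet(applied=sorted(crits.values(), key=lambda c: c.code.value))


# ---------------------------------------------------------------------------
# combining rules


class Tier(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


@dataclass(frozen=True)
class Classification:
    tier: Tier
    rationale: tuple[str, ...]


def classify(criteria: CriteriaSet) -> Classification:
    """Apply the published combining rules, counting each criterion at its
    (possibly modified) strength. Conflicting pathogenic and benign
    combinations, or insufficient evidence, yield VUS."""
    nvs = ns = nm = nsup = 0
    ba1 = False
    nbs = nbp = 0
    for c in criteria.applied:
        if is_pathogenic_code(c.code):
            if c.strength is Strength.VERY_STRONG:
                nvs += 1
            elif c.strength is Strength.STRONG:
                ns += 1
            elif c.strength is Strength.MODERATE:
                nm += 1
            elif c.strength is Strength.SUPPORTING:
                nsup += 1
        else:
            if c.strength is Strength.STANDALONE:
                ba1 = True
            elif c.strength in (Strength.STRONG, Strength.VERY_STRONG):
                nbs += 1
            else:
                nbp += 1

    path_rules: list[str] = []
    if nvs >= 1 and (
        ns >= 1 or nm >= 2 or (nm == 1 and nsup == 1) or nsup >= 2
    ):
        path_rules.append("1 very-strong + (>=1 strong | >=2 moderate | "
                          "1 moderate + 1 supporting | >=2 supporting)")
    if nvs >= 2:
        path_rules.append(">=2 very-strong")
    if ns >= 2:
        path_rules.append(">=2 strong")
    if ns == 1 and (nm >= 3 or (nm == 2 and nsup >= 2) or (nm == 1 and nsup >= 4)):
        path_rules.append("1 strong + (>=3 moderate | 2 moderate + >=2 supporting"
                          " | 1 moderate + >=4 supporting)")

    lp_rules: list[str] = []
    if nvs == 1 and nm == 1:
        lp_rules.append("1 very-strong + 1 moderate")
    if ns == 1 and 1 <= nm <= 2:
        lp_rules.append("1 strong + 1-2 moderate")
    if ns == 1 and nsup >= 2:
        lp_rules.append("1 strong + >=2 supporting")
    if nm >= 3:
        lp_rules.append(">=3 moderate")
    if nm == 2 and nsup >= 2:
        lp_rules.append("2 moderate + >=2 supporting")
    if nm == 1 and nsup >= 4:
        lp_rules.append("1 moderate + >=4 supporting")

    benign_rules: list[str] = []
    if ba1:
        benign_rules.append("stand-alone benign frequency")
    if nbs >= 2:
        benign_rules.append(">=2 benign strong")

    lb_rules: list[str] = []
    if nbs == 1 and nbp == 1:
        lb_rules.append("1 benign strong + 1 benign supporting")
    if nbp >= 2:
        lb_rules.append(">=2 benign supporting")

    pathogenic_side = bool(path_rules or lp_rules)
    benign_side = bool(benign_rules or lb_rules)
    if pathogenic_side and benign_side:
        return Classification(
            tier=Tier.VUS,
            rationale=("conflicting pathogenic and benign evidence",),
        )
    if path_rules:
        return Classification(tier=Tier.PATHOGENIC, rationale=tuple(path_rules))
    if lp_rules:
        return Classification(tier=Tier.LIKELY_PATHOGENIC, rationale=tuple(lp_rules))
    if benign_rules:
        return Classification(tier=Tier.BENIGN, rationale=tuple(benign_rules))
    if lb_rules:
        return Classification(tier=Tier.LIKELY_BENIGN, rationale=tuple(lb_rules))
    return Classification(tier=Tier.VUS, rationale=("insufficient evidence",))
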