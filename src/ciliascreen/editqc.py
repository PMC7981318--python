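"""QC arithmetic for CRISPR-edited clones.

Two small calculations performed on the edited cell lines: the percentage
of junction-spanning reads carrying the heterozygous insertion (per RNA
fraction), and the mutant/wild-type transcript-dosage ratio used to judge
consistency with haploinsufficiency.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum


class RnaFraction(str, Enum):
    NUCLEAR = "nuclear"
    CYTOPLASMIC = "cytoplasmic"


@dataclass(frozen=True)
class JunctionReadCounts:
    fraction_label: RnaFraction
    n_ref: int  # wild-type junction reads
    n_ins: int  # insertion-bearing junction reads

    def __post_init__(self) -> None:
        if self.n_ref < 0 or self.n_ins < 0:
            raise ValueError("read counts must be non-negative")
        if self.n_ref + self.n_ins == 0:
            raise ValueError("a fraction needs at least one junction read")


def insertion_fraction(counts: JunctionReadCounts | None = None,
                       n_ref: int | None = None,
                       n_ins: int | None = None) -> float:
    """Percentage of junction reads carrying the insertion, rounded
    half-away-from-zero to one decimal place."""
    if counts is not None:
        n_ref, n_ins = counts.n_ref, counts.n_ins
    if n_ref is None or n_ins is None:
        raise ValueError("provide JunctionReadCounts or both n_ref and n_ins")
    if n_ref < 0 or n_ins < 0:
        raise ValueError("read counts must be non-negative")
    total = n_ref + n_ins
    if total == 0:
        raise ValueError("zero total reads: insertion fraction undefined")
    pct = Decimal(100 * n_ins) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DosageRatio:
    value_mut: float  # transcript abundance (FPKM) in the edited line
    value_wt: float  # same transcript in the unedited sister line
    ratio: float
    haploinsufficiency_consistent: bool


def dosage_ratio(
    mut: float,
    wt: float,
    band: tuple[float, float] = (0.35, 0.65),
) -> DosageRatio:
    """Mutant/wild-type abundance ratio; flagged consistent with
    haploinsufficiency when it falls inside `band` (roughly a 50% reduction)."""
    if wt <= 0:
        raise ValueError("wild-type abundance must be positive")
    if mut < 0:
        raise ValueError("mutant abundance must be non-negative")
    ratio = mut / wt
    lo, hi = band
    return DosageRatio(
        value_mut=float(mut),
        value_wt=float(wt),
        ratio=float(ratio),
        haploinsufficiency_consistent=lo <= ratio <= hi,
    )


def allele_bias_note(
    nuclear_pct: float,
    cytoplasmic_pct: float,
    low_threshold: float = 25.0,
) -> str | None:
    """When the insertion allele is under-represented (well below the 50%
    expected from balanced biallelic expression) in BOTH fractions, the
    simplest reading is preferential expression from the wild-type allele
    rather than cytoplasmic degradation of the mutant transcript."""
    if nuclear_pct < low_threshold and cytoplasmic_pct < low_threshold:
        return (
            "insertion allele under-represented in nuclear and cytoplasmic "
            "RNA alike: consistent with preferential expression from the "
            "wild-type allele (not with cytoplasm-restricted decay)"
        )
    return None
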