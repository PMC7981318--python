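"""Bundled editable inputs: the PRPF31 variant panel (five tested VUS, three
common synonymous benign validation controls with their population
frequencies, three published pathogenic missense validation controls)."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .acmg import SpliceImpact, VariantRecord, Verdict
from .rescuecall import Call

VARIANT_FIXTURE = "prpf31_variants.csv"


def load_variant_table() -> pd.DataFrame:
    with resources.files("ciliascreen.data").joinpath(VARIANT_FIXTURE).open() as fh:
        return pd.read_csv(fh)


def variant_records(table: pd.DataFrame | None = None) -> list[VariantRecord]:
    if table is None:
        table = load_variant_table()
    records = []
    for _, row in table.iterrows():
        maf = row.get("maf")
        records.append(
            VariantRecord(
                gene=row["gene"],
                transcript=row.get("transcript", ""),
                cdna_change=row.get("cdna_change", ""),
                protein_change=row.get("protein_change", ""),
                n_reported_cases=int(row.get("n_reported_cases", 0) or 0),
                insilico_verdicts={
                    tool: Verdict(str(row.get(tool, "unavailable")))
                    for tool in ("align_gvgd", "sift", "polyphen2")
                },
                splice_impact=SpliceImpact(
                    str(row.get("splice_impact", "unavailable"))
                ),
                domain_location=str(row.get("domain_location", "") or ""),
                maf=None if pd.isna(maf) else float(maf),
                same_codon_known_variant=bool(row.get("same_codon_known_variant")),
            )
        )
    return records


def fixture_functional_calls(table: pd.DataFrame | None = None) -> dict[str, Call]:
    """protein_change -> reported assay call, where the fixture states one."""
    if table is None:
        table = load_variant_table()
    out = {}
    for _, row in table.iterrows():
        call = row.get("functional_call")
        if isinstance(call, str) and call:
            out[row["protein_change"]] = Call(call)
    return out
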