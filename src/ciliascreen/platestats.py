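"""Robust z scoring of constructs against the mock-transfected control.

For each construct on a plate, the summary value x is the median of its
technical-replicate well values (each well value being the median of that
well's usable fields), and

    robust z = (x - median(mock)) / MAD(mock)

where the mock population is, by default, every usable mock field value on
the plate and MAD is the unscaled median absolute deviation. Scores are
aggregated across biological replicates (plates) as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate import PlateLayout, Role

METRIC_COLUMNS = {
    "pct_single_cilium": "pct_single_cilium",
    "cell_count": "n_nuclei",
}


class NonScorableError(RuntimeError):
    """The mock population has zero spread; the plate cannot be scored."""


@dataclass(frozen=True)
class NegControlStats:
    plate_id: str
    metric: str
    center: float  # median of mock values
    spread: float  # unscaled MAD of mock values
    n_values: int


@dataclass(frozen=True)
class RobustZScore:
    construct_id: str
    plate_id: str
    metric: str
    x: float
    center: float
    spread: float
    z: float


@dataclass(frozen=True)
class ConstructSummary:
    construct_id: str
    metric: str
    z_values: tuple[float, ...]
    mean_z: float
    sem_z: float | None  # None (flagged undefined) when n_plates < 2
    n_plates: int


def median_abs_dev(values) -> float:
    """Unscaled MAD: median(|v - median(values)|)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_abs_dev requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("median_abs_dev requires finite values")
    return float(np.median(np.abs(arr - np.median(arr))))


def robust_z(x: float, neg_values) -> float:
    """(x - median(neg)) / MAD(neg); refuses to score when MAD is zero."""
    arr = np.asarray(neg_values, dtype=float)
    center = float(np.median(arr))
    spread = median_abs_dev(arr)
    if spread == 0:
        raise NonScorableError(
            "MAD of the negative-control population is zero; plate non-scorable"
        )
    return (float(x) - center) / spread


def _usable(fields: pd.DataFrame) -> pd.DataFrame:
    if "usable" in fields.columns:
        return fields[fields["usable"].astype(bool)]
    return fields[fields["n_whole_cells"] > 0]


def neg_control_stats(
    fields: pd.DataFrame,
    layout: PlateLayout,
    metric: str = "pct_single_cilium",
    mock_population: str = "fields",
) -> NegControlStats:
    """Median/MAD of the mock-transfected population on this plate.

    mock_population: "fields" pools every usable mock field value (default);
    "well_medians" uses the mock wells' per-well medians instead.
    """
    col = METRIC_COLUMNS[metric]
    mock_wells = layout.wells_for_role(Role.MOCK)
    sub = _usable(fields)
    sub = sub[sub["well"].isin(mock_wells)]
    if not len(sub):
        raise ValueError("no usable mock fields on this plate")
    if mock_population == "fields":
        values = sub[col].to_numpy(dtype=float)
    elif mock_population == "well_medians":
        values = sub.groupby("well")[col].median().to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mock_population {mock_population!r}")
    return NegControlStats(
        plate_id=layout.plate_id,
        metric=metric,
        center=float(np.median(values)),
        spread=median_abs_dev(values),
        n_values=len(values),
    )


def score_construct(
    fields: pd.DataFrame,
    layout: PlateLayout,
    construct_id: str,
    metric: str = "pct_single_cilium",
    mock_population: str = "fields",
) -> RobustZScore:
    """Robust z of one construct on one plate: per-well medians of usable
    fields, construct value = median of its well values, normalized to the
    mock population."""
    col = METRIC_COLUMNS[metric]
    wells = layout.replicate_group.get(construct_id)
    if not wells:
        raise KeyError(f"construct {construct_id!r} not on plate {layout.plate_id}")
    sub = _usable(fields)
    sub = sub[sub["well"].isin(wells)]
    if not len(sub):
        raise ValueError(
            f"no usable fields for construct {construct_id!r} on {layout.plate_id}"
        )
    well_medians = sub.groupby("well")[col].median()
    x = float(well_medians.median())
    stats = neg_control_stats(fields, layout, metric, mock_population)
    if stats.spread == 0:
        raise NonScorableError(
            f"plate {layout.plate_id} non-scorable for {metric}: mock MAD is zero"
        )
    return RobustZScore(
        construct_id=construct_id,
        plate_id=layout.plate_id,
        metric=metric,
        x=x,
        center=stats.center,
        spread=stats.spread,
        z=(x - stats.center) / stats.spread,
    )


def score_plate(
    fields: pd.DataFrame,
    layout: PlateLayout,
    metrics: tuple[str, ...] = ("pct_single_cilium", "cell_count"),
    mock_population: str = "fields",
) -> pd.DataFrame:
    """Score every non-media construct on the plate for each metric."""
    rows = []
    for metric in metrics:
        for construct in layout.constructs:
            s = score_construct(fields, layout, construct, metric, mock_population)
            rows.append(
                {
                    "construct": s.construct_id,
                    "plate": s.plate_id,
                    "role": layout.role_of(construct).value,
                    "metric": s.metric,
                    "x": s.x,
                    "center": s.center,
                    "spread": s.spread,
                    "z": s.z,
                }
            )
    return pd.DataFrame(rows)


def aggregate_replicates(per_plate: list[RobustZScore]) -> ConstructSummary:
    """Mean and SEM of a construct's z across biological replicates."""
    if not per_plate:
        raise ValueError("aggregate_replicates requires at least one plate score")
    constructs = {s.construct_id for s in per_plate}
    metrics = {s.metric for s in per_plate}
    if len(constructs) > 1 or len(metrics) > 1:
        raise ValueError("scores must share one construct and one metric")
    zs = np.array([s.z for s in per_plate], dtype=float)
    n = len(zs)
    sem = float(np.std(zs, ddof=1) / np.sqrt(n)) if n >= 2 else None
    return ConstructSummary(
        construct_id=per_plate[0].construct_id,
        metric=per_plate[0].metric,
        z_values=tuple(float(z) for z in zs),
        mean_z=float(zs.mean()),
        sem_z=sem,
        n_plates=n,
    )


def summarize_plates(score_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-plate score tables into a construct summary table."""
    allscores = pd.concat(score_tables, ignore_index=True)
    rows = []
    for (construct, metric), grp in allscores.groupby(["construct", "metric"]):
        scores = [
            RobustZScore(
                construct_id=construct,
                plate_id=r["plate"],
                metric=metric,
                x=r["x"],
                center=r["center"],
                spread=r["spread"],
                z=r["z"],
            )
            for _, r in grp.iterrows()
        ]
        summ = aggregate_replicates(scores)
        rows.append(
            {
                "construct": construct,
                "role": grp["role"].iloc[0],
                "metric": metric,
                "mean_z": summ.mean_z,
                "sem_z": np.nan if summ.sem_z is None else summ.sem_z,
                "n_plates": summ.n_plates,
            }
        )
    return pd.DataFrame(rows)
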