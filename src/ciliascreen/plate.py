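"""96-well plate layouts for the ciliogenesis rescue assay.

A plate maps wells to transfected constructs and their experimental role.
The outer perimeter of the plate carries media only (no cells), to limit
evaporation/edge effects; each construct occupies a fixed number of inner
wells (technical replicates, default 3), and exactly one construct per
plate is the mock-transfected negative control against which robust z
scores are computed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from enum import Enum

import yaml

MEDIA_CONSTRUCT = "media"


class Role(str, Enum):
    MOCK = "mock"
    EMPTY_VECTOR = "empty_vector"
    WILD_TYPE = "wild_type"
    BENIGN_CONTROL = "benign_control"
    PATHOGENIC_CONTROL = "pathogenic_control"
    TEST_VARIANT = "test_variant"
    MEDIA_ONLY = "media_only"


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> conventional well id, e.g. (1, 1) -> 'B02'."""
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


class LayoutError(ValueError):
    pass


@dataclass
class PlateLayout:
    plate_id: str
    n_rows: int = 8
    n_cols: int = 12
    # well id -> (construct_id, role)
    well_assignments: dict[str, tuple[str, Role]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.well_assignments = {
            w: (c, Role(r)) for w, (c, r) in self.well_assignments.items()
        }
        self.validate()

    # -- geometry helpers -------------------------------------------------
    def is_outer(self, well_id: str) -> bool:
        row = string.ascii_uppercase.index(well_id[0])
        col = int(well_id[1:]) - 1
        return row in (0, self.n_rows - 1) or col in (0, self.n_cols - 1)

    @property
    def inner_capacity(self) -> int:
        return (self.n_rows - 2) * (self.n_cols - 2)

    # -- derived views -----------------------------------------------------
    @property
    def replicate_group(self) -> dict[str, list[str]]:
        """construct_id -> sorted list of wells carrying it (media excluded)."""
        groups: dict[str, list[str]] = {}
        for well, (construct, role) in sorted(self.well_assignments.items()):
            if role is Role.MEDIA_ONLY:
                continue
            groups.setdefault(construct, []).append(well)
        return groups

    def wells_for_role(self, role: Role) -> list[str]:
        return sorted(
            w for w, (_, r) in self.well_assignments.items() if r is role
        )

    @property
    def mock_construct(self) -> str:
        mocks = {
            c for _, (c, r) in self.well_assignments.items() if r is Role.MOCK
        }
        return next(iter(mocks))

    def role_of(self, construct_id: str) -> Role:
        for _, (c, r) in self.well_assignments.items():
            if c == construct_id:
                return r
        raise KeyError(construct_id)

    @property
    def constructs(self) -> list[str]:
        return sorted(self.replicate_group)

    def validate(self) -> None:
        for well, (construct, role) in self.well_assignments.items():
            if self.is_outer(well) and role is not Role.MEDIA_ONLY:
                raise LayoutError(
                    f"outer well {well} must be media_only, got {role.value}"
                )
        n_outer = 2 * self.n_cols + 2 * (self.n_rows - 2)
        outer_media = sum(
            1
            for w, (_, r) in self.well_assignments.items()
            if self.is_outer(w) and r is Role.MEDIA_ONLY
        )
        if outer_media != n_outer:
            raise LayoutError(
                f"expected all {n_outer} outer wells media_only, got {outer_media}"
            )
        mocks = {
            c for _, (c, r) in self.well_assignments.items() if r is Role.MOCK
        }
        if len(mocks) != 1:
            raise LayoutError(f"expected exactly one mock construct, got {len(mocks)}")
        for construct, wells in self.replicate_group.items():
            if not wells:
                raise LayoutError(f"construct {construct} has no wells")

    # -- IO ----------------------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "plate_id": self.plate_id,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "wells": {
                w: {"construct": c, "role": r.value}
                for w, (c, r) in sorted(self.well_assignments.items())
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            plate_id=doc["plate_id"],
            n_rows=doc.get("n_rows", 8),
            n_cols=doc.get("n_cols", 12),
            well_assignments={
                w: (v["construct"], Role(v["role"]))
                for w, v in doc["wells"].items()
            },
        )


def build_layout(
    assignments: list[tuple[str, Role]],
    plate_id: str = "plate01",
    n_rows: int = 8,
    n_cols: int = 12,
    wells_per_construct: int = 3,
) -> PlateLayout:
    """Fill inner wells row-major with `wells_per_construct` technical
    replicates per construct; all remaining wells are media only."""
    needed = len(assignments) * wells_per_construct
    capacity = (n_rows - 2) * (n_cols - 2)
    if needed > capacity:
        raise LayoutError(
            f"{len(assignments)} constructs x {wells_per_construct} wells "
            f"= {needed} exceeds inner capacity {capacity}"
        )
    inner = [
        well_name(r, c)
        for r in range(1, n_rows - 1)
        for c in range(1, n_cols - 1)
    ]
    wells: dict[str, tuple[str, Role]] = {}
    i = 0
    for construct, role in assignments:
        for _ in range(wells_per_construct):
            wells[inner[i]] = (construct, Role(role))
            i += 1
    for w in inner[i:]:
        wells[w] = (MEDIA_CONSTRUCT, Role.MEDIA_ONLY)
    for r in range(n_rows):
        for c in range(n_cols):
            w = well_name(r, c)
            if w not in wells:
                wells[w] = (MEDIA_CONSTRUCT, Role.MEDIA_ONLY)
    return PlateLayout(
        plate_id=plate_id,
        n_rows=n_rows,
        n_cols=n_cols,
        well_assignments=wells,
    )
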