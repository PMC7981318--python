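"""Seeded synthetic two-channel imaging plates with ground truth.

Emulates the rescue assay's raw data: 96-well optical plates whose outer
wells hold media only, six imaged fields per inner well, a nuclear-stain
channel (DAPI-like) and a cilium-marker channel (ARL13B-like). Nuclei are
non-overlapping ellipses; each cell independently grows 0, 1 or 2 cilia
(short bright rods adjacent to its nucleus); micronuclei are small blobs
near nuclei with Poisson-distributed counts. A multiplicative vignette and
additive Gaussian noise are applied.

Every random draw happens in the sampling stage, before rasterization, so
the ground-truth table produced by the fast truth-only path is bit-identical
to the truth accompanying fully rendered images under the same seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk, ellipse, line_aa

from .plate import PlateLayout, Role

TRUTH_COLUMNS = [
    "plate",
    "well",
    "field",
    "cell_id",
    "x",
    "y",
    "nucleus_area",
    "touches_border",
    "n_cilia",
    "n_micronuclei",
]


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed without overlap."""


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated field of view."""

    well_id: str = "B02"
    field_index: int = 1
    n_cells: int = 100
    ciliation_prob: float = 0.25
    multi_cilium_prob: float = 0.05
    micronucleus_rate: float = 0.1
    nucleus_radius_px: tuple[float, float] = (9.0, 1.5)
    cilium_length_px: tuple[float, float] = (5.0, 15.0)
    background_level: float = 200.0
    noise_sd: float = 8.0
    edge_gradient: float = 0.9
    seed: int = 0
    image_shape: tuple[int, int] = (512, 512)
    nucleus_intensity: float = 2400.0
    cilium_intensity: float = 1600.0
    cell_expansion_px: float = 25.0  # used only for the truth border flag

    def validate(self) -> None:
        if self.ciliation_prob < 0 or self.multi_cilium_prob < 0:
            raise ValueError("probabilities must be non-negative")
        if self.ciliation_prob + self.multi_cilium_prob > 1.0 + 1e-12:
            raise ValueError("ciliation_prob + multi_cilium_prob must be <= 1")
        if not 1 <= self.field_index <= 6:
            raise ValueError("field_index must be in 1..6 (six fields per well)")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.micronucleus_rate < 0:
            raise ValueError("micronucleus_rate must be >= 0")
        if not 0 < self.edge_gradient <= 1:
            raise ValueError("edge_gradient must be in (0, 1]")
        if min(self.image_shape) < 10 * self.nucleus_radius_px[0]:
            raise ValueError(
                "image dimensions must be >= 10x the mean nucleus radius"
            )


@dataclass(frozen=True)
class CellTruth:
    cell_id: int
    centroid: tuple[float, float]  # (row, col)
    nucleus_area_px: float
    touches_border: bool
    n_cilia: int
    n_micronuclei: int


@dataclass
class SyntheticField:
    nuclear_channel: np.ndarray
    cilium_channel: np.ndarray
    truth: list[CellTruth]


@dataclass
class _Geometry:
    """Everything the rasterizer needs; fully determined by sampling."""

    nuclei: list[tuple[float, float, float, float, float, float]] = field(
        default_factory=list
    )  # (row, col, major, minor, orientation, intensity)
    micronuclei: list[tuple[float, float, float]] = field(default_factory=list)
    cilia: list[tuple[float, float, float, float]] = field(default_factory=list)


def _sample_field(spec: FieldSpec, rng: np.random.Generator):
    """Draw all stochastic content of a field. Consumes rng in a fixed order."""
    spec.validate()
    h, w = spec.image_shape
    mean_r, sd_r = spec.nucleus_radius_px
    geom = _Geometry()
    centers: list[tuple[float, float, float]] = []  # (row, col, major)

    max_tries = 200
    for i in range(spec.n_cells):
        major = float(
            np.clip(rng.normal(mean_r, sd_r), 0.5 * mean_r, 1.8 * mean_r)
        )
        ratio = rng.uniform(0.7, 1.0)
        minor = major * ratio
        orient = rng.uniform(0, math.pi)
        placed = False
        for _ in range(max_tries):
            cr = rng.uniform(major + 1, h - major - 2)
            cc = rng.uniform(major + 1, w - major - 2)
            ok = True
            for (pr, pc, pm) in centers:
                if (cr - pr) ** 2 + (cc - pc) ** 2 < (major + pm + 2.0) ** 2:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"placed only {i} of {spec.n_cells} nuclei without overlap; "
                f"achievable density ~{i / (h * w):.2e} cells/px^2"
            )
        centers.append((cr, cc, major))
        intensity = rng.uniform(0.85, 1.15) * spec.nucleus_intensity
        geom.nuclei.append((cr, cc, major, minor, orient, intensity))

    # cilia counts per cell
    u = rng.random(spec.n_cells)
    n_cilia = np.zeros(spec.n_cells, dtype=int)
    n_cilia[u < spec.ciliation_prob] = 1
    n_cilia[
        (u >= spec.ciliation_prob)
        & (u < spec.ciliation_prob + spec.multi_cilium_prob)
    ] = 2

    # micronuclei counts per cell
    n_micro = (
        rng.poisson(spec.micronucleus_rate, spec.n_cells)
        if spec.n_cells
        else np.zeros(0, dtype=int)
    )

    truth: list[CellTruth] = []
    lmin, lmax = spec.cilium_length_px
    centers_arr = np.array([(r, c) for r, c, _ in centers]) if centers else None
    majors_arr = np.array([m for _, _, m in centers]) if centers else None

    def _owned(mid_r: float, mid_c: float, i: int) -> bool:
        # rod midpoint must lie safely in its own cell's territory (nearest
        # nucleus with a 3 px margin, approximating each nucleus by a circle
        # of its major radius)
        d = np.hypot(centers_arr[:, 0] - mid_r, centers_arr[:, 1] - mid_c)
        d -= majors_arr
        own = d[i]
        d[i] = np.inf
        return own + 3.0 <= d.min()

    for i, (cr, cc, major, minor, orient, _) in enumerate(geom.nuclei):
        # cilia: anchored within one nucleus-radius of the nucleus edge,
        # resampled (bounded) until the rod stays in its own cell's territory;
        # multiple cilia on one cell emerge on well-separated sides so distinct
        # rods stay resolvable
        used_phis: list[float] = []
        for _ in range(n_cilia[i]):
            for _attempt in range(20):
                phi = rng.uniform(0, 2 * math.pi)
                dist = major + rng.uniform(1.0, major)
                ar = cr + dist * math.sin(phi)
                ac = cc + dist * math.cos(phi)
                length = rng.uniform(lmin, lmax)
                psi = rng.uniform(0, 2 * math.pi)
                er = ar + length * math.sin(psi)
                ec = ac + length * math.cos(psi)
                ar, er = np.clip([ar, er], 1, h - 2)
                ac, ec = np.clip([ac, ec], 1, w - 2)
                separated = all(
                    min(abs(phi - q), 2 * math.pi - abs(phi - q)) > 1.0
                    for q in used_phis
                )
                if separated and _owned((ar + er) / 2, (ac + ec) / 2, i):
                    break
            used_phis.append(phi)
            geom.cilia.append((float(ar), float(ac), float(er), float(ec)))
        # micronuclei: small blobs just outside the nucleus
        for _ in range(n_micro[i]):
            phi = rng.uniform(0, 2 * math.pi)
            dist = major + rng.uniform(3.0, 10.0)
            mr = float(np.clip(cr + dist * math.sin(phi), 3, h - 4))
            mc = float(np.clip(cc + dist * math.cos(phi), 3, w - 4))
            radius = rng.uniform(1.5, 2.5)
            geom.micronuclei.append((mr, mc, radius))

        border_dist = min(cr, cc, h - 1 - cr, w - 1 - cc) - major
        truth.append(
            CellTruth(
                cell_id=i + 1,
                centroid=(cr, cc),
                nucleus_area_px=math.pi * major * minor,
                touches_border=border_dist < spec.cell_expansion_px,
                n_cilia=int(n_cilia[i]),
                n_micronuclei=int(n_micro[i]),
            )
        )
    return truth, geom


def _vignette(shape: tuple[int, int], edge_gradient: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.hypot(rr - (h - 1) / 2, cc - (w - 1) / 2)
    dmax = math.hypot((h - 1) / 2, (w - 1) / 2)
    return 1.0 - (1.0 - edge_gradient) * (d / dmax)


def _rasterize(
    spec: FieldSpec, geom: _Geometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.image_shape
    nuc = np.zeros((h, w), dtype=np.float64)
    cil = np.zeros((h, w), dtype=np.float64)

    for cr, cc, major, minor, orient, intensity in geom.nuclei:
        rr, xx = ellipse(cr, cc, major, minor, shape=(h, w), rotation=orient)
        nuc[rr, xx] = np.maximum(nuc[rr, xx], intensity)
    for mr, mc, radius in geom.micronuclei:
        rr, xx = disk((mr, mc), radius, shape=(h, w))
        nuc[rr, xx] = np.maximum(nuc[rr, xx], 0.9 * spec.nucleus_intensity)
    for ar, ac, er, ec in geom.cilia:
        rr, xx, val = line_aa(round(ar), round(ac), round(er), round(ec))
        keep = (rr >= 0) & (rr < h) & (xx >= 0) & (xx < w)
        rr, xx, val = rr[keep], xx[keep], val[keep]
        cil[rr, xx] = np.maximum(cil[rr, xx], val * spec.cilium_intensity)

    vig = _vignette((h, w), spec.edge_gradient)
    nuc = (nuc + spec.background_level) * vig
    cil = (cil + spec.background_level) * vig
    nuc += rng.normal(0.0, spec.noise_sd, (h, w))
    cil += rng.normal(0.0, spec.noise_sd, (h, w))
    np.clip(nuc, 0, None, out=nuc)
    np.clip(cil, 0, None, out=cil)
    return nuc, cil


def render_field(spec: FieldSpec) -> SyntheticField:
    """Render one field. Identical spec (incl. seed) gives identical output."""
    rng = np.random.default_rng(spec.seed)
    truth, geom = _sample_field(spec, rng)
    nuc, cil = _rasterize(spec, geom, rng)
    return SyntheticField(nuclear_channel=nuc, cilium_channel=cil, truth=truth)


def sample_field_truth(spec: FieldSpec) -> list[CellTruth]:
    """Ground truth only, skipping rasterization; same RNG stream as
    render_field, so the truth table is identical."""
    rng = np.random.default_rng(spec.seed)
    truth, _ = _sample_field(spec, rng)
    return truth


# ---------------------------------------------------------------------------
# plate-level simulation


@dataclass(frozen=True)
class ConstructEffect:
    ciliation_prob: float
    multi_cilium_prob: float = 0.05
    n_cells_mean: float = 100.0


def field_seed(root_seed: int, plate_id: str, well_id: str, field_index: int) -> int:
    """Per-field seed: hash of (root seed, plate, well, field) so any well is
    independently reproducible."""
    key = f"{root_seed}/{plate_id}/{well_id}/{field_index}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _plate_field_specs(
    layout: PlateLayout,
    effects: dict[str, ConstructEffect],
    seed: int,
    base_spec: FieldSpec,
) -> list[tuple[str, str, FieldSpec]]:
    """One spec per (well, field); media wells get none. n_cells ~ Poisson."""
    for construct in layout.constructs:
        if construct not in effects:
            raise KeyError(f"construct {construct!r} missing from effects mapping")
    out = []
    for well, (construct, role) in sorted(layout.well_assignments.items()):
        if role is Role.MEDIA_ONLY:
            continue
        eff = effects[construct]
        for fi in range(1, 7):
            fseed = field_seed(seed, layout.plate_id, well, fi)
            n_cells = int(np.random.default_rng(fseed + 1).poisson(eff.n_cells_mean))
            spec = replace(
                base_spec,
                well_id=well,
                field_index=fi,
                n_cells=n_cells,
                ciliation_prob=eff.ciliation_prob,
                multi_cilium_prob=eff.multi_cilium_prob,
                seed=fseed,
            )
            out.append((construct, well, spec))
    return out


def iter_plate_fields(
    layout: PlateLayout,
    effects: dict[str, ConstructEffect],
    seed: int = 0,
    base_spec: FieldSpec = FieldSpec(),
):
    """Yield (well_id, field_index, SyntheticField) for every non-media well."""
    for _, well, spec in _plate_field_specs(layout, effects, seed, base_spec):
        yield well, spec.field_index, render_field(spec)


def _truth_rows(plate_id: str, well: str, fi: int, truth: list[CellTruth]):
    for cell in truth:
        yield {
            "plate": plate_id,
            "well": well,
            "field": fi,
            "cell_id": cell.cell_id,
            "x": cell.centroid[1],
            "y": cell.centroid[0],
            "nucleus_area": cell.nucleus_area_px,
            "touches_border": cell.touches_border,
            "n_cilia": cell.n_cilia,
            "n_micronuclei": cell.n_micronuclei,
        }


def simulate_plate_truth(
    layout: PlateLayout,
    effects: dict[str, ConstructEffect],
    seed: int = 0,
    base_spec: FieldSpec = FieldSpec(),
) -> pd.DataFrame:
    """Ground-truth table for a whole plate without rendering any pixels."""
    rows = []
    for _, well, spec in _plate_field_specs(layout, effects, seed, base_spec):
        truth = sample_field_truth(spec)
        rows.extend(_truth_rows(layout.plate_id, well, spec.field_index, truth))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def measure_plate_truth(truth: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Per-field measurements computed from ground truth (no imaging).

    Matches the schema of the image-analysis output closely enough for the
    scoring stage: whole cells are cells whose truth border flag is unset,
    and the headline statistic is the percentage of whole cells with exactly
    one cilium.
    """
    rows = []
    specs = {
        (well, fi)
        for well, (c, role) in layout.well_assignments.items()
        if role is not Role.MEDIA_ONLY
        for fi in range(1, 7)
    }
    grouped = dict(iter(truth.groupby(["well", "field"]))) if len(truth) else {}
    for well, fi in sorted(specs):
        sub = grouped.get((well, fi))
        if sub is None or not len(sub):
            rows.append(
                {
                    "plate": layout.plate_id,
                    "well": well,
                    "field": fi,
                    "n_nuclei": 0,
                    "n_whole_cells": 0,
                    "n_cilia": 0,
                    "n_cells_single_cilium": 0,
                    "pct_single_cilium": np.nan,
                    "micronuclei_per_cell": np.nan,
                    "usable": False,
                }
            )
            continue
        whole = ~sub["touches_border"].to_numpy(dtype=bool)
        n_whole = int(whole.sum())
        n_single = int(((sub["n_cilia"].to_numpy() == 1) & whole).sum())
        rows.append(
            {
                "plate": layout.plate_id,
                "well": well,
                "field": fi,
                "n_nuclei": int(len(sub)),
                "n_whole_cells": n_whole,
                "n_cilia": int(sub["n_cilia"].sum()),
                "n_cells_single_cilium": n_single,
                "pct_single_cilium": (
                    100.0 * n_single / n_whole if n_whole else np.nan
                ),
                "micronuclei_per_cell": float(sub["n_micronuclei"].mean()),
                "usable": n_whole > 0,
            }
        )
    return pd.DataFrame(rows)


def render_plate_to_dir(
    layout: PlateLayout,
    effects: dict[str, ConstructEffect],
    outdir,
    seed: int = 0,
    base_spec: FieldSpec = FieldSpec(),
) -> pd.DataFrame:
    """Write 16-bit grayscale TIFF pairs and truth.csv; return the truth table."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, well, spec in _plate_field_specs(layout, effects, seed, base_spec):
        fld = render_field(spec)
        stem = f"{layout.plate_id}_{well}_f{spec.field_index}"
        tifffile.imwrite(
            outdir / f"{stem}_dapi.tif",
            np.clip(fld.nuclear_channel, 0, 65535).astype(np.uint16),
        )
        tifffile.imwrite(
            outdir / f"{stem}_arl13b.tif",
            np.clip(fld.cilium_channel, 0, 65535).astype(np.uint16),
        )
        rows.extend(_truth_rows(layout.plate_id, well, spec.field_index, fld.truth))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth.to_csv(outdir / "truth.csv", index=False)
    layout.to_yaml(outdir / "layout.yaml")
    return truth


# ---------------------------------------------------------------------------
# default study panels


def rescue_panel() -> tuple[list[tuple[str, Role]], dict[str, ConstructEffect]]:
    """Default assay panel mirroring the experiment's construct structure.

    Mock nucleofection and empty vector sit at the mutant baseline (no
    rescue); wild-type construct rescues; three benign validation controls
    rescue at or above wild-type level; three pathogenic validation controls
    span a low range with the most severe slightly below mock (as observed
    for the most damaging published missense control); one test construct
    sits at each end.
    """
    levels = {
        "mock": (Role.MOCK, 0.25),
        "empty_vector": (Role.EMPTY_VECTOR, 0.25),
        "wild_type": (Role.WILD_TYPE, 0.55),
        "benign_1": (Role.BENIGN_CONTROL, 0.60),
        "benign_2": (Role.BENIGN_CONTROL, 0.65),
        "benign_3": (Role.BENIGN_CONTROL, 0.70),
        "pathogenic_1": (Role.PATHOGENIC_CONTROL, 0.20),
        "pathogenic_2": (Role.PATHOGENIC_CONTROL, 0.30),
        "pathogenic_3": (Role.PATHOGENIC_CONTROL, 0.35),
        "test_benign_like": (Role.TEST_VARIANT, 0.70),
        "test_pathogenic_like": (Role.TEST_VARIANT, 0.22),
    }
    assignments = [(name, role) for name, (role, _) in levels.items()]
    effects = {
        name: ConstructEffect(ciliation_prob=p) for name, (_, p) in levels.items()
    }
    return assignments, effects


def gradient_panel() -> tuple[list[tuple[str, Role]], dict[str, ConstructEffect]]:
    """Ten constructs spanning single-cilium probabilities 0.05-0.80, with the
    mock control fixed at the mutant baseline 0.25; used for recovery and
    monotonicity checks."""
    probs = [0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80]
    assignments: list[tuple[str, Role]] = [("mock", Role.MOCK)]
    effects = {"mock": ConstructEffect(ciliation_prob=0.25)}
    for p in probs:
        name = f"c{int(round(p * 100)):03d}"
        assignments.append((name, Role.TEST_VARIANT))
        effects[name] = ConstructEffect(ciliation_prob=p)
    return assignments, effects
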