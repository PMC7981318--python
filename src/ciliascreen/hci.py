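"""High-content image analysis for the ciliogenesis rescue assay.

Workflow per field of view: segment nuclei in the nuclear-stain channel
(global automatic threshold, hole filling, watershed declumping), derive
cell regions by bounded nearest-nucleus expansion, exclude border-touching
cells ("whole cells" are those fully inside the field), detect cilia in the
marker channel with a robust background threshold plus shape filter, assign
each cilium to the cell containing its centroid, and report the headline
statistic: the percentage of whole cells with a single cilium. Secondary
nuclear phenotypes (micronuclei per cell, nuclear area/shape/intensity) are
measured alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, relabel_sequential, watershed


@dataclass(frozen=True)
class HCIConfig:
    """All tunable analysis parameters, logged with every run."""

    nucleus_min_area: int = 40  # px^2
    nucleus_max_area: int = 2500
    declump_min_distance: int = 10  # px between watershed seeds
    declump_smooth_sigma: float = 2.0
    micro_min_area: int = 3
    micro_max_area: int = 35  # must stay below nucleus_min_area
    micro_search_radius: float = 25.0  # px from nucleus boundary
    cell_expansion: float = 25.0  # px, distance-limited dilation
    cilia_k_mad: float = 6.0  # threshold = background median + k * MAD
    cilia_min_area: int = 3
    cilia_max_area: int = 200
    cilia_min_eccentricity: float = 0.80
    cilia_max_gap: float = 10.0  # px, centroid-to-cell rescue distance
    min_foreground_snr: float = 4.0  # Otsu fg/bg separation, in bg SDs

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


_MEASURE_COLS = [
    "label",
    "area_px",
    "centroid_r",
    "centroid_c",
    "eccentricity",
    "compactness",
    "integrated_intensity",
    "touches_border",
]


@dataclass
class LabeledObjects:
    """A label image (0 = background) plus per-object measurements."""

    label_map: np.ndarray
    measurements: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return len(self.measurements)

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "LabeledObjects":
        return cls(
            label_map=np.zeros(shape, dtype=np.int32),
            measurements=pd.DataFrame(columns=_MEASURE_COLS),
        )


def _check_image(img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.size and img.min() < 0:
        raise ValueError("image intensities must be non-negative")


def _measure(label_map: np.ndarray, intensity: np.ndarray | None) -> pd.DataFrame:
    h, w = label_map.shape
    rows = []
    for p in regionprops(label_map, intensity_image=intensity):
        perim = p.perimeter
        compact = (
            perim**2 / (4 * math.pi * p.area) if p.area > 0 and perim > 0 else np.nan
        )
        minr, minc, maxr, maxc = p.bbox
        rows.append(
            {
                "label": p.label,
                "area_px": int(p.area),
                "centroid_r": p.centroid[0],
                "centroid_c": p.centroid[1],
                "eccentricity": p.eccentricity,
                "compactness": compact,
                "integrated_intensity": (
                    float(p.image_intensity[p.image].sum())
                    if intensity is not None
                    else np.nan
                ),
                "touches_border": minr == 0 or minc == 0 or maxr == h or maxc == w,
            }
        )
    return pd.DataFrame(rows, columns=_MEASURE_COLS)


def _relabel_filtered(label_map: np.ndarray, keep: set[int]) -> np.ndarray:
    out = np.where(np.isin(label_map, list(keep)), label_map, 0)
    return relabel_sequential(out)[0].astype(np.int32)


def segment_nuclei(
    nuclear_channel: np.ndarray, config: HCIConfig = HCIConfig()
) -> LabeledObjects:
    """Segment nuclei: Otsu threshold, hole filling, distance-transform
    watershed declumping of touching nuclei, then a size filter."""
    _check_image(nuclear_channel)
    img = np.asarray(nuclear_channel, dtype=np.float64)
    if img.size == 0 or img.max() == img.min():
        return LabeledObjects.empty(img.shape)
    thr = threshold_otsu(img)
    fg, bg = img[img > thr], img[img <= thr]
    if fg.size == 0 or bg.size == 0:
        return LabeledObjects.empty(img.shape)
    # Otsu always splits the histogram, even on a stain-free field of pure
    # noise; demand real foreground/background separation before believing it
    bg_sd = bg.std()
    if bg_sd > 0 and (fg.mean() - bg.mean()) < config.min_foreground_snr * bg_sd:
        return LabeledObjects.empty(img.shape)
    mask = ndi.binary_fill_holes(img > thr)
    if not mask.any():
        return LabeledObjects.empty(img.shape)

    distance = ndi.distance_transform_edt(mask)
    smoothed = ndi.gaussian_filter(distance, sigma=config.declump_smooth_sigma)
    coords = peak_local_max(
        smoothed,
        min_distance=config.declump_min_distance,
        labels=mask,
        exclude_border=False,
    )
    peaks = np.zeros_like(mask)
    peaks[tuple(coords.T)] = True
    markers, n_markers = ndi.label(peaks)
    if n_markers == 0:
        labels, _ = ndi.label(mask)
    else:
        labels = watershed(-smoothed, markers, mask=mask)
        # components too flat to yield a peak: keep them as whole objects
        orphan = mask & (labels == 0)
        if orphan.any():
            extra, n_extra = ndi.label(orphan)
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)

    sizes = np.bincount(labels.ravel())
    keep = {
        int(lbl)
        for lbl in np.nonzero(
            (sizes >= config.nucleus_min_area) & (sizes <= config.nucleus_max_area)
        )[0]
        if lbl != 0
    }
    label_map = _relabel_filtered(labels, keep)
    return LabeledObjects(label_map=label_map, measurements=_measure(label_map, img))


def detect_micronuclei(
    nuclear_channel: np.ndarray,
    nuclei: LabeledObjects,
    config: HCIConfig = HCIConfig(),
) -> np.ndarray:
    """Count micronuclei per nucleus: small above-threshold objects (area in
    [micro_min, micro_max]) within a search radius of a nucleus; objects
    farther away are discarded. Returns counts aligned with nucleus labels
    (index 0 -> label 1, ...)."""
    _check_image(nuclear_channel)
    img = np.asarray(nuclear_channel, dtype=np.float64)
    counts = np.zeros(nuclei.n_objects, dtype=int)
    if img.size == 0 or img.max() == img.min() or nuclei.n_objects == 0:
        return counts
    thr = threshold_otsu(img)
    mask = (img > thr) & (nuclei.label_map == 0)
    cand_labels, n_cand = ndi.label(mask)
    if n_cand == 0:
        return counts
    dist_to_nucleus, (ir, ic) = ndi.distance_transform_edt(
        nuclei.label_map == 0, return_indices=True
    )
    for p in regionprops(cand_labels):
        if not (config.micro_min_area <= p.area <= config.micro_max_area):
            continue
        r, c = (int(round(p.centroid[0])), int(round(p.centroid[1])))
        r = min(max(r, 0), img.shape[0] - 1)
        c = min(max(c, 0), img.shape[1] - 1)
        if dist_to_nucleus[r, c] <= config.micro_search_radius:
            owner = nuclei.label_map[ir[r, c], ic[r, c]]
            if owner > 0:
                counts[owner - 1] += 1
    return counts


def delineate_cells(
    nuclei: LabeledObjects,
    image_shape: tuple[int, int],
    config: HCIConfig = HCIConfig(),
) -> LabeledObjects:
    """Cell regions by bounded distance-limited dilation of nuclei; contested
    pixels go to the nearest nucleus. Cells touching the image border are
    flagged; whole cells are the unflagged ones."""
    if nuclei.n_objects == 0:
        return LabeledObjects.empty(image_shape)
    cell_map = expand_labels(nuclei.label_map, distance=config.cell_expansion)
    return LabeledObjects(
        label_map=cell_map.astype(np.int32), measurements=_measure(cell_map, None)
    )


def detect_cilia(
    cilium_channel: np.ndarray, config: HCIConfig = HCIConfig()
) -> LabeledObjects:
    """Detect cilia: robust threshold (background median + k*MAD) then a shape
    filter keeping elongated objects of plausible size."""
    _check_image(cilium_channel)
    img = np.asarray(cilium_channel, dtype=np.float64)
    if img.size == 0 or img.max() == img.min():
        return LabeledObjects.empty(img.shape)
    med = np.median(img)
    mad = np.median(np.abs(img - med))
    thr = med + config.cilia_k_mad * mad
    mask = img > thr
    labels, n = ndi.label(mask)
    if n == 0:
        return LabeledObjects.empty(img.shape)
    keep = set()
    for p in regionprops(labels):
        if (
            config.cilia_min_area <= p.area <= config.cilia_max_area
            and p.eccentricity >= config.cilia_min_eccentricity
        ):
            keep.add(p.label)
    label_map = _relabel_filtered(labels, keep)
    return LabeledObjects(label_map=label_map, measurements=_measure(label_map, img))


def assign_cilia(
    cilia: LabeledObjects,
    cells: LabeledObjects,
    config: HCIConfig = HCIConfig(),
) -> np.ndarray:
    """Assign each cilium to the cell containing its centroid; a centroid on
    background is rescued to the nearest cell within `cilia_max_gap` px, else
    the cilium stays unassigned. Returns per-cell counts aligned with cell
    labels (index 0 -> label 1, ...)."""
    if cilia.label_map.shape != cells.label_map.shape:
        raise ValueError(
            f"shape mismatch: cilia {cilia.label_map.shape} vs "
            f"cells {cells.label_map.shape}"
        )
    counts = np.zeros(cells.n_objects, dtype=int)
    if cilia.n_objects == 0 or cells.n_objects == 0:
        return counts
    h, w = cells.label_map.shape
    need_rescue = (cells.label_map == 0).any()
    if need_rescue:
        dist, (ir, ic) = ndi.distance_transform_edt(
            cells.label_map == 0, return_indices=True
        )
    for _, row in cilia.measurements.iterrows():
        r = min(max(int(round(row["centroid_r"])), 0), h - 1)
        c = min(max(int(round(row["centroid_c"])), 0), w - 1)
        owner = int(cells.label_map[r, c])
        if owner == 0 and need_rescue and dist[r, c] <= config.cilia_max_gap:
            owner = int(cells.label_map[ir[r, c], ic[r, c]])
        if owner > 0:
            counts[owner - 1] += 1
    return counts


@dataclass
class FieldMeasurement:
    """Per-field counts and the headline statistic."""

    plate: str
    well: str
    field: int
    n_nuclei: int
    n_whole_cells: int
    n_cilia: int
    n_cells_single_cilium: int
    pct_single_cilium: float  # NaN when the field is unusable
    micronuclei_per_cell: float
    mean_nuclear_area: float
    mean_eccentricity: float
    mean_compactness: float
    mean_nuclear_intensity: float
    usable: bool

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


FIELDS_COLUMNS = list(FieldMeasurement.__dataclass_fields__)


def measure_field(
    nuclei: LabeledObjects,
    cells: LabeledObjects,
    cilia_counts: np.ndarray,
    *,
    n_cilia_detected: int | None = None,
    micronuclei_counts: np.ndarray | None = None,
    plate: str = "",
    well: str = "",
    field: int = 0,
) -> FieldMeasurement:
    """Combine per-object results into field-level counts. A "single cilium"
    means exactly one assigned cilium; only whole (non-border) cells enter
    the numerator and denominator. Fields with no whole cells are flagged
    unusable and excluded downstream."""
    whole = ~cells.measurements["touches_border"].to_numpy(dtype=bool)
    n_whole = int(whole.sum())
    counts = np.asarray(cilia_counts, dtype=int)
    n_single = int(((counts == 1) & whole).sum()) if len(counts) else 0
    pct = 100.0 * n_single / n_whole if n_whole > 0 else float("nan")
    nm = nuclei.measurements
    return FieldMeasurement(
        plate=plate,
        well=well,
        field=field,
        n_nuclei=nuclei.n_objects,
        n_whole_cells=n_whole,
        n_cilia=(
            int(n_cilia_detected)
            if n_cilia_detected is not None
            else int(counts.sum())
        ),
        n_cells_single_cilium=n_single,
        pct_single_cilium=pct,
        micronuclei_per_cell=(
            float(np.mean(micronuclei_counts))
            if micronuclei_counts is not None and len(micronuclei_counts)
            else float("nan")
        ),
        mean_nuclear_area=float(nm["area_px"].mean()) if len(nm) else float("nan"),
        mean_eccentricity=(
            float(nm["eccentricity"].mean()) if len(nm) else float("nan")
        ),
        mean_compactness=(
            float(nm["compactness"].mean()) if len(nm) else float("nan")
        ),
        mean_nuclear_intensity=(
            float(nm["integrated_intensity"].mean()) if len(nm) else float("nan")
        ),
        usable=n_whole > 0,
    )


def analyze_field(
    nuclear_channel: np.ndarray,
    cilium_channel: np.ndarray,
    config: HCIConfig = HCIConfig(),
    *,
    plate: str = "",
    well: str = "",
    field: int = 0,
) -> FieldMeasurement:
    """Full per-field workflow on a pair of channel images."""
    nuclei = segment_nuclei(nuclear_channel, config)
    cells = delineate_cells(nuclei, np.asarray(nuclear_channel).shape, config)
    cilia = detect_cilia(cilium_channel, config)
    counts = assign_cilia(cilia, cells, config)
    micro = detect_micronuclei(nuclear_channel, nuclei, config)
    return measure_field(
        nuclei,
        cells,
        counts,
        n_cilia_detected=cilia.n_objects,
        micronuclei_counts=micro,
        plate=plate,
        well=well,
        field=field,
    )


def analyze_fields(field_iter, config: HCIConfig = HCIConfig(), plate: str = "") -> pd.DataFrame:
    """Analyze an iterable of (well_id, field_index, nuclear, cilium) tuples
    (or synthgen SyntheticField objects) into a fields table."""
    rows = []
    for item in field_iter:
        if len(item) == 3:  # (well, field_index, SyntheticField)
            well, fi, fld = item
            nuc, cil = fld.nuclear_channel, fld.cilium_channel
        else:
            well, fi, nuc, cil = item
        fm = analyze_field(nuc, cil, config, plate=plate, well=well, field=fi)
        rows.append(fm.as_dict())
    return pd.DataFrame(rows, columns=FIELDS_COLUMNS)


def analyze_image_dir(image_dir, plate_id: str, config: HCIConfig = HCIConfig()) -> pd.DataFrame:
    """Analyze a directory of `<plate>_<well>_f<k>_{dapi,arl13b}.tif` pairs."""
    from pathlib import Path

    import tifffile

    image_dir = Path(image_dir)
    items = []
    for dapi in sorted(image_dir.glob(f"{plate_id}_*_dapi.tif")):
        stem = dapi.name[: -len("_dapi.tif")]
        arl = image_dir / f"{stem}_arl13b.tif"
        if not arl.exists():
            raise FileNotFoundError(f"missing cilium channel for {stem}")
        _, well, ftag = stem.rsplit("_", 2)
        items.append(
            (
                well,
                int(ftag.lstrip("f")),
                tifffile.imread(dapi),
                tifffile.imread(arl),
            )
        )
    return analyze_fields(items, config, plate=plate_id)
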