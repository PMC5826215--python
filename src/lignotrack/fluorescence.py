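"""Quantitative analysis of two-channel autofluorescence time-lapse images.

The branch implements flat-field (shading) correction ``IMC = (IM - BKG)/ILL``
with a Fourier-domain estimate of the illumination inhomogeneity, false-colour
composites of the enzyme and cell-wall channels, region-mean kinetic curves,
normalisation of kinetics by the free-enzyme (cavity) level, and the
small-variation enhancement used to display cavity curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import MAX_COUNT, FluorescenceStack, SceneTruth

__all__ = [
    "FluorescenceFrame",
    "IlluminationModel",
    "Region",
    "RegionSet",
    "KINETIC_COLUMNS",
    "estimate_illumination",
    "correct_shading",
    "correct_stack",
    "compose_rgb",
    "measure_regions",
    "normalize_kinetics",
    "enhance_deviation",
    "regions_from_truth",
]

#: Schema of a kinetic table (one row per experiment x region x time point).
KINETIC_COLUMNS = [
    "experiment_id",
    "region_id",
    "cell_type_code",
    "is_cavity",
    "time_min",
    "mean_intensity",
    "n_pixels",
]


@dataclass
class FluorescenceFrame:
    """A single raw (IM) or corrected (IMC) frame of one emission channel."""

    pixels: np.ndarray
    channel: str = "enzyme"  # 'enzyme' (327-353 nm) or 'wall' (420-480 nm)
    time_min: float = 0.0
    pixel_size_um: float = 1.092

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ValueError("frame pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("frame pixels must be finite")


@dataclass
class IlluminationModel:
    """Additive background BKG plus multiplicative illumination ILL (mean 1)."""

    background: np.ndarray | float = 0.0
    illumination: np.ndarray | float = 1.0

    def __post_init__(self):
        ill = np.asarray(self.illumination, dtype=float)
        if np.any(ill <= 0):
            raise ValueError("illumination must be strictly positive everywhere")
        # estimated fields are normalized; scalar broadcasts may take any value
        if ill.ndim >= 1 and abs(float(np.mean(ill)) - 1.0) > 1e-9:
            raise ValueError("illumination field must be normalized to mean 1")


@dataclass
class Region:
    id: str
    cell_type_code: str
    mask: np.ndarray  # boolean pixel membership
    is_cavity: bool = False


@dataclass
class RegionSet:
    regions: list[Region] = field(default_factory=list)
    provenance: str = "manual"  # 'manual' or 'truth-derived'

    def __post_init__(self):
        ids = [r.id for r in self.regions]
        if len(ids) != len(set(ids)):
            raise ValueError("region ids must be unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)


def estimate_illumination(
    frame: FluorescenceFrame | np.ndarray, cutoff_sigma: float = 2.0
) -> np.ndarray:
    """Estimate the illumination field by Gaussian low-pass Fourier filtering.

    The frame's spectrum is attenuated by a Gaussian of width ``cutoff_sigma``
    (in cycles per image), transformed back, clipped to a small positive floor
    and rescaled to mean 1. The default keeps only vignette-scale variation.
    """
    pixels = frame.pixels if isinstance(frame, FluorescenceFrame) else np.asarray(frame, float)
    if cutoff_sigma <= 0:
        raise ValueError("cutoff_sigma must be > 0")
    if not np.any(pixels):
        raise ValueError("cannot estimate illumination from empty image")
    rows, cols = pixels.shape
    fr = np.fft.fftfreq(rows) * rows  # cycles per image
    fc = np.fft.fftfreq(cols) * cols
    radius2 = fr[:, None] ** 2 + fc[None, :] ** 2
    gaussian = np.exp(-radius2 / (2.0 * cutoff_sigma**2))
    smooth = np.fft.ifft2(np.fft.fft2(pixels) * gaussian).real
    floor = 1e-6 * max(float(np.max(np.abs(smooth))), 1e-30)
    smooth = np.clip(smooth, floor, None)
    return smooth / smooth.mean()


def correct_shading(
    frame: FluorescenceFrame, model: IlluminationModel
) -> FluorescenceFrame:
    """Apply IMC = (IM - BKG)/ILL; negative corrected values are floored at 0."""
    bkg = np.asarray(model.background, dtype=float)
    ill = np.asarray(model.illumination, dtype=float)
    for name, arr in (("background", bkg), ("illumination", ill)):
        if arr.ndim == 2 and arr.shape != frame.pixels.shape:
            raise ValueError(
                f"{name} shape {arr.shape} does not match frame shape {frame.pixels.shape}"
            )
    if np.any(ill <= 0):
        raise ValueError("illumination must be strictly positive")
    corrected = np.clip((frame.pixels - bkg) / ill, 0.0, None)
    return FluorescenceFrame(
        pixels=corrected,
        channel=frame.channel,
        time_min=frame.time_min,
        pixel_size_um=frame.pixel_size_um,
    )


def correct_stack(
    stack: FluorescenceStack,
    model: IlluminationModel,
    channels: tuple[str, ...] = ("enzyme", "wall"),
) -> dict[str, list[FluorescenceFrame]]:
    """Shading-correct every frame of the requested channels of a stack."""
    out: dict[str, list[FluorescenceFrame]] = {}
    for channel in channels:
        data = stack.channel(channel)
        out[channel] = [
            correct_shading(
                FluorescenceFrame(
                    data[t], channel=channel, time_min=float(stack.times_min[t]),
                    pixel_size_um=stack.pixel_size_um,
                ),
                model,
            )
            for t in range(stack.n_frames)
        ]
    return out


def compose_rgb(
    enzyme: FluorescenceFrame,
    wall: FluorescenceFrame,
    display_max: tuple[float, float] | None = None,
) -> np.ndarray:
    """Build the false-colour composite: enzyme in R and G, cell wall in B.

    Enzyme-only pixels render yellow, wall-only pixels blue, co-localisation
    white. Each channel is scaled linearly by its ``display_max`` (default:
    99.5th percentile of the frame) and clipped to [0, 1].
    """
    if enzyme.pixels.shape != wall.pixels.shape:
        raise ValueError("enzyme and wall frames must share the same shape")
    if enzyme.time_min != wall.time_min:
        raise ValueError("enzyme and wall frames must share the same time point")
    if display_max is None:
        display_max = (
            max(float(np.percentile(enzyme.pixels, 99.5)), 1e-12),
            max(float(np.percentile(wall.pixels, 99.5)), 1e-12),
        )
    e_max, w_max = display_max
    if e_max <= 0 or w_max <= 0:
        raise ValueError("display_max values must be > 0")
    e = np.clip(enzyme.pixels / e_max, 0.0, 1.0)
    w = np.clip(wall.pixels / w_max, 0.0, 1.0)
    return np.stack([e, e, w], axis=-1)


def measure_regions(
    frames: list[FluorescenceFrame],
    regions: RegionSet,
    experiment_id: str = "exp1",
) -> pd.DataFrame:
    """Region-mean intensity at every time point -> tidy kinetic table."""
    if not frames:
        raise ValueError("no frames to measure")
    shape = frames[0].pixels.shape
    rows = []
    for region in regions:
        if region.mask.shape != shape:
            raise ValueError(f"region {region.id!r} mask shape does not match frames")
        n_px = int(region.mask.sum())
        if n_px == 0:
            raise ValueError(f"region {region.id!r} is empty")
        for frame in frames:
            rows.append(
                {
                    "experiment_id": experiment_id,
                    "region_id": region.id,
                    "cell_type_code": region.cell_type_code,
                    "is_cavity": region.is_cavity,
                    "time_min": frame.time_min,
                    "mean_intensity": float(frame.pixels[region.mask].mean()),
                    "n_pixels": n_px,
                }
            )
    return pd.DataFrame(rows, columns=KINETIC_COLUMNS)


def normalize_kinetics(
    table: pd.DataFrame, cavity_reference: dict[str, float] | float
) -> pd.DataFrame:
    """Divide intensities by the per-experiment free-enzyme (cavity) level.

    After normalisation a pure-solution cavity region sits at ~1, making
    kinetic curves comparable across experiments with different enzyme loads.
    """
    out = table.copy()
    if np.isscalar(cavity_reference):
        refs = {exp: float(cavity_reference) for exp in out["experiment_id"].unique()}
    else:
        refs = {k: float(v) for k, v in cavity_reference.items()}
    missing = set(out["experiment_id"].unique()) - set(refs)
    if missing:
        raise ValueError(f"missing cavity reference for experiments {sorted(missing)}")
    for exp, ref in refs.items():
        if ref <= 0:
            raise ValueError(f"cavity reference for experiment {exp!r} must be > 0")
    out["mean_intensity"] = out["mean_intensity"] / out["experiment_id"].map(refs)
    return out


def enhance_deviation(curve: np.ndarray, factor: float = 10.0) -> np.ndarray:
    """Magnify variations from the initial value: out(t) = y0 + factor*(y(t)-y0)."""
    y = np.asarray(curve, dtype=float)
    if y.size == 0:
        raise ValueError("curve must be non-empty")
    return y[0] + factor * (y - y[0])


def regions_from_polygons(
    polygons: list[dict], image_shape: tuple[int, int], provenance: str = "manual"
) -> RegionSet:
    """Rasterize JSON polygon regions into pixel masks.

    Each entry is ``{"id", "cell_type_code", "is_cavity", "vertices"}`` with
    vertices as (row, col) pairs in 0-based pixel-edge coordinates.
    Rasterization is half-open: a pixel belongs to the region if its center
    (row+0.5, col+0.5) lies inside the polygon, so polygons sharing an edge
    tile the image without overlapping.
    """
    from matplotlib.path import Path as MplPath

    rows, cols = image_shape
    rr, cc = np.meshgrid(np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij")
    points = np.column_stack([rr.ravel(), cc.ravel()])
    regions = []
    for poly in polygons:
        verts = np.asarray(poly["vertices"], dtype=float)
        if verts.ndim != 2 or verts.shape[0] < 3:
            raise ValueError(f"region {poly.get('id')!r}: need at least 3 vertices")
        if verts.min() < 0 or np.any(verts.max(axis=0) > (rows, cols)):
            raise ValueError(f"region {poly.get('id')!r}: vertices outside image bounds")
        path = MplPath(verts)
        mask = path.contains_points(points).reshape(rows, cols)
        regions.append(
            Region(
                poly["id"], poly["cell_type_code"], mask,
                bool(poly.get("is_cavity", False)),
            )
        )
    return RegionSet(regions=regions, provenance=provenance)


def regions_from_truth(
    truth: SceneTruth,
    max_regions_per_code: int = 4,
    include_cavities: bool = True,
    min_pixels: int = 4,
) -> RegionSet:
    """Build a RegionSet from scene ground truth, one region per lattice cell.

    Wall regions are labelled with the cell-type code; cavity regions with the
    conventional ``i<code>`` prefix and ``is_cavity=True``. At most
    ``max_regions_per_code`` lattice cells per code are used, mirroring the
    few manually drawn regions per cell type of a real analysis.
    """
    regions: list[Region] = []
    for label, code in truth.code_of_label.items():
        cells = np.unique(truth.cell_index_image[truth.label_image == label])
        kept = 0
        for cell in cells:
            if kept >= max_regions_per_code:
                break
            in_cell = truth.cell_index_image == cell
            wall_mask = in_cell & (truth.label_image == label)
            cav_mask = in_cell & (truth.cavity_label_image == label)
            if wall_mask.sum() < min_pixels or cav_mask.sum() < min_pixels:
                continue
            regions.append(Region(f"{code}_w{kept}", code, wall_mask, is_cavity=False))
            if include_cavities:
                regions.append(Region(f"i{code}_{kept}", f"i{code}", cav_mask, is_cavity=True))
            kept += 1
    return RegionSet(regions=regions, provenance="truth-derived")
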