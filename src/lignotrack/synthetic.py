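"""Synthetic fluorescence scenes and FT-IR spectral series with known ground truth.

The forward models emulate the two acquisition modalities the analysis code is
written for:

* a full-field deep-UV fluorescence microscope imaging enzymatic degradation of
  a plant stem section — two emission channels (protein autofluorescence of the
  enzymes, phenolic autofluorescence of the cell walls), 16-bit frames every
  few minutes, multiplicative illumination inhomogeneity (vignetting), an
  additive dark background and photon-counting noise;
* a microfluidic FT-IR microspectroscope recording time-lapse absorbance
  spectra at fixed points, built from cellulose / xylan / lignin-ester band
  sets whose pools decay at polymer-specific rates.

Every generated dataset is returned together with the complete ground truth
(label images, illumination field, per-cell-type survival and enzyme series,
per-polymer decay rates), so downstream operators can be tested quantitatively
without any real acquisition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CellTypeParams",
    "SceneConfig",
    "SceneTruth",
    "FluorescenceStack",
    "BandComponent",
    "SpectraConfig",
    "default_cell_types",
    "default_band_library",
    "default_composition",
    "generate_scene",
    "generate_spectral_series",
    "component_spectrum",
    "wall_survival",
]

MAX_COUNT = 65535

#: Maize-stem cell-type codes used throughout: parenchyma below the rind
#: (pri, split into pr1/pr2 in kinetic analyses), parenchyma near vascular
#: bundles (pnv), parenchyma in the pith (ppi), sclerenchyma sheath (scl),
#: xylem fibers (xyl), phloem (phl) and xylem parenchyma (pxy).
RECALCITRANT_CODES = ("ppi", "scl", "xyl")


@dataclass
class CellTypeParams:
    """Per-cell-type forward-model parameters.

    wall_intensity_counts
        Phenolic-autofluorescence level of the intact wall (wall channel).
    enzyme_affinity
        Dimensionless equilibrium enrichment of enzyme on the wall relative to
        the free solution (0 for walls enzymes do not bind).
    binding_rate_per_min
        First-order approach rate of enzyme binding.
    degradation_lag_min / degradation_rate_per_min
        Wall survival is 1 until the lag, then decays exponentially.
    recalcitrant
        Lignified walls: no binding, no degradation.
    """

    wall_intensity_counts: float
    enzyme_affinity: float
    binding_rate_per_min: float
    degradation_lag_min: float
    degradation_rate_per_min: float
    recalcitrant: bool = False

    def validate(self, code: str) -> None:
        if not 0 <= self.wall_intensity_counts <= MAX_COUNT:
            raise ValueError(
                f"cell_type_params[{code!r}].wall_intensity_counts must be in "
                f"[0, {MAX_COUNT}]"
            )
        if self.enzyme_affinity < 0:
            raise ValueError(f"cell_type_params[{code!r}].enzyme_affinity must be >= 0")
        if self.recalcitrant and (
            self.degradation_rate_per_min != 0 or self.enzyme_affinity != 0
        ):
            raise ValueError(
                f"cell_type_params[{code!r}]: recalcitrant cell types must have "
                "degradation_rate_per_min = 0 and enzyme_affinity = 0"
            )
        if self.degradation_rate_per_min < 0:
            raise ValueError(
                f"cell_type_params[{code!r}].degradation_rate_per_min must be >= 0"
            )
        if self.binding_rate_per_min < 0:
            raise ValueError(
                f"cell_type_params[{code!r}].binding_rate_per_min must be >= 0"
            )


def default_cell_types() -> dict[str, CellTypeParams]:
    """Default parameter set for the seven maize-stem cell types.

    Enzyme affinities are anchored to the measured intensity contrasts of the
    study system: degradable parenchyma walls reach roughly 1.9x the free
    solution level, phloem/xylem parenchyma about 1.2x, and lignified walls
    (ppi, scl, xyl) bind no enzyme at all.
    """
    return {
        "pri": CellTypeParams(600.0, 1.9, 0.15, 12.0, 0.10),
        "pnv": CellTypeParams(600.0, 1.87, 0.15, 10.0, 0.12),
        "ppi": CellTypeParams(400.0, 0.0, 0.0, 0.0, 0.0, recalcitrant=True),
        "scl": CellTypeParams(300.0, 0.0, 0.0, 0.0, 0.0, recalcitrant=True),
        "xyl": CellTypeParams(900.0, 0.0, 0.0, 0.0, 0.0, recalcitrant=True),
        "phl": CellTypeParams(700.0, 1.23, 0.12, 6.0, 0.06),
        "pxy": CellTypeParams(700.0, 1.24, 0.18, 6.0, 0.20),
    }


@dataclass
class SceneConfig:
    """Configuration of a synthetic fluorescence time-lapse scene.

    The default geometry is a rectangular lattice of cells with 3-px walls;
    frames are taken every 6 min over roughly an hour, coded on 65536 gray
    levels, with a Gaussian vignette, a dark additive background and Poisson
    (photon-counting) noise.
    """

    image_size: tuple[int, int] = (120, 120)
    pixel_size_um: float = 1.092
    n_frames: int = 12
    frame_interval_min: float = 6.0
    cell_type_params: dict[str, CellTypeParams] = field(default_factory=default_cell_types)
    solution_enzyme_counts: float = 50.0
    vignette_sigma_frac: float = 0.5
    background_mean_counts: float = 20.0
    poisson_noise: bool = True
    gaussian_sd_counts: float = 2.0
    cell_size_px: int = 24
    wall_thickness_px: int = 3
    seed: int = 7

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if not 0 <= self.background_mean_counts <= MAX_COUNT:
            raise ValueError(f"background_mean_counts must be in [0, {MAX_COUNT}]")
        if not 0 <= self.solution_enzyme_counts <= MAX_COUNT:
            raise ValueError(f"solution_enzyme_counts must be in [0, {MAX_COUNT}]")
        if self.vignette_sigma_frac <= 0:
            raise ValueError("vignette_sigma_frac must be > 0")
        if self.cell_size_px <= self.wall_thickness_px:
            raise ValueError("cell_size_px must exceed wall_thickness_px")
        if not self.cell_type_params:
            raise ValueError("cell_type_params must not be empty")
        for code, params in self.cell_type_params.items():
            params.validate(code)

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass
class FluorescenceStack:
    """Time-ordered two-channel 16-bit image stack.

    ``enzyme`` holds the 327–353 nm protein-autofluorescence channel,
    ``wall`` the 420–480 nm phenolic channel; both are (T, rows, cols) uint16.
    """

    enzyme: np.ndarray
    wall: np.ndarray
    times_min: np.ndarray
    pixel_size_um: float = 1.092

    def channel(self, name: str) -> np.ndarray:
        if name not in ("enzyme", "wall"):
            raise KeyError(f"unknown channel {name!r}; expected 'enzyme' or 'wall'")
        return getattr(self, name)

    @property
    def n_frames(self) -> int:
        return self.enzyme.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.enzyme.shape[1:]


@dataclass
class SceneTruth:
    """Complete ground truth of a generated scene.

    label_image codes wall pixels by cell type (0 = cavity/medium);
    cavity_label_image does the same for cavity pixels; cell_index_image gives
    the lattice-cell id of every pixel, so individual cells can be turned into
    regions. The per-code time series are noise-free expectations.
    """

    label_image: np.ndarray
    cavity_label_image: np.ndarray
    cell_index_image: np.ndarray
    code_of_label: dict[int, str]
    illumination_field: np.ndarray
    background_image: np.ndarray
    times_min: np.ndarray
    wall_survival: dict[str, np.ndarray]
    enzyme_on_wall: dict[str, np.ndarray]
    enzyme_in_cavity: dict[str, np.ndarray]
    wall_intensity: dict[str, np.ndarray]
    config: SceneConfig

    def noise_free_frame(self, channel: str, frame: int) -> np.ndarray:
        """Evaluate the analytic forward model ILL*signal + BKG for one frame."""
        signal = self.signal_frame(channel, frame)
        return self.illumination_field * signal + self.background_image

    def signal_frame(self, channel: str, frame: int) -> np.ndarray:
        """Noise-free signal S (before illumination/background) for one frame."""
        out = np.zeros(self.label_image.shape, dtype=float)
        for label, code in self.code_of_label.items():
            wall_mask = self.label_image == label
            cav_mask = self.cavity_label_image == label
            if channel == "enzyme":
                out[wall_mask] = self.enzyme_on_wall[code][frame]
                out[cav_mask] = self.enzyme_in_cavity[code][frame]
            elif channel == "wall":
                out[wall_mask] = self.wall_intensity[code][frame]
            else:
                raise KeyError(f"unknown channel {channel!r}")
        return out


def wall_survival(times: np.ndarray, lag_min: float, rate_per_min: float) -> np.ndarray:
    """Survival law s(t): 1 up to the lag, exponential decay afterwards."""
    t = np.asarray(times, dtype=float)
    s = np.ones_like(t)
    after = t > lag_min
    s[after] = np.exp(-rate_per_min * (t[after] - lag_min))
    return s


def _vignette(shape: tuple[int, int], sigma_frac: float) -> np.ndarray:
    rows, cols = shape
    r = np.arange(rows)[:, None] - (rows - 1) / 2.0
    c = np.arange(cols)[None, :] - (cols - 1) / 2.0
    sigma = sigma_frac * cols
    v = np.exp(-(r**2 + c**2) / (2.0 * sigma**2))
    return v / v.mean()


def generate_scene(config: SceneConfig) -> tuple[FluorescenceStack, SceneTruth]:
    """Generate a two-channel degradation time-lapse plus its ground truth.

    Each frame is ``clip_round_16bit(ILL * S + BKG + noise)``. On wall pixels
    the wall channel carries ``wall_intensity * s(t)``; the enzyme channel
    carries bound enzyme plus solution showing through the degraded fraction,
    ``affinity*solution*(1-exp(-binding_rate*t))*s(t) + solution*(1-s(t))``,
    so degradable walls rise above the solution level and then relax back to
    it as the wall disappears, while recalcitrant walls stay dark. Cavity
    pixels carry the solution level minus the enzyme mass currently bound on
    the cell's own walls (scaled by the wall/cavity pixel ratio), recovering
    after wall disappearance.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_size
    cs, wt = config.cell_size_px, config.wall_thickness_px
    times = config.times_min

    codes = list(config.cell_type_params)
    code_of_label = {i + 1: code for i, code in enumerate(codes)}
    label_of_code = {code: lab for lab, code in code_of_label.items()}

    rr = np.arange(rows)[:, None]
    cc = np.arange(cols)[None, :]
    cell_row, cell_col = rr // cs, cc // cs
    n_cell_cols = -(-cols // cs)
    cell_index = (cell_row * n_cell_cols + cell_col).astype(np.int32)
    is_wall = ((rr % cs) < wt) | ((cc % cs) < wt)
    cell_code_idx = cell_index % len(codes)

    label_image = np.zeros((rows, cols), dtype=np.int32)
    cavity_label = np.zeros((rows, cols), dtype=np.int32)
    for i, code in enumerate(codes):
        members = cell_code_idx == i
        label_image[members & is_wall] = label_of_code[code]
        cavity_label[members & ~is_wall] = label_of_code[code]

    # geometric wall/cavity pixel ratio of a full interior cell
    n_wall_px = cs * cs - (cs - wt) ** 2
    n_cav_px = (cs - wt) ** 2
    wall_cav_ratio = n_wall_px / n_cav_px

    S = config.solution_enzyme_counts
    survival: dict[str, np.ndarray] = {}
    on_wall: dict[str, np.ndarray] = {}
    in_cavity: dict[str, np.ndarray] = {}
    wall_int: dict[str, np.ndarray] = {}
    for code, p in config.cell_type_params.items():
        s = wall_survival(times, p.degradation_lag_min, p.degradation_rate_per_min)
        bound = p.enzyme_affinity * S * (1.0 - np.exp(-p.binding_rate_per_min * times)) * s
        survival[code] = s
        on_wall[code] = bound + S * (1.0 - s)
        in_cavity[code] = np.clip(S - wall_cav_ratio * bound, 0.0, None)
        wall_int[code] = p.wall_intensity_counts * s

    illumination = _vignette((rows, cols), config.vignette_sigma_frac)
    background = np.full((rows, cols), float(config.background_mean_counts))

    truth = SceneTruth(
        label_image=label_image,
        cavity_label_image=cavity_label,
        cell_index_image=cell_index,
        code_of_label=code_of_label,
        illumination_field=illumination,
        background_image=background,
        times_min=times,
        wall_survival=survival,
        enzyme_on_wall=on_wall,
        enzyme_in_cavity=in_cavity,
        wall_intensity=wall_int,
        config=config,
    )

    frames = {"enzyme": [], "wall": []}
    for t in range(config.n_frames):
        for channel in ("enzyme", "wall"):
            expected = truth.noise_free_frame(channel, t)
            if config.poisson_noise:
                frame = rng.poisson(expected).astype(float)
            else:
                frame = expected.copy()
            if config.gaussian_sd_counts > 0:
                frame = frame + rng.normal(0.0, config.gaussian_sd_counts, frame.shape)
            frames[channel].append(np.clip(np.rint(frame), 0, MAX_COUNT).astype(np.uint16))

    stack = FluorescenceStack(
        enzyme=np.stack(frames["enzyme"]),
        wall=np.stack(frames["wall"]),
        times_min=times,
        pixel_size_um=config.pixel_size_um,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# FT-IR spectral forward model
# ---------------------------------------------------------------------------


@dataclass
class BandComponent:
    """One cell-wall polymer as a set of Gaussian absorbance bands."""

    name: str
    bands: list[dict]  # {"center": cm^-1, "width": cm^-1 (sd), "amplitude": absorbance}
    decay_rate_per_min: float = 0.0

    def validate(self) -> None:
        for b in self.bands:
            if not 800 <= b["center"] <= 1800:
                raise ValueError(f"{self.name}: band center {b['center']} outside 800-1800 cm^-1")
            if b["width"] <= 0:
                raise ValueError(f"{self.name}: band width must be > 0")
            if b["amplitude"] < 0:
                raise ValueError(f"{self.name}: band amplitude must be >= 0")
        if self.decay_rate_per_min < 0:
            raise ValueError(f"{self.name}: decay_rate_per_min must be >= 0")


def default_band_library() -> list[BandComponent]:
    """Band sets for cellulose, xylan and lignin esters.

    Centers follow the standard mid-IR assignments for plant cell walls:
    cellulose at 1035 and 1053 cm-1; xylan with its main band at 1045 cm-1
    and shoulders at 1070, 1000 and 980 cm-1; the lignin aromatic band at
    1510 cm-1 and the strong ester band at 1250 cm-1. Default decay rates
    encode the study condition that hemicellulose (xylan) is degraded about
    three times faster than cellulose while lignin is untouched.
    """
    w = 12.0  # Gaussian sd in cm^-1, ~28 cm^-1 FWHM at 8 cm^-1 resolution
    return [
        BandComponent(
            "cellulose",
            [
                {"center": 1035.0, "width": w, "amplitude": 1.0},
                {"center": 1053.0, "width": w, "amplitude": 0.8},
            ],
            decay_rate_per_min=0.02,
        ),
        BandComponent(
            "xylan",
            [
                {"center": 1045.0, "width": w, "amplitude": 1.0},
                {"center": 1070.0, "width": w, "amplitude": 0.35},
                {"center": 1000.0, "width": w, "amplitude": 0.30},
                {"center": 980.0, "width": w, "amplitude": 0.25},
            ],
            decay_rate_per_min=0.06,
        ),
        BandComponent(
            "lignin_ester",
            [
                {"center": 1510.0, "width": w, "amplitude": 0.30},
                {"center": 1250.0, "width": w, "amplitude": 0.60},
            ],
            decay_rate_per_min=0.0,
        ),
    ]


def default_composition() -> dict[str, dict[str, float]]:
    """Initial polymer concentrations per cell type.

    Degradable parenchyma walls are cellulose-rich, phloem / xylem parenchyma
    are xylan-rich, lignified types carry a lignin-ester contribution.
    """
    return {
        "pri": {"cellulose": 1.0, "xylan": 0.7},
        "pnv": {"cellulose": 1.1, "xylan": 0.6},
        "ppi": {"cellulose": 0.8, "xylan": 0.5, "lignin_ester": 0.8},
        "scl": {"cellulose": 0.7, "xylan": 0.6, "lignin_ester": 1.0},
        "xyl": {"cellulose": 0.9, "xylan": 0.6, "lignin_ester": 0.7},
        "phl": {"cellulose": 0.5, "xylan": 1.0},
        "pxy": {"cellulose": 0.5, "xylan": 1.1},
    }


@dataclass
class SpectraConfig:
    """Configuration of synthetic time-lapse absorbance series."""

    wavenumber_range: tuple[float, float] = (800.0, 4000.0)
    resolution_cm: float = 8.0
    n_times: int = 11
    time_step_min: float = 6.0
    composition: dict[str, dict[str, float]] = field(default_factory=default_composition)
    recalcitrant_codes: tuple[str, ...] = RECALCITRANT_CODES
    baseline_slope: float = 0.0  # absorbance per cm^-1
    baseline_sin_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 11

    def validate(self) -> None:
        lo, hi = self.wavenumber_range
        if lo >= hi:
            raise ValueError("wavenumber_range must be (min, max) with min < max")
        if lo > 950 or hi < 1550:
            raise ValueError("wavenumber_range must cover at least 950-1550 cm^-1")
        if self.resolution_cm <= 0:
            raise ValueError("resolution_cm must be > 0")
        if self.n_times < 1:
            raise ValueError("n_times must be >= 1")
        if not self.composition:
            raise ValueError("composition must not be empty")
        for code, comp in self.composition.items():
            for polymer, c0 in comp.items():
                if c0 < 0:
                    raise ValueError(f"composition[{code!r}][{polymer!r}] must be >= 0")

    @property
    def wavenumbers(self) -> np.ndarray:
        lo, hi = self.wavenumber_range
        n = int(np.floor((hi - lo) / self.resolution_cm)) + 1
        return lo + self.resolution_cm * np.arange(n)

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_times) * self.time_step_min


def component_spectrum(component: BandComponent, wavenumbers: np.ndarray) -> np.ndarray:
    """Unit-concentration absorbance spectrum of one polymer component."""
    wn = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(wn)
    for b in component.bands:
        out += b["amplitude"] * np.exp(-((wn - b["center"]) ** 2) / (2.0 * b["width"] ** 2))
    return out


def generate_spectral_series(
    config: SpectraConfig, library: list[BandComponent]
) -> tuple[dict, dict[str, dict[str, float]]]:
    """Generate per-cell-type time-lapse spectra plus true decay rates.

    spectrum(nu, t) = sum_p c_p(0) exp(-k_p t) B_p(nu) + baseline(nu) + noise,
    with k_p = 0 for recalcitrant cell types. Returns
    (``{code: SpectrumSeries}``, ``{code: {polymer: k_p}}``); the series share
    one wavenumber axis and carry synthetic mosaic coordinates.
    """
    from .ftir import SpectrumSeries  # local import to avoid a cycle

    config.validate()
    if not library:
        raise ValueError("band library must not be empty")
    for comp in library:
        comp.validate()
    components = {c.name: c for c in library}

    rng = np.random.default_rng(config.seed)
    wn = config.wavenumbers
    times = config.times_min

    baseline = config.baseline_slope * (wn - wn[0])
    if config.baseline_sin_amplitude:
        baseline = baseline + config.baseline_sin_amplitude * np.sin(
            2.0 * np.pi * (wn - wn[0]) / (wn[-1] - wn[0])
        )

    series: dict[str, SpectrumSeries] = {}
    truth: dict[str, dict[str, float]] = {}
    for i, (code, comp) in enumerate(config.composition.items()):
        unknown = set(comp) - set(components)
        if unknown:
            raise ValueError(f"composition[{code!r}] references unknown polymers {sorted(unknown)}")
        rates = {
            polymer: 0.0
            if code in config.recalcitrant_codes
            else components[polymer].decay_rate_per_min
            for polymer in comp
        }
        truth[code] = rates
        absorbances = np.zeros((len(times), len(wn)))
        for polymer, c0 in comp.items():
            profile = component_spectrum(components[polymer], wn)
            decay = np.exp(-rates[polymer] * times)
            absorbances += (c0 * decay)[:, None] * profile[None, :]
        absorbances += baseline[None, :]
        if config.noise_sd > 0:
            absorbances = absorbances + rng.normal(0.0, config.noise_sd, absorbances.shape)
        series[code] = SpectrumSeries(
            point_id=code,
            wavenumbers=wn.copy(),
            times_min=times.copy(),
            absorbances=absorbances,
            cell_type_code=code,
            mosaic_xy=(100.0 * (i % 4), 100.0 * (i // 4)),
        )
    return series, truth
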