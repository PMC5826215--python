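"""File formats, pipeline runners and run manifests.

Stacks travel as one multi-page 16-bit grayscale TIFF per channel plus a JSON
sidecar (channel names, acquisition times in minutes, pixel size in um).
Spectra travel as CSV with the wavenumber axis (descending, FT-IR convention)
in the first column and one column per time point labelled in minutes, or as
single-spectrum JCAMP-DX (AFFN XYDATA). Every pipeline run writes a manifest
(inputs, parameters, seeds, package version, output checksums) sufficient to
re-run it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .ftir import Spectrum, SpectrumSeries
from .synthetic import FluorescenceStack, SceneTruth

__all__ = [
    "RunConfig",
    "load_stack",
    "save_stack",
    "load_spectra",
    "save_spectra",
    "read_jcampdx",
    "write_jcampdx",
    "save_truth",
    "load_regions",
    "save_regions",
    "run_pipeline",
]

logger = logging.getLogger("lignotrack")

DEFAULT_PIXEL_SIZE_UM = 1.092  # 10x objective


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def save_stack(stack: FluorescenceStack, directory: str | Path) -> Path:
    """Write one multi-page uint16 TIFF per channel plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for channel in ("enzyme", "wall"):
        tifffile.imwrite(
            directory / f"{channel}.tif",
            stack.channel(channel),
            photometric="minisblack",
        )
    sidecar = {
        "channels": ["enzyme", "wall"],
        "times_min": [float(t) for t in stack.times_min],
        "pixel_size_um": float(stack.pixel_size_um),
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_stack(directory: str | Path) -> FluorescenceStack:
    """Load a two-channel stack saved by :func:`save_stack`."""
    directory = Path(directory)
    sidecar_path = directory / "stack.json"
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    channels = {}
    for channel in ("enzyme", "wall"):
        path = directory / f"{channel}.tif"
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.dtype != np.uint16:
            raise ValueError(
                f"{path.name}: expected 16-bit grayscale TIFF, got dtype {data.dtype}"
            )
        if data.ndim != 3:
            raise ValueError(f"{path.name}: expected grayscale pages, got shape {data.shape}")
        channels[channel] = data
    if "times_min" in sidecar:
        times = np.asarray(sidecar["times_min"], dtype=float)
        if times.size != channels["enzyme"].shape[0]:
            raise ValueError(
                f"sidecar lists {times.size} time points but TIFF has "
                f"{channels['enzyme'].shape[0]} pages"
            )
    else:
        warnings.warn("sidecar lacks times_min; defaulting to 6-min intervals")
        times = 6.0 * np.arange(channels["enzyme"].shape[0])
    if "pixel_size_um" in sidecar:
        pixel_size = float(sidecar["pixel_size_um"])
    else:
        warnings.warn(f"sidecar lacks pixel_size_um; defaulting to {DEFAULT_PIXEL_SIZE_UM} um")
        pixel_size = DEFAULT_PIXEL_SIZE_UM
    return FluorescenceStack(
        enzyme=channels["enzyme"],
        wall=channels["wall"],
        times_min=times,
        pixel_size_um=pixel_size,
    )


def save_truth(truth: SceneTruth, directory: str | Path) -> Path:
    """Write scene ground truth: label images as PNG, fields and series as JSON."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "label_image.png", truth.label_image.astype(np.uint16))
    iio.imwrite(directory / "cavity_label_image.png", truth.cavity_label_image.astype(np.uint16))
    payload = {
        "code_of_label": {str(k): v for k, v in truth.code_of_label.items()},
        "times_min": truth.times_min.tolist(),
        "illumination_field": truth.illumination_field.tolist(),
        "background_image": truth.background_image.tolist(),
        "wall_survival": {k: v.tolist() for k, v in truth.wall_survival.items()},
        "enzyme_on_wall": {k: v.tolist() for k, v in truth.enzyme_on_wall.items()},
        "enzyme_in_cavity": {k: v.tolist() for k, v in truth.enzyme_in_cavity.items()},
        "seed": truth.config.seed,
    }
    (directory / "truth.json").write_text(json.dumps(payload))
    return directory


def save_regions(regions, directory: str | Path) -> Path:
    """Write a RegionSet as a 16-bit label TIFF plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shape = regions.regions[0].mask.shape
    label = np.zeros(shape, dtype=np.uint16)
    mapping = {}
    for i, region in enumerate(regions, start=1):
        label[region.mask] = i
        mapping[str(i)] = {
            "id": region.id,
            "cell_type_code": region.cell_type_code,
            "is_cavity": region.is_cavity,
        }
    tifffile.imwrite(directory / "regions.tif", label)
    (directory / "regions.json").write_text(
        json.dumps({"provenance": regions.provenance, "labels": mapping}, indent=2)
    )
    return directory


def load_regions(directory: str | Path):
    """Load a RegionSet: a label TIFF + sidecar, or JSON polygons.

    A ``polygons.json`` file of the form ``{"image_shape": [rows, cols],
    "provenance": ..., "polygons": [...]}`` is rasterized with half-open
    semantics; otherwise ``regions.tif`` + ``regions.json`` are read.
    """
    from .fluorescence import Region, RegionSet, regions_from_polygons

    directory = Path(directory)
    poly_path = directory / "polygons.json"
    if poly_path.exists():
        meta = json.loads(poly_path.read_text())
        return regions_from_polygons(
            meta["polygons"],
            tuple(meta["image_shape"]),
            provenance=meta.get("provenance", "manual"),
        )
    label = tifffile.imread(directory / "regions.tif")
    meta = json.loads((directory / "regions.json").read_text())
    regions = []
    for key, info in meta["labels"].items():
        mask = label == int(key)
        if not mask.any():
            raise ValueError(f"region label {key} has no pixels in regions.tif")
        regions.append(
            Region(info["id"], info["cell_type_code"], mask, bool(info["is_cavity"]))
        )
    return RegionSet(regions=regions, provenance=meta.get("provenance", "manual"))


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def save_spectra(series: SpectrumSeries, path: str | Path) -> Path:
    """Write a series as CSV: descending wavenumber axis, one column per minute."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wn = series.wavenumbers[::-1]  # descending on disk (FT-IR convention)
    data = {"wavenumber_cm-1": wn}
    for i, t in enumerate(series.times_min):
        data[f"{t:g}"] = series.absorbances[i][::-1]
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def load_spectra(
    path: str | Path,
    point_id: str | None = None,
    cell_type_code: str | None = None,
) -> SpectrumSeries:
    """Read a time-lapse series from CSV (time columns labelled in minutes)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path.name}: ragged rows (missing values) in CSV")
    wn = df.iloc[:, 0].to_numpy(dtype=float)
    if np.unique(wn).size != wn.size:
        raise ValueError(f"{path.name}: duplicate wavenumber rows")
    d = np.diff(wn)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{path.name}: wavenumber axis must be strictly monotone")
    try:
        times = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(
            f"{path.name}: time columns must be labelled with minutes"
        ) from exc
    order = np.argsort(times)
    absorb = df.iloc[:, 1:].to_numpy(dtype=float).T[order]
    return SpectrumSeries(
        point_id=point_id or path.stem,
        wavenumbers=wn,
        times_min=times[order],
        absorbances=absorb,
        cell_type_code=cell_type_code,
    )


def write_jcampdx(spectrum: Spectrum, path: str | Path, title: str = "spectrum") -> Path:
    """Write one spectrum as a minimal JCAMP-DX file (AFFN XYDATA)."""
    path = Path(path)
    wn, ab = spectrum.wavenumbers, spectrum.absorbance
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={wn[0]:.6f}",
        f"##LASTX={wn[-1]:.6f}",
        f"##NPOINTS={wn.size}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, wn.size, 6):
        ys = " ".join(f"{y:.8g}" for y in ab[i : i + 6])
        lines.append(f"{wn[i]:.6f} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (uncompressed AFFN XYDATA only)."""
    path = Path(path)
    header: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = value.strip()
            continue
        if in_data:
            parts = line.replace(",", " ").split()
            row = [float(p) for p in parts]
            x0, yvals = row[0], row[1:]
            if not yvals:
                raise ValueError(f"{path.name}: XYDATA line without Y values")
            xs.append(x0)
            ys.append(yvals)
    if not xs:
        raise ValueError(f"{path.name}: no XYDATA found")
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    npoints = int(header.get("NPOINTS", 0)) or sum(len(r) for r in ys)
    firstx = float(header.get("FIRSTX", xs[0] * xfac))
    lastx = float(header.get("LASTX", xs[-1] * xfac))
    yflat = np.array([v for row in ys for v in row]) * yfac
    if yflat.size != npoints:
        raise ValueError(
            f"{path.name}: NPOINTS={npoints} but {yflat.size} Y values present"
        )
    wn = np.linspace(firstx, lastx, npoints)
    return Spectrum(wn, yflat, point_id=path.stem)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline run configuration."""

    mode: str  # 'simulate' | 'fluorescence' | 'ftir'
    output_dir: str | Path = "lignotrack_out"
    stack_dir: str | Path | None = None
    regions_dir: str | Path | None = None
    spectra_paths: list[str] | None = None
    cavity_reference: float | None = None  # counts; estimated from cavities if None
    t_late_min: float = 30.0
    seed: int = 7
    overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path, **cli_overrides) -> "RunConfig":
        """Build a RunConfig from a JSON file; explicit arguments win."""
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)} in {path}")
        data.update({k: v for k, v in cli_overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in ("simulate", "fluorescence", "ftir"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "fluorescence" and self.stack_dir is None:
            raise ValueError("fluorescence mode requires stack_dir")
        if self.mode == "ftir" and not self.spectra_paths:
            raise ValueError("ftir mode requires spectra_paths")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, inputs: list[Path]) -> Path:
    manifest = {
        "package": "lignotrack",
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "overrides"
        },
        "overrides": config.overrides,
        "inputs": {str(p): _sha256(p) for p in inputs if p.is_file()},
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run one of the three workflows end to end; returns a report bundle.

    * ``simulate``: generate a fluorescence scene and spectral series with the
      default study conditions and write stacks, regions, spectra and truth.
    * ``fluorescence``: shading-correct a stack, measure region kinetics,
      normalise by the cavity level, compute group statistics, ANOVA and a
      kinetics PCA, and write composites.
    * ``ftir``: preprocess spectral series, compute summed-absorbance curves,
      decay fits, difference spectra, the aggregated difference and a spectral
      PCA with score maps.
    """
    from . import chemometrics, fluorescence as fl, ftir
    from .synthetic import (
        SceneConfig,
        SpectraConfig,
        default_band_library,
        generate_scene,
        generate_spectral_series,
    )

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []
    report: dict = {"mode": config.mode, "output_dir": str(outdir)}

    if config.mode == "simulate":
        scene_cfg = SceneConfig(seed=config.seed, **config.overrides.get("scene", {}))
        stack, truth = generate_scene(scene_cfg)
        save_stack(stack, outdir / "stack")
        save_truth(truth, outdir / "truth")
        regions = fl.regions_from_truth(truth)
        save_regions(regions, outdir / "regions")
        spectra_cfg = SpectraConfig(
            seed=config.seed + 4, **config.overrides.get("spectra", {})
        )
        series, decay_truth = generate_spectral_series(spectra_cfg, default_band_library())
        (outdir / "spectra").mkdir(exist_ok=True)
        for code, s in series.items():
            save_spectra(s, outdir / "spectra" / f"{code}.csv")
        (outdir / "truth" / "decay_rates.json").write_text(json.dumps(decay_truth, indent=2))
        report["n_frames"] = stack.n_frames
        report["codes"] = list(series)

    elif config.mode == "fluorescence":
        stack_dir = Path(config.stack_dir)
        inputs.extend(stack_dir.rglob("*"))
        stack = load_stack(stack_dir)
        if config.regions_dir is None:
            raise ValueError("fluorescence mode requires regions_dir")
        regions_dir = Path(config.regions_dir)
        inputs.extend(regions_dir.rglob("*"))
        regions = load_regions(regions_dir)

        ill = fl.estimate_illumination(
            fl.FluorescenceFrame(stack.enzyme[0].astype(float)),
            cutoff_sigma=config.overrides.get("cutoff_sigma", 2.0),
        )
        model = fl.IlluminationModel(
            background=config.overrides.get("background", 0.0), illumination=ill
        )
        corrected = fl.correct_stack(stack, model)
        table = fl.measure_regions(corrected["enzyme"], regions)
        table.to_csv(outdir / "kinetics.csv", index=False)

        ref = config.cavity_reference
        if ref is None:
            cav = table[table["is_cavity"]]
            ref = float(cav[cav["time_min"] == cav["time_min"].min()]["mean_intensity"].mean())
        normalized = fl.normalize_kinetics(table, ref)
        normalized.to_csv(outdir / "kinetics_normalized.csv", index=False)

        stats_tab = chemometrics.group_stats(table, at_time=float(stack.times_min[1]))
        stats_tab.to_csv(outdir / "group_stats.csv", index=False)
        aov = chemometrics.anova(table, factors=("cell_type", "time"))
        aov.to_csv(outdir / "anova.csv", index=False)
        pca_res = chemometrics.pca_kinetics(normalized)
        _save_pca(pca_res, outdir / "kinetics_pca")

        import imageio.v3 as iio

        rgb = fl.compose_rgb(corrected["enzyme"][0], corrected["wall"][0])
        iio.imwrite(outdir / "composite_t0.png", (rgb * 255).astype(np.uint8))
        report.update(
            {
                "cavity_reference": ref,
                "anova": aov.to_dict("records"),
                "pca_variance_fraction": pca_res.variance_fraction.tolist(),
            }
        )

    elif config.mode == "ftir":
        series_list = []
        for p in config.spectra_paths:
            p = Path(p)
            inputs.append(p)
            series_list.append(load_spectra(p, cell_type_code=p.stem))
        processed, sums, diffs = [], [], []
        for s in series_list:
            proc, audits = ftir.preprocess_series(s)
            processed.append(proc)
            curve = ftir.sum_absorbance(proc)
            curve["point_id"] = s.point_id
            sums.append(curve)
            (outdir / "anchors").mkdir(exist_ok=True)
            (outdir / "anchors" / f"{s.point_id}.json").write_text(
                json.dumps(
                    [
                        {
                            "a_priori": a.anchors_a_priori,
                            "adjusted": a.anchors_adjusted,
                        }
                        for a in audits
                    ],
                    indent=2,
                )
            )
            try:
                diff = ftir.difference_spectrum(proc, config.t_late_min)
            except ValueError:
                logger.warning("series %s lacks t=%g min; skipped in differences",
                               s.point_id, config.t_late_min)
                continue
            # only degraded walls enter the aggregate: a recalcitrant point has a
            # near-zero difference that cannot be area-normalized meaningfully
            lost = ftir.trapezoid_area(diff)
            initial = ftir.trapezoid_area(proc.spectrum(0))
            if initial > 0 and lost / initial > 0.05:
                diffs.append(diff)
            else:
                logger.info("series %s shows no degradation; excluded from aggregate",
                            s.point_id)
        pd.concat(sums).to_csv(outdir / "sum_absorbance.csv", index=False)
        if diffs:
            agg = ftir.aggregate_differences(diffs)
            pd.DataFrame(
                {"wavenumber_cm-1": agg.wavenumbers[::-1], "absorbance": agg.absorbance[::-1]}
            ).to_csv(outdir / "difference_aggregate.csv", index=False)
            peak = float(agg.wavenumbers[np.argmax(agg.absorbance)])
            report["difference_peak_cm"] = peak
        spectra0 = [p.spectrum(i) for p in processed for i in range(p.times_min.size)]
        X = np.stack([s.absorbance for s in spectra0])
        pca_res = chemometrics.pca(X, n_components=2)
        pca_res.variable_axis = processed[0].wavenumbers
        _save_pca(pca_res, outdir / "spectra_pca")
        coords = [
            p.mosaic_xy if p.mosaic_xy is not None else (float(i), 0.0)
            for i, p in enumerate(processed)
            for _ in range(p.times_min.size)
        ]
        points = chemometrics.map_scores(pca_res, coords, component=0)
        (outdir / "score_map.json").write_text(json.dumps(points, indent=2))
        chemometrics.render_score_map(points, outdir / "score_map.png")
        report["pca_variance_fraction"] = pca_res.variance_fraction.tolist()

    report["manifest"] = str(_write_manifest(outdir, config, inputs))
    return report


def _save_pca(result, prefix: Path) -> None:
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.scores).to_csv(prefix.with_suffix(".scores.csv"), index=False)
    pd.DataFrame(result.loadings).to_csv(prefix.with_suffix(".loadings.csv"), index=False)
    pd.DataFrame({"variance_percent": result.variance_fraction}).to_csv(
        prefix.with_suffix(".variance.csv"), index=False
    )
    meta = {
        "n_components": int(result.n_components),
        "variable_axis": None
        if result.variable_axis is None
        else [float(v) for v in result.variable_axis],
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
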