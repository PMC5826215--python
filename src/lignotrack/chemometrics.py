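"""Shared multivariate and statistical layer.

Mean-centered PCA (no variance scaling — the chemometrics convention for
absorbance/intensity data, which keeps loadings interpretable as spectra),
PCA of kinetic curves, mapping of scores back onto mosaic coordinates,
k-means grouping of spectra with group-average spectra, region statistics and
fixed-effects variance analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ftir import Spectrum

__all__ = [
    "PcaResult",
    "pca",
    "pca_kinetics",
    "map_scores",
    "group_spectra",
    "group_stats",
    "anova",
]


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a PCA.

    Loadings are unit-norm columns with a deterministic sign convention (the
    largest-magnitude element of each loading is positive); variance fractions
    are percentages of the total centered variance, so they sum to <= 100
    when fewer components than the rank are kept.
    """

    scores: np.ndarray  # (n_obs, k)
    loadings: np.ndarray  # (n_vars, k)
    variance_fraction: np.ndarray  # percent, length k
    center: np.ndarray  # (n_vars,)
    variable_axis: np.ndarray | None = None  # wavenumbers or time grid
    observation_labels: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Back-project scores into the original (uncentered) variable space."""
        return self.scores @ self.loadings.T + self.center

    def summary(self) -> str:
        lines = ["Principal component analysis",
                 f"  observations: {self.scores.shape[0]}, variables: {self.center.size}"]
        for k, v in enumerate(self.variance_fraction, start=1):
            lines.append(f"  PC{k}: {v:6.2f}% of total variance")
        return "\n".join(lines)


def pca(matrix: np.ndarray, n_components: int | None = None) -> PcaResult:
    """Mean-centered PCA via SVD (no unit-variance scaling).

    ``scores = centered_data @ loadings``; variance fractions are
    ``100 * lambda_k / sum(lambda)`` over *all* eigenvalues of the covariance
    matrix, and the sign of each loading is fixed so its largest-magnitude
    element is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("input must be a 2-D observations x variables matrix")
    n_obs, n_vars = X.shape
    if n_obs < 2:
        raise ValueError("PCA requires at least 2 observations")
    max_k = min(n_obs - 1, n_vars)
    if n_components is None:
        n_components = max_k
    if not 1 <= n_components <= min(n_obs, n_vars):
        raise ValueError(
            f"n_components must be in [1, {min(n_obs, n_vars)}], got {n_components}"
        )
    n_components = min(n_components, max_k) or 1
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        # degenerate: all observations identical
        loadings = Vt[:n_components].T
        return PcaResult(
            scores=np.zeros((n_obs, n_components)),
            loadings=loadings,
            variance_fraction=np.zeros(n_components),
            center=center,
        )
    k = n_components
    loadings = Vt[:k].T.copy()
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|.| element of each loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    variance_fraction = 100.0 * (s[:k] ** 2) / total
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_fraction=variance_fraction,
        center=center,
    )


def _common_grid_curves(table: pd.DataFrame, value_col: str, resample: bool):
    """Pivot a kinetic table into curves on a shared time grid."""
    keys = ["experiment_id", "region_id", "cell_type_code", "is_cavity"]
    keys = [k for k in keys if k in table.columns]
    groups = list(table.groupby(keys, sort=True))
    grids = [np.sort(g["time_min"].unique()) for _, g in groups]
    same = all(len(g) == len(grids[0]) and np.allclose(g, grids[0]) for g in grids)
    if same:
        target = grids[0]
    elif not resample:
        raise ValueError(
            "kinetic curves are on inconsistent time grids; "
            "enable resampling to interpolate onto a common grid"
        )
    else:
        # coarsest grid restricted to the overlapping time range
        lo = max(g[0] for g in grids)
        hi = min(g[-1] for g in grids)
        if lo >= hi:
            raise ValueError("kinetic curves have no overlapping time range")
        target = min(grids, key=len)
        target = target[(target >= lo) & (target <= hi)]
    curves, labels = [], []
    for key, g in groups:
        g = g.sort_values("time_min")
        curves.append(np.interp(target, g["time_min"].to_numpy(), g[value_col].to_numpy()))
        labels.append(dict(zip(keys, key if isinstance(key, tuple) else (key,))))
    return np.asarray(curves), pd.DataFrame(labels), target


def pca_kinetics(
    table: pd.DataFrame,
    n_components: int = 2,
    value_col: str = "mean_intensity",
    resample: bool = True,
) -> PcaResult:
    """PCA of (normalized) kinetic curves; one observation per region curve.

    Curves from different experiments are linearly interpolated onto a common
    time grid when their acquisition grids differ.
    """
    curves, labels, grid = _common_grid_curves(table, value_col, resample)
    result = pca(curves, n_components=min(n_components, min(curves.shape[0] - 1, len(grid))))
    result.variable_axis = grid
    result.observation_labels = labels
    return result


def map_scores(
    result: PcaResult,
    coordinates: list[tuple[float, float]] | np.ndarray,
    component: int = 0,
    cmap: str = "viridis",
) -> list[dict]:
    """Attach PCA scores to mosaic coordinates as plottable coloured points."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (result.scores.shape[0], 2):
        raise ValueError(
            f"need one (x, y) pair per observation: got {coords.shape}, "
            f"expected ({result.scores.shape[0]}, 2)"
        )
    if not 0 <= component < result.n_components:
        raise ValueError(
            f"component {component} out of range [0, {result.n_components})"
        )
    from matplotlib import colormaps

    values = result.scores[:, component]
    span = values.max() - values.min()
    norm = (values - values.min()) / span if span > 0 else np.full_like(values, 0.5)
    palette = colormaps[cmap]
    return [
        {
            "x": float(x),
            "y": float(y),
            "score": float(v),
            "color": tuple(float(c) for c in palette(float(u))),
        }
        for (x, y), v, u in zip(coords, values, norm)
    ]


def render_score_map(points: list[dict], path, background=None) -> None:
    """Render coloured score points (from :func:`map_scores`) as a PNG overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper")
    xs = [p["x"] for p in points]
    ys = [p["y"] for p in points]
    colors = [p["color"] for p in points]
    ax.scatter(xs, ys, c=colors, s=40, edgecolors="black", linewidths=0.3)
    ax.set_xlabel("mosaic x (um)")
    ax.set_ylabel("mosaic y (um)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def group_spectra(
    spectra: list[Spectrum],
    k: int = 3,
    labels: list[int] | None = None,
    seed: int = 0,
    n_restarts: int = 50,
) -> tuple[np.ndarray, list[Spectrum]]:
    """Partition spectra into k groups and return per-group mean spectra.

    By default the spectra are clustered by k-means on their first two PCA
    score dimensions (fixed seed, multiple restarts); user-supplied labels
    bypass the clustering. Group ids are renumbered by ascending mean PC1
    score so the labelling is deterministic.
    """
    if not spectra:
        raise ValueError("no spectra to group")
    axis = spectra[0].wavenumbers
    for s in spectra:
        if s.wavenumbers.shape != axis.shape or not np.allclose(s.wavenumbers, axis):
            raise ValueError("all spectra must share the wavenumber axis")
    X = np.stack([s.absorbance for s in spectra])
    if labels is not None:
        out = np.asarray(labels)
        if out.size != len(spectra):
            raise ValueError("one label per spectrum required")
    else:
        if k < 1 or k > len(spectra):
            raise ValueError(f"k must be in [1, {len(spectra)}]")
        if k == 1:
            out = np.zeros(len(spectra), dtype=int)
        else:
            from sklearn.cluster import KMeans

            scores = pca(X, n_components=min(2, len(spectra) - 1, X.shape[1])).scores
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
            raw = km.fit_predict(scores)
            order = np.argsort(
                [scores[raw == g, 0].mean() for g in range(k)]
            )
            remap = {int(g): i for i, g in enumerate(order)}
            out = np.array([remap[int(g)] for g in raw])
    means = []
    for g in sorted(set(int(v) for v in out)):
        mask = out == g
        means.append(
            Spectrum(axis.copy(), X[mask].mean(axis=0), point_id=f"group{g}")
        )
    return out, means


def group_stats(table: pd.DataFrame, at_time: float) -> pd.DataFrame:
    """Per-cell-type mean and standard error of region means at one time point.

    SE = SD/sqrt(n) over regions; a single-region cell type reports SE 0 and
    is flagged by n = 1.
    """
    times = table["time_min"].unique()
    match = times[np.isclose(times, at_time)]
    if match.size == 0:
        raise ValueError(f"time {at_time} min not present; available: {sorted(times)}")
    sub = table[np.isclose(table["time_min"], match[0])]
    rows = []
    for code, g in sub.groupby("cell_type_code", sort=True):
        vals = g["mean_intensity"].to_numpy()
        n = vals.size
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "cell_type_code": code,
                "mean_intensity": float(vals.mean()),
                "standard_error": se,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


_FACTOR_COLUMNS = {
    "cell_type": "cell_type_code",
    "time": "time_min",
    "experiment": "experiment_id",
}


def anova(
    table: pd.DataFrame,
    factors: tuple[str, ...] = ("cell_type", "time", "experiment"),
) -> pd.DataFrame:
    """Fixed-effects main-effects ANOVA of intensities (type-II sums of squares).

    Factors are any subset of cell type, time and experiment, all treated as
    categorical. Returns one row per factor with F, p and degrees of freedom.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if not factors:
        raise ValueError("at least one factor required")
    cols = {}
    for f in factors:
        if f not in _FACTOR_COLUMNS:
            raise ValueError(f"unknown factor {f!r}; expected subset of {list(_FACTOR_COLUMNS)}")
        col = _FACTOR_COLUMNS[f]
        if table[col].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")
        cols[f] = col
    data = table.rename(columns={v: k for k, v in cols.items()}).copy()
    formula = "mean_intensity ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=2)
    rows = []
    for f in factors:
        row = aov.loc[f"C({f})"]
        rows.append(
            {
                "factor": f,
                "F": float(row["F"]),
                "p_value": float(row["PR(>F)"]),
                "df": float(row["df"]),
                "df_resid": float(aov.loc["Residual", "df"]),
            }
        )
    return pd.DataFrame(rows)
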