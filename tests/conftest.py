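import numpy as np
import pandas as pd
import pytest

import lignotrack as lt
from lignotrack.chemometrics import anova


@pytest.fixture(scope="session")
def noise_free_scene():
    """Default-geometry scene with all noise sources disabled."""
    cfg = lt.SceneConfig(poisson_noise=False, gaussian_sd_counts=0.0, seed=7)
    stack, truth = lt.generate_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Default scene with Poisson + Gaussian noise (the study-like condition)."""
    cfg = lt.SceneConfig(seed=7)
    stack, truth = lt.generate_scene(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def band_library():
    return lt.default_band_library()


def simulate_anova_table(rng, type_means=(50.0, 50.0, 50.0), sd=3.0,
                         n_regions=4, n_times=5, n_experiments=2):
    """Balanced intensity table: cell type x regions x times x experiments."""
    rows = []
    for e in range(n_experiments):
        for mean, ct in zip(type_means, ("a", "b", "c")):
            for r in range(n_regions):
                for t in range(n_times):
                    rows.append(
                        {
                            "experiment_id": f"e{e}",
                            "region_id": f"e{e}_{ct}{r}",
                            "cell_type_code": ct,
                            "is_cavity": False,
                            "time_min": 6.0 * t,
                            "mean_intensity": mean + rng.normal(0.0, sd),
                            "n_pixels": 100,
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_anova_pvalues():
    """Cell-type p-values from 1000 simulated null (no-effect) tables."""
    rng = np.random.default_rng(20240901)
    pvals = []
    for _ in range(1000):
        table = simulate_anova_table(rng)
        res = anova(table)
        pvals.append(float(res.loc[res["factor"] == "cell_type", "p_value"].iloc[0]))
    return np.asarray(pvals)
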