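import numpy as np
import pandas as pd
import pytest

import vectorshift as vs


@pytest.fixture(scope="session")
def small_landscape():
    """100x100 landscape with four gradient layers and mild noise.

    Large enough that the modelling domain dwarfs the presence set, as in a
    global-scale study, so pseudo-absence sampling is effectively uniform.
    """
    cfg = vs.LandscapeConfig(
        n_rows=100, n_cols=100, n_gradient_layers=4, noise_sd=0.5, seed=7
    )
    return cfg, vs.generate_landscape(cfg)


@pytest.fixture(scope="session")
def strong_signal_species(small_landscape):
    """A virtual species with a crisp Gaussian niche and its presences."""
    cfg, stack = small_landscape
    niche = vs.VirtualNiche(mu=(6, 6, 4, 5), sigma=(1.2, 1.2, 1.5, 1.5))
    suit = vs.suitability_surface(stack, niche)
    occ = vs.sample_occurrences(suit, stack.grid, 600, seed=3, population="native")
    return {"stack": stack, "niche": niche, "suitability": suit, "occurrences": occ}


@pytest.fixture(scope="session")
def sdm_result(strong_signal_species):
    """Fitted ensemble SDM on the strong-signal fixture (shared; ~10 s)."""
    sp = strong_signal_species
    return vs.fit_population_sdm(
        sp["occurrences"],
        sp["stack"],
        algorithms=("GLM", "RF", "CTA", "SRE"),
        replicates=3,
        repeats=5,
        seed=42,
    )


def make_occurrences(lons, lats, uncertainty=None, population="unassigned"):
    n = len(lons)
    return vs.OccurrenceSet(
        pd.DataFrame(
            {
                "lon": lons,
                "lat": lats,
                "uncertainty_km": uncertainty if uncertainty is not None else [np.nan] * n,
                "source": ["test"] * n,
                "population": [population] * n,
            }
        )
    )
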