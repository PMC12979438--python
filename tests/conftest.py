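import io

import numpy as np
import pytest

import seedlong as sl


@pytest.fixture
def gy_params():
    """Printed three-parameter Weibull fit for the GY population."""
    return sl.DecayParams("weibull3", (139.35, 329.10, -137.65))


@pytest.fixture
def gy_noise_free_assay(gy_params):
    """Noise-free replicate samples of the GY curve on the standard design."""
    times = [0.0, 1.0, 2.0, 3.0, 4.0]
    obs = []
    for t in times:
        v = sl.viability(t, gy_params)
        for r in (1, 2, 3):
            obs.append(
                sl.ViabilityObservation(
                    time=t, replicate=r, n_tested=1000, n_viable=round(1000 * v),
                    viability_override=float(v),
                )
            )
    return sl.ViabilityAssay(lot_id="GY", observations=obs)


@pytest.fixture
def assay_factory():
    """Binomial assays drawn from a known curve on the standard 5x3x50 design."""

    def make(params=(2.0, 4.0, -0.3), rng_seed=42, replicates=3, seeds=50):
        cfg = sl.SimulationConfig(
            params=sl.DecayParams("weibull3", tuple(params)),
            replicates=replicates,
            seeds_per_replicate=seeds,
            rng_seed=rng_seed,
        )
        return sl.simulate_assay(cfg)

    return make


@pytest.fixture
def viability_csv():
    """Two-lot, 5-timepoint, 3-replicate viability table as a CSV stream."""
    rng = np.random.default_rng(0)
    lines = ["lot_id,collection_year,habitat,time_days,replicate,n_tested,n_viable"]
    for lot, year in (("A", 2021), ("B", 2019)):
        for t in (0, 1, 2, 3, 4):
            for r in (1, 2, 3):
                v = int(rng.integers(0, 51))
                lines.append(f"{lot},{year},,{t},{r},50,{v}")
    return io.StringIO("\n".join(lines))
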