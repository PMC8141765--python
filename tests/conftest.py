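import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myfrquant import simdata
from myfrquant.msio import Run, Spectrum

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_run(peaks_per_scan, rts, polarity="negative"):
    """Build a run from explicit per-scan (mz, intensity) peak lists."""
    spectra = []
    for rt, peaks in zip(rts, peaks_per_scan):
        peaks = sorted(peaks)
        spectra.append(
            Spectrum(
                rt=float(rt),
                ms_level=1,
                polarity=polarity,
                mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]),
            )
        )
    return Run(spectra=spectra, metadata={"polarity": polarity})


@pytest.fixture
def wt_run():
    """Small wild-type-like run: tyrosine core, chains 6-24, with noise."""
    species = simdata.preset_species("wt_extorquens", core="tyrosine", rt_apex=60.0)
    cfg = simdata.SimConfig(scan_interval=1.0, rt_span=120.0, seed=42)
    run, truth = simdata.generate_run(species, cfg)
    return run, truth


@pytest.fixture
def single_species_run():
    """One species, one charge state, no noise: exact-recovery baseline."""
    sp = simdata.SimSpecies(
        formula={"C": 15, "H": 18, "N": 2, "O": 4},
        total_area=5.0e5,
        rt_apex=60.0,
        rt_sigma=4.0,
        charge_envelope={1: 1.0},
        label="core_only",
    )
    cfg = simdata.SimConfig(
        scan_interval=1.0,
        rt_span=120.0,
        noise_peaks_per_scan=0.0,
        ppm_jitter_sigma=0.0,
        intensity_threshold=1e-6,
        seed=7,
    )
    run, truth = simdata.generate_run([sp], cfg)
    return run, truth
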