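import numpy as np
import pytest

from spheroflux.flux_io import InjectionSchedule, WellKinetics

# Published 16-measurement mean OCR series (single- and multiple-spheroid
# cohorts) used as hand-checkable extraction fixtures.
SSP_MEAN_OCR = [
    54.24, 48.90, 47.54,                # basal 1-3
    47.97, 46.21, 44.16, 42.54, 41.01,  # oligomycin 4-8
    73.77, 75.22, 76.33, 77.31,         # FCCP 9-12
    60.53, 38.72, 28.34, 22.11,         # rot/AA 13-16
]
MSP_MEAN_OCR = [
    26.99, 24.64, 24.85,
    21.15, 16.79, 14.75, 13.91, 13.82,
    39.51, 35.34, 32.58, 30.55,
    17.33, 12.78, 11.97, 11.47,
]


@pytest.fixture
def schedule() -> InjectionSchedule:
    return InjectionSchedule.default_mito_stress()


def make_well(ocr, ecar=None, well_id="A2", schedule=None, assign=True) -> WellKinetics:
    """Build a WellKinetics from a plain OCR list, optionally phase-labelled."""
    ocr = np.asarray(ocr, dtype=float)
    n = len(ocr)
    ecar = np.zeros(n) if ecar is None else np.asarray(ecar, dtype=float)
    phase = None
    if assign:
        schedule = schedule or InjectionSchedule.default_mito_stress()
        phase = tuple(schedule.phase_of(i) for i in range(1, n + 1))
    return WellKinetics(
        well_id=well_id,
        index=np.arange(1, n + 1),
        time_min=np.arange(n, dtype=float) * 6.5,
        ocr=ocr,
        ecar=ecar,
        phase=phase,
    )


@pytest.fixture
def ssp_well(schedule) -> WellKinetics:
    return make_well(SSP_MEAN_OCR, schedule=schedule)


@pytest.fixture
def msp_well(schedule) -> WellKinetics:
    return make_well(MSP_MEAN_OCR, schedule=schedule)


def sample_with_moments(mean: float, sd: float, n: int, rng) -> np.ndarray:
    """An n-point sample whose sample mean and (n-1)-SD are exactly as given."""
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z
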