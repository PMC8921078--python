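import numpy as np
import pytest

from fractalperf import LesionInputs, PhantomSpec, RunConfig, generate_phantom, run_lesion


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=42))


def lesion_inputs_from(phantom, **overrides):
    kwargs = dict(
        series=phantom.series,
        muscle_roi=phantom.muscle_roi(),
        prostate=phantom.masks["prostate"],
        capsule=phantom.masks["capsule"],
        seed_point=phantom.truth["seed_point"],
        adc=phantom.adc,
        adc_hotspot=phantom.masks["adc_hotspot"],
    )
    kwargs.update(overrides)
    return LesionInputs(**kwargs)


@pytest.fixture(scope="session")
def default_lesion_artifacts(default_phantom):
    """Full pipeline output on the default phantom (computed once)."""
    return run_lesion(RunConfig(), lesion_inputs_from(default_phantom))


def fdmax_for(hurst: float, seed: int, **spec_overrides) -> float:
    ph = generate_phantom(PhantomSpec(hurst=hurst, seed=seed, **spec_overrides))
    art = run_lesion(RunConfig(), lesion_inputs_from(ph))
    return art.record.fdmax


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))
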