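import numpy as np
import pytest

from ggnquant.phantom import PhantomSpec, generate_nodule, sample_spec
from ggnquant.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def inv_phantom():
    """One invasive-class phantom with an embedded 3-mm solid focus."""
    spec = PhantomSpec(
        class_label="INV", diameter_mm=18.0, ggo_mean_hu=-600.0, ggo_sd_hu=80.0,
        right_tail_weight=0.2, solid_focus_mm=3.0, invasion_extent_mm=9.8, seed=42,
    )
    return generate_nodule(spec)


@pytest.fixture(scope="session")
def ais_phantom():
    """A pure ground-glass AIS phantom (no solid focus)."""
    spec = PhantomSpec(
        class_label="AIS", diameter_mm=13.0, ggo_mean_hu=-710.0, ggo_sd_hu=55.0,
        right_tail_weight=0.03, solid_focus_mm=0.0, invasion_extent_mm=0.0, seed=43,
    )
    return generate_nodule(spec)


def make_random_phantom(rng: np.random.Generator):
    """A random small phantom of a random class, for property sweeps."""
    label = str(rng.choice(["AIS", "MIA", "INV"]))
    seed = int(rng.integers(0, 2**31 - 1))
    spec = sample_spec(label, rng, seed)
    # keep property-sweep phantoms small so thousands fit in the time budget
    spec = PhantomSpec(
        class_label=spec.class_label,
        diameter_mm=float(np.clip(spec.diameter_mm, 5.0, 14.0)),
        ggo_mean_hu=spec.ggo_mean_hu,
        ggo_sd_hu=spec.ggo_sd_hu,
        right_tail_weight=spec.right_tail_weight,
        solid_focus_mm=spec.solid_focus_mm,
        invasion_extent_mm=spec.invasion_extent_mm,
        seed=seed,
    )
    return generate_nodule(spec)


@pytest.fixture(scope="session")
def default_cohort_analysis(tmp_path_factory):
    """One full default-cohort pipeline run (38/61/92 nodules, fixed seed)."""
    out = tmp_path_factory.mktemp("default_run")
    return run_pipeline(PipelineConfig(master_seed=11), out)
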