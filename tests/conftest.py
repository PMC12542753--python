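import numpy as np
import pytest

from viraltc.annotation import AnnotatedFeature, GenomeAnnotation, Strand
from viraltc.coverage import CoverageExperiment
from viraltc.simulate import SimulationSpec, simulate


def small_spec(**overrides) -> SimulationSpec:
    """A compact simulation for fast unit tests: ~15 genes on 9 kb."""
    kwargs = dict(
        seed=0,
        genome_length=9_000,
        n_features=14,
        n_trna=1,
        n_antisense_tss=4,
        noise="none",
        host_n_genes=400,
        host_planted_deg={5: (0, 0), 20: (2, 2), 60: (8, 8), 120: (12, 10), 180: (15, 12), 300: (14, 10)},
        enrich_category_size=20,
        enrich_planted_in_category=3,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


@pytest.fixture(scope="session")
def clean_bundle():
    """Default-size noise-free experiment with planted truth."""
    return simulate(SimulationSpec(seed=0, noise="none"))


@pytest.fixture(scope="session")
def small_bundle():
    return simulate(small_spec())


def make_experiment(
    tracks: np.ndarray,
    timepoints=(5, 20, 60, 120, 180, 300),
    library_size=None,
) -> CoverageExperiment:
    """Wrap a raw (T, R, 2, L) array into a CoverageExperiment."""
    tracks = np.asarray(tracks, dtype=float)
    T, R, _, L = tracks.shape
    if library_size is None:
        library_size = np.full((T, R), 1e6)
    return CoverageExperiment(L, tuple(timepoints[:T]), R, tracks, library_size)


def step_experiment(L=1000, step_at=100, depth=50.0, strand=Strand.FORWARD, T=6, R=3):
    """Ideal coverage step: zero before ``step_at``, ``depth`` after (forward)."""
    tracks = np.zeros((T, R, 2, L))
    si = 0 if strand is Strand.FORWARD else 1
    if strand is Strand.FORWARD:
        tracks[:, :, si, step_at:] = depth
    else:
        tracks[:, :, si, : step_at + 1] = depth
    return make_experiment(tracks)


def single_feature_annotation(start, end, strand=Strand.FORWARD, L=1000, fid="gp01"):
    return GenomeAnnotation("toy", L, [AnnotatedFeature(fid, start, end, strand)])
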