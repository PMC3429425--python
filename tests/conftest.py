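import numpy as np
import pytest

from ppisite import (
    AnnotationTracks,
    Chain,
    SyntheticSpec,
    extract_windows,
    generate_chain_with_tracks,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture()
def small_chain_tracks():
    """A 60-residue synthetic chain with full tracks and interaction sites."""
    spec = SyntheticSpec(length_range=(60, 60), seed=7)
    return generate_chain_with_tracks(spec)


@pytest.fixture()
def chain21():
    """An exactly-21-residue chain so the central window needs no padding."""
    return Chain("c21", "ACDEFGHIKLMNPQRSTVWYA")


def make_tracks(chain: Chain, rng=None, with_3d=True) -> AnnotationTracks:
    """Deterministic hand-rolled tracks for a given chain."""
    rng = rng or np.random.default_rng(11)
    n = chain.length
    kwargs = {}
    if with_3d:
        kwargs = {
            "cx": rng.normal(size=n),
            "dpx": rng.normal(size=n),
            "asa": rng.uniform(0, 100, size=n),
            "msa": rng.uniform(0, 120, size=n),
            "sc": rng.normal(size=n),
        }
    tracks = AnnotationTracks(
        chain_id=chain.chain_id,
        pssm=rng.integers(-8, 13, size=(n, 20)).astype(float),
        disorder=rng.uniform(0, 1, size=n),
        ss3=rng.choice(["helix", "strand", "other"], size=n),
        accessibility=rng.choice(["buried", "exposed"], size=n),
        **kwargs,
    )
    tracks.validate()
    return tracks


@pytest.fixture()
def windows21(chain21):
    return extract_windows(chain21, {11})
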