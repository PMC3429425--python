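"""Synthetic chains, annotation tracks and labeled feature matrices.

Two generators make every pipeline stage testable without external
databases or annotation tools:

* :func:`generate_feature_matrix` emits a labeled matrix with the exact
  34-per-site column layout of the encoder (714 columns for a 21-mer
  with 3D descriptors), a small set of planted informative columns that
  differ between classes by a chosen standardized mean shift, and
  within-(site, category)-block correlation produced by a shared latent
  factor with loading sqrt(rho).  Secondary-structure blocks stay valid
  one-hots.
* :func:`generate_chain_with_tracks` emits a random protein chain with
  self-consistent annotation tracks and interaction sites drawn among
  exposed residues, for exercising the windowing/encoding path.

The track distributions are stylized (integer-score conservation,
uniform disorder, Gaussian surface descriptors); they emulate the
statistical shape of real annotations, not alignment-derived PSSM
score distributions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .encoding import FeatureMatrix, feature_layout
from .io_formats import AA20, ACC_STATES, SS_STATES, AnnotationTracks, Chain


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the benchmark conditions of the method: 21-site
    windows with the 3D descriptor group (714 columns), chains of at
    least 50 residues, roughly balanced classes, a minority of
    informative columns with a strong standardized effect, and moderate
    within-block correlation.
    """

    n_chains: int = 20
    length_range: tuple[int, int] = (50, 200)
    positive_site_rate: float = 0.35
    n_samples: int = 1000
    class_balance: float = 0.5
    n_informative: int = 5
    effect_size: float = 3.0
    rho: float = 0.3
    n_sites: int = 21
    include_3d: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("within-block correlation rho must lie in [0, 1)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class balance must lie in (0, 1)")
        if not 0.0 <= self.positive_site_rate <= 1.0:
            raise ValueError("positive-site rate must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid chain length range")
        if self.n_sites % 2 != 1:
            raise ValueError("window length must be odd")


def generate_feature_matrix(
    spec: SyntheticSpec,
) -> tuple[FeatureMatrix, list[int]]:
    """A labeled feature matrix with planted informative columns.

    Returns the matrix and the ground-truth list of informative column
    indices (sorted).  Continuous columns have unit noise variance and a
    between-class mean shift of ``effect_size`` on informative columns;
    columns within one (site, category) block share correlation ``rho``.
    Secondary-structure one-hot blocks are drawn categorically and carry
    no planted signal.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    meta = feature_layout(spec.n_sites, spec.include_3d)
    n, m = spec.n_samples, len(meta)

    continuous = [mm.column_index for mm in meta
                  if mm.category != "SecondaryStructure"]
    if spec.n_informative > len(continuous):
        raise ValueError(
            f"n_informative={spec.n_informative} exceeds the "
            f"{len(continuous)} continuous columns"
        )

    labels = (rng.random(n) < spec.class_balance).astype(int)
    informative = sorted(
        int(c) for c in rng.choice(continuous, size=spec.n_informative,
                                   replace=False)
    )
    informative_set = set(informative)

    values = np.zeros((n, m))
    # continuous blocks: shared latent factor per (site, category) block
    blocks: dict[tuple[int, str], list[int]] = {}
    for mm in meta:
        if mm.category != "SecondaryStructure":
            blocks.setdefault((mm.site, mm.category), []).append(mm.column_index)
    load = np.sqrt(spec.rho)
    resid = np.sqrt(1.0 - spec.rho)
    for key in sorted(blocks):
        latent = rng.standard_normal(n)
        for col in blocks[key]:
            values[:, col] = load * latent + resid * rng.standard_normal(n)
            if col in informative_set:
                values[:, col] += spec.effect_size * labels

    # secondary-structure blocks: one categorical draw per site per sample
    ss_cols: dict[int, list[int]] = {}
    for mm in meta:
        if mm.category == "SecondaryStructure":
            ss_cols.setdefault(mm.site, []).append(mm.column_index)
    probs = np.array([0.35, 0.25, 0.40])
    for site in sorted(ss_cols):
        states = rng.choice(3, size=n, p=probs)
        for k, col in enumerate(ss_cols[site]):
            values[:, col] = (states == k).astype(float)

    fm = FeatureMatrix(values, meta, labels)
    fm.validate()
    return fm, informative


def generate_chain_with_tracks(
    spec: SyntheticSpec,
    chain_id: str = "synth1",
    rng: np.random.Generator | None = None,
) -> tuple[Chain, AnnotationTracks, set[int]]:
    """A random chain plus self-consistent tracks and interaction sites.

    Interaction sites are drawn per exposed residue at the positive-site
    rate, so the buried-center filter cannot remove positives.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    sequence = "".join(rng.choice(list(AA20), size=length))
    pssm = rng.integers(-8, 13, size=(length, 20)).astype(float)
    disorder = rng.random(length)
    ss3 = rng.choice(list(SS_STATES), size=length, p=[0.35, 0.25, 0.40])
    accessibility = rng.choice(list(ACC_STATES), size=length, p=[0.45, 0.55])
    kwargs = {}
    if spec.include_3d:
        kwargs = {
            "cx": rng.normal(0.0, 1.0, length),
            "dpx": np.abs(rng.normal(1.0, 0.8, length)),
            "asa": np.clip(rng.normal(60.0, 25.0, length), 0.0, None),
            "msa": np.clip(rng.normal(80.0, 30.0, length), 0.0, None),
            "sc": rng.normal(0.0, 0.5, length),
        }
    tracks = AnnotationTracks(chain_id, pssm, disorder, ss3, accessibility, **kwargs)
    tracks.validate()
    exposed = np.flatnonzero(accessibility == "exposed") + 1  # 1-based
    drawn = rng.random(len(exposed)) < spec.positive_site_rate
    sites = {int(p) for p in exposed[drawn]}
    return Chain(chain_id, sequence), tracks, sites


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[Chain], dict[str, AnnotationTracks], dict[str, set[int]]]:
    """n_chains chains with tracks and interaction-site annotations."""
    rng = np.random.default_rng(spec.seed)
    chains: list[Chain] = []
    tracks: dict[str, AnnotationTracks] = {}
    sites: dict[str, set[int]] = {}
    for i in range(spec.n_chains):
        cid = f"synth{i + 1}"
        chain, tr, ss = generate_chain_with_tracks(spec, chain_id=cid, rng=rng)
        chains.append(chain)
        tracks[cid] = tr
        sites[cid] = ss
    return chains, tracks, sites
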