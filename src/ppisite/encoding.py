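"""Turn peptide windows plus annotation tracks into fixed-length feature vectors.

Each window site contributes a fixed block of columns, site-major (all of
site 1's block, then site 2's, ...).  Within a site the order is:

    PSSM (20 columns, PSI-BLAST alphabet order)
    amino-acid factors (5: polarity, secondary structure, molecular
        volume, codon diversity, electrostatic charge)
    disorder (1)
    secondary structure one-hot (3: helix=100, strand=010, other=001)
    CX, DPX, AS, MS, SC (5, only when 3D descriptors are enabled)

giving 34 columns per site with the 3D group (34*21 = 714 for a 21-mer)
and 29 without (29*21 = 609).  Padding "X" sites contribute all-zero
columns.  Solvent accessibility is used only to filter buried-center
windows and is deliberately never encoded — it is not part of the
34-column block.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .io_formats import PSSM_ALPHABET, SS_STATES, AnnotationTracks, ConsistencyError
from .windowing import POSITIVE, PeptideWindow

CATEGORIES = (
    "PSSM", "AAFactor", "Disorder", "SecondaryStructure",
    "CX", "DPX", "AS", "MS", "SC",
)
CATEGORIES_3D = ("CX", "DPX", "AS", "MS", "SC")

FACTOR_NAMES = (
    "polarity", "secondary_structure", "molecular_volume",
    "codon_diversity", "charge",
)

# Five-factor physicochemical solution of Atchley et al. (2005), PNAS 102:
# factor scores per amino acid (polarity/accessibility, secondary-structure
# propensity, molecular volume, codon diversity, electrostatic charge).
# "X" (padding / unknown) maps to five zeros.
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "C": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "D": (1.050, 0.302, -3.656, -0.259, -3.242),
    "E": (1.357, -1.453, 1.477, 0.113, -0.837),
    "F": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "G": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "H": (0.336, -0.417, -1.673, -1.474, -0.078),
    "I": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "K": (1.831, -0.561, 0.533, -0.277, 1.648),
    "L": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "M": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "N": (0.945, 0.828, 1.299, -0.169, 0.933),
    "P": (0.189, 2.081, -1.628, 0.421, -1.392),
    "Q": (0.931, -0.179, -3.005, -0.503, -1.853),
    "R": (1.538, -0.055, 1.502, 0.440, 2.897),
    "S": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "T": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "V": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "W": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "Y": (0.260, 0.830, 3.097, -0.838, 1.512),
    "X": (0.0, 0.0, 0.0, 0.0, 0.0),
}

COLUMNS_PER_SITE_3D = 34
COLUMNS_PER_SITE_NO3D = 29


@dataclasses.dataclass(frozen=True)
class FeatureMeta:
    """Metadata for one feature column: window site, category, subfeature."""

    column_index: int  # 0-based
    site: int  # 1-based window site
    category: str
    subname: str

    @property
    def name(self) -> str:
        return f"{self.category}.{self.subname}@site{self.site}"


@dataclasses.dataclass
class FeatureMatrix:
    """samples x features table with per-column metadata and class labels."""

    values: np.ndarray  # n_samples x n_features, float
    meta: list[FeatureMeta]
    labels: np.ndarray  # n_samples, int (1 = interaction site, 0 = not)

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_features(self) -> int:
        return int(self.values.shape[1])

    @property
    def feature_names(self) -> list[str]:
        return [m.name for m in self.meta]

    def validate(self) -> None:
        if self.values.shape != (len(self.labels), len(self.meta)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.labels)} labels / {len(self.meta)} meta entries"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")


def feature_layout(n_sites: int = 21, include_3d: bool = True) -> list[FeatureMeta]:
    """The per-column metadata of the feature space, site-major."""
    meta: list[FeatureMeta] = []
    col = 0
    for site in range(1, n_sites + 1):
        for aa in PSSM_ALPHABET:
            meta.append(FeatureMeta(col, site, "PSSM", aa)); col += 1
        for fname in FACTOR_NAMES:
            meta.append(FeatureMeta(col, site, "AAFactor", fname)); col += 1
        meta.append(FeatureMeta(col, site, "Disorder", "score")); col += 1
        for state in SS_STATES:
            meta.append(FeatureMeta(col, site, "SecondaryStructure", state)); col += 1
        if include_3d:
            for cat, track in zip(CATEGORIES_3D, ("cx", "dpx", "asa", "msa", "sc")):
                meta.append(FeatureMeta(col, site, cat, "value")); col += 1
    return meta


def encode_window(
    window: PeptideWindow,
    tracks: AnnotationTracks,
    include_3d: bool = True,
) -> tuple[np.ndarray, list[FeatureMeta]]:
    """Encode one window as a flat feature vector plus its column metadata.

    Padded sites contribute all-zero columns.  Raises a ConsistencyError
    when 3D features are requested but the track group is absent.
    """
    if include_3d and not tracks.has_3d:
        raise ConsistencyError(
            f"chain {tracks.chain_id!r}: 3D features requested but the "
            f"CX/DPX/AS/MS/SC track group is absent"
        )
    if window.chain_id != tracks.chain_id:
        raise ConsistencyError(
            f"window chain {window.chain_id!r} does not match tracks for "
            f"{tracks.chain_id!r}"
        )
    n_sites = window.n_sites
    per_site = COLUMNS_PER_SITE_3D if include_3d else COLUMNS_PER_SITE_NO3D
    vec = np.zeros(per_site * n_sites, dtype=float)
    half = n_sites // 2
    for s in range(n_sites):
        if window.pad_mask[s]:
            continue  # padding "X": all features stay 0
        pos0 = window.center_pos - 1 - half + s  # 0-based chain index
        base = s * per_site
        vec[base : base + 20] = tracks.pssm[pos0]
        vec[base + 20 : base + 25] = ATCHLEY_FACTORS[window.residues[s]]
        vec[base + 25] = tracks.disorder[pos0]
        ss_idx = SS_STATES.index(tracks.ss3[pos0])
        vec[base + 26 + ss_idx] = 1.0
        if include_3d:
            vec[base + 29] = tracks.cx[pos0]
            vec[base + 30] = tracks.dpx[pos0]
            vec[base + 31] = tracks.asa[pos0]
            vec[base + 32] = tracks.msa[pos0]
            vec[base + 33] = tracks.sc[pos0]
    return vec, feature_layout(n_sites, include_3d)


def build_matrix(
    windows: Sequence[PeptideWindow],
    tracks_by_chain: Mapping[str, AnnotationTracks],
    include_3d: bool = True,
) -> FeatureMatrix:
    """Encode windows into a FeatureMatrix; row order follows window order."""
    if not windows:
        raise ValueError("no windows to encode")
    n_sites = windows[0].n_sites
    meta = feature_layout(n_sites, include_3d)
    values = np.zeros((len(windows), len(meta)), dtype=float)
    labels = np.zeros(len(windows), dtype=int)
    for i, w in enumerate(windows):
        if w.n_sites != n_sites:
            raise ValueError(
                f"row {i}: window has {w.n_sites} sites, expected {n_sites}"
            )
        try:
            tracks = tracks_by_chain[w.chain_id]
        except KeyError:
            raise ConsistencyError(
                f"row {i}: no annotation tracks for chain {w.chain_id!r}"
            ) from None
        try:
            values[i], _ = encode_window(w, tracks, include_3d)
        except Exception as exc:
            raise type(exc)(f"row {i} (chain {w.chain_id!r}, "
                            f"pos {w.center_pos}): {exc}") from exc
        labels[i] = 1 if w.label == POSITIVE else 0
    fm = FeatureMatrix(values, meta, labels)
    fm.validate()
    return fm


# ---------------------------------------------------------------------------
# FeatureMatrix TSV serialization (header row = feature names + "label")
# ---------------------------------------------------------------------------

def write_matrix_tsv(fm: FeatureMatrix, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(fm.feature_names + ["label"]) + "\n")
        for row, lab in zip(fm.values, fm.labels):
            fh.write("\t".join(repr(float(v)) for v in row) + f"\t{int(lab)}\n")


def write_meta_tsv(meta: Sequence[FeatureMeta], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("column_index\tsite\tcategory\tsubname\n")
        for m in meta:
            fh.write(f"{m.column_index}\t{m.site}\t{m.category}\t{m.subname}\n")


def read_meta_tsv(path) -> list[FeatureMeta]:
    meta = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            col, site, cat, sub = line.rstrip("\n").split("\t")
            meta.append(FeatureMeta(int(col), int(site), cat, sub))
    return meta


def meta_from_name(name: str, column_index: int = 0) -> FeatureMeta:
    """Invert the ``<category>.<subname>@site<k>`` feature-name grammar."""
    catsub, sep, site = name.rpartition("@site")
    cat, dot, sub = catsub.partition(".")
    if not sep or not dot or not site.isdigit():
        raise ValueError(f"not a feature name: {name!r}")
    return FeatureMeta(column_index, int(site), cat, sub)


def read_matrix_tsv(path) -> FeatureMatrix:
    """Read a feature-matrix TSV; metadata is reconstructed from names."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if "label" not in df.columns:
        raise ValueError(f"{path}: matrix TSV lacks a 'label' column")
    labels = df.pop("label").to_numpy(dtype=int)
    meta = [meta_from_name(name, i) for i, name in enumerate(df.columns)]
    return FeatureMatrix(df.to_numpy(dtype=float), meta, labels)
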