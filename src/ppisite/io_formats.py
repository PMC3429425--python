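"""Readers and writers for the file formats the pipeline touches.

Sequence input is FASTA; per-residue conservation comes from PSI-BLAST
ASCII PSSM dumps; the remaining annotation tracks (disorder, 3-state
secondary structure, 2-state solvent accessibility and the five surface
descriptors CX/DPX/AS/MS/SC) are plain ``pos<TAB>value`` TSV files keyed
by 1-based residue position.  Internal result tables (MaxRel, mRMR, IFS,
optimal feature list) are TSV with optional ``#``-prefixed header lines.

Positions are 1-based in every file and error message; in-memory indices
are 0-based.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: sequence alphabet: the 20 standard amino acids plus the padding letter
ALPHABET = frozenset(AA20) | {"X"}

#: amino-acid column order of a PSI-BLAST ASCII PSSM header
PSSM_ALPHABET = tuple("ARNDCQEGHILKMFPSTWYV")

SS_STATES = ("helix", "strand", "other")
ACC_STATES = ("buried", "exposed")

#: names of the five per-residue 3D surface descriptor tracks
TRACKS_3D = ("cx", "dpx", "asa", "msa", "sc")


class FormatError(ValueError):
    """Raised when an input file does not follow its declared format."""


class ConsistencyError(ValueError):
    """Raised when tracks and chain disagree (length, range, alphabet)."""


@dataclasses.dataclass(frozen=True)
class Chain:
    """A protein chain: identifier plus sequence over the 20 letters and X."""

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise FormatError(
                f"chain {self.chain_id!r}: illegal letters {sorted(bad)} "
                f"(allowed: 20 standard amino acids and X)"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass
class AnnotationTracks:
    """Per-residue feature tracks for one chain.

    The five 3D descriptor tracks are either all present or all absent
    (``has_3d``); every present track has exactly ``length`` entries.
    """

    chain_id: str
    pssm: np.ndarray  # length x 20, PSI-BLAST log-odds, columns = PSSM_ALPHABET
    disorder: np.ndarray  # length, in [0, 1]
    ss3: np.ndarray  # length, strings from SS_STATES
    accessibility: np.ndarray  # length, strings from ACC_STATES
    cx: np.ndarray | None = None
    dpx: np.ndarray | None = None
    asa: np.ndarray | None = None
    msa: np.ndarray | None = None
    sc: np.ndarray | None = None

    @property
    def length(self) -> int:
        return int(self.pssm.shape[0])

    @property
    def has_3d(self) -> bool:
        return self.cx is not None

    def validate(self) -> None:
        n = self.length
        if self.pssm.shape != (n, 20):
            raise ConsistencyError(
                f"chain {self.chain_id!r}: pssm shape {self.pssm.shape} != ({n}, 20)"
            )
        for name in ("disorder", "ss3", "accessibility"):
            if len(getattr(self, name)) != n:
                raise ConsistencyError(
                    f"chain {self.chain_id!r}: track {name!r} has "
                    f"{len(getattr(self, name))} entries, expected {n}"
                )
        if np.any(self.disorder < 0) or np.any(self.disorder > 1):
            raise ConsistencyError(
                f"chain {self.chain_id!r}: disorder values outside [0, 1]"
            )
        if not set(self.ss3) <= set(SS_STATES):
            raise ConsistencyError(
                f"chain {self.chain_id!r}: ss3 states outside {SS_STATES}"
            )
        if not set(self.accessibility) <= set(ACC_STATES):
            raise ConsistencyError(
                f"chain {self.chain_id!r}: accessibility states outside {ACC_STATES}"
            )
        present = [t for t in TRACKS_3D if getattr(self, t) is not None]
        if present and len(present) != len(TRACKS_3D):
            missing = sorted(set(TRACKS_3D) - set(present))
            raise ConsistencyError(
                f"chain {self.chain_id!r}: 3D tracks must be all present or all "
                f"absent; missing {missing}"
            )
        for t in present:
            if len(getattr(self, t)) != n:
                raise ConsistencyError(
                    f"chain {self.chain_id!r}: track {t!r} has "
                    f"{len(getattr(self, t))} entries, expected {n}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[Chain]:
    """Read a FASTA file into Chain objects, one per record, in file order.

    Letters outside the 20 standard amino acids plus X are rejected with a
    FormatError naming the offending record.  An empty file yields [].
    """
    chains: list[Chain] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise FormatError(
                f"FASTA record {record.id!r}: illegal letters {sorted(bad)}"
            )
        chains.append(Chain(record.id, seq))
    return chains


def write_fasta(chains: Iterable[Chain], path: str | Path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chain in chains:
            fh.write(f">{chain.chain_id}\n")
            for i in range(0, chain.length, width):
                fh.write(chain.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm(path: str | Path, expected_length: int | None = None) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into a length x 20 matrix of scores.

    Only the first 20 score columns (the log-odds block) are used; the
    column order is the PSI-BLAST header order (``PSSM_ALPHABET``).  Data
    rows start with the 1-based position and the residue letter.
    """
    rows: list[list[float]] = []
    positions: list[int] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            # data rows: "<pos> <letter> <20+ numbers ...>"
            if len(fields) >= 22 and fields[0].isdigit() and len(fields[1]) == 1:
                try:
                    scores = [float(v) for v in fields[2:22]]
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric PSSM score ({exc})"
                    ) from None
                positions.append(int(fields[0]))
                rows.append(scores)
            elif fields and fields[0].isdigit() and len(fields) > 2:
                raise FormatError(
                    f"{path}:{lineno}: PSSM row at position {fields[0]} has "
                    f"{len(fields) - 2} score columns, expected at least 20"
                )
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    if positions != list(range(1, len(positions) + 1)):
        raise FormatError(f"{path}: PSSM positions are not consecutive from 1")
    matrix = np.asarray(rows, dtype=float)
    if expected_length is not None and matrix.shape[0] != expected_length:
        raise FormatError(
            f"{path}: PSSM has {matrix.shape[0]} rows, declared sequence "
            f"length is {expected_length}"
        )
    return matrix


def write_pssm(matrix: np.ndarray, path: str | Path, sequence: str | None = None) -> None:
    """Write a length x 20 matrix in PSI-BLAST ASCII PSSM layout."""
    matrix = np.asarray(matrix)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("    " + "  ".join(PSSM_ALPHABET) * 2 + "\n")
        for i, row in enumerate(matrix):
            letter = sequence[i] if sequence else "X"
            scores = " ".join(f"{v:g}" for v in row)
            # repeat the block so rows carry >= 40 numeric columns like the
            # real tool (log-odds then percentages)
            fh.write(f"{i + 1:5d} {letter} {scores} {scores}\n")


# ---------------------------------------------------------------------------
# Annotation track TSVs
# ---------------------------------------------------------------------------

def _read_track_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["pos", "value"], dtype={"pos": int})
    return df.sort_values("pos", kind="stable").reset_index(drop=True)


def _track_values(path: str | Path, chain: Chain, name: str) -> np.ndarray:
    df = _read_track_tsv(path)
    if list(df["pos"]) != list(range(1, chain.length + 1)):
        raise ConsistencyError(
            f"track {name!r} for chain {chain.chain_id!r}: positions do not "
            f"cover 1..{chain.length} exactly"
        )
    return df["value"].to_numpy()


def read_tracks(paths: Mapping[str, str | Path], chain: Chain) -> AnnotationTracks:
    """Assemble AnnotationTracks for ``chain`` from per-track files.

    ``paths`` maps track names (pssm, disorder, ss3, accessibility, and
    optionally the 3D group cx/dpx/asa/msa/sc) to file paths.  Track rows
    may appear in any order; they are keyed by 1-based position.  If the
    3D files are missing the 3D group is absent.
    """
    required = ("pssm", "disorder", "ss3", "accessibility")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ConsistencyError(
            f"chain {chain.chain_id!r}: missing required track files {missing}"
        )
    pssm = read_pssm(paths["pssm"], expected_length=chain.length)
    disorder = _track_values(paths["disorder"], chain, "disorder").astype(float)
    ss3 = _track_values(paths["ss3"], chain, "ss3").astype(str)
    acc = _track_values(paths["accessibility"], chain, "accessibility").astype(str)

    present_3d = [t for t in TRACKS_3D if t in paths]
    kwargs: dict[str, np.ndarray] = {}
    if present_3d:
        if len(present_3d) != len(TRACKS_3D):
            raise ConsistencyError(
                f"chain {chain.chain_id!r}: 3D track files must be supplied as a "
                f"group; got only {present_3d}"
            )
        for t in TRACKS_3D:
            kwargs[t] = _track_values(paths[t], chain, t).astype(float)

    tracks = AnnotationTracks(chain.chain_id, pssm, disorder, ss3, acc, **kwargs)
    tracks.validate()
    return tracks


def write_track_tsv(values: Sequence, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, v in enumerate(values, start=1):
            fh.write(f"{i}\t{v}\n")


def read_sites(path: str | Path) -> dict[str, set[int]]:
    """Read interaction-site annotations (``chain_id<TAB>pos`` TSV)."""
    sites: dict[str, set[int]] = {}
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chain_id", "pos"], dtype={"chain_id": str, "pos": int})
    for cid, pos in zip(df["chain_id"], df["pos"]):
        sites.setdefault(cid, set()).add(int(pos))
    return sites


def write_sites(sites: Mapping[str, Iterable[int]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid in sites:
            for pos in sorted(sites[cid]):
                fh.write(f"{cid}\t{pos}\n")


# ---------------------------------------------------------------------------
# Result tables (MaxRel / mRMR / IFS / optimal feature list)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_maxrel_table(entries, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a MaxRel ranking: rank, feature name, relevance score."""
    df = pd.DataFrame(
        [(e.h, e.name, e.score) for e in entries],
        columns=["rank", "feature", "relevance"],
    )
    _write_tsv(df, path, header_lines)


def write_mrmr_table(entries, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write an mRMR ranking: selection round h, feature name, score."""
    df = pd.DataFrame(
        [(e.h, e.name, e.score) for e in entries],
        columns=["h", "feature", "score"],
    )
    _write_tsv(df, path, header_lines)


def write_ifs_table(records, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write an IFS table: subset size i, Sn, Pr, Sp, Ac, MCC."""
    df = pd.DataFrame(
        [(r.i, r.sensitivity, r.precision, r.specificity, r.accuracy, r.mcc)
         for r in records],
        columns=["i", "Sn", "Pr", "Sp", "Ac", "MCC"],
    )
    _write_tsv(df, path, header_lines)


def read_ifs_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_optimal_list(names: Sequence[str], path: str | Path,
                       header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame({"index": range(1, len(names) + 1), "feature": list(names)})
    _write_tsv(df, path, header_lines)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back any of the TSV result tables (``#`` headers skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
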