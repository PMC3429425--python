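"""Build labeled peptide windows around candidate residues.

Every residue of a chain becomes the center of one window of 2w+1 sites
(default w=10, a 21-mer with the candidate at site 11).  Windows centered
on an annotated interaction residue are the positive class; all others
are negative.  Sites that fall outside the chain are padded with "X" and
flagged in the pad mask.  Windows centered on residues predicted buried
are removed before encoding, since buried residues essentially never form
part of a protein-protein interface.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .io_formats import AnnotationTracks, Chain, ConsistencyError

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclasses.dataclass(frozen=True)
class PeptideWindow:
    """A 2w+1-site residue window with padding mask and center label.

    Sites are numbered 1..2w+1; the candidate residue sits at site w+1
    (site 11 for the default 21-mer) and is never a padding "X".
    """

    chain_id: str
    center_pos: int  # 1-based residue index in the source chain
    residues: str
    pad_mask: tuple[bool, ...]
    label: str

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length must be odd, got {n}")
        if len(self.pad_mask) != n:
            raise ValueError("pad_mask length must equal window length")
        center = n // 2
        if self.residues[center] == "X":
            raise ValueError("window center must be a real residue, not padding")
        for res, padded in zip(self.residues, self.pad_mask):
            if padded != (res == "X"):
                # a genuine X in the chain is not boundary padding; the mask
                # must mark exactly the boundary-padded sites
                if padded and res != "X":
                    raise ValueError("pad_mask marks a non-X site as padded")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")

    @property
    def n_sites(self) -> int:
        return len(self.residues)

    @property
    def center_site(self) -> int:
        """1-based site index of the candidate residue (11 for a 21-mer)."""
        return self.n_sites // 2 + 1


def extract_windows(
    chain: Chain,
    interaction_sites: Iterable[int],
    half_width: int = 10,
) -> list[PeptideWindow]:
    """Extract one labeled window per residue of ``chain``.

    ``interaction_sites`` are 1-based residue positions annotated as
    interface residues; windows centered on them are labeled positive.
    Sites within ``half_width`` of either chain end are padded with "X".
    """
    sites = set(interaction_sites)
    out_of_range = [p for p in sites if not 1 <= p <= chain.length]
    if out_of_range:
        raise IndexError(
            f"chain {chain.chain_id!r}: interaction sites {sorted(out_of_range)} "
            f"outside 1..{chain.length}"
        )
    windows: list[PeptideWindow] = []
    seq = chain.sequence
    for center in range(1, chain.length + 1):
        left_pad = max(0, half_width - (center - 1))
        right_pad = max(0, center + half_width - chain.length)
        start = max(0, center - 1 - half_width)
        stop = min(chain.length, center + half_width)
        residues = "X" * left_pad + seq[start:stop] + "X" * right_pad
        pad_mask = (
            (True,) * left_pad
            + (False,) * (stop - start)
            + (True,) * right_pad
        )
        windows.append(
            PeptideWindow(
                chain_id=chain.chain_id,
                center_pos=center,
                residues=residues,
                pad_mask=pad_mask,
                label=POSITIVE if center in sites else NEGATIVE,
            )
        )
    return windows


def filter_buried(
    windows: Sequence[PeptideWindow], tracks: AnnotationTracks
) -> list[PeptideWindow]:
    """Drop windows whose center residue is predicted buried.

    Applies to positive and negative windows alike; relative order is
    preserved.  Requires the accessibility track for the windows' chain.
    """
    if tracks.accessibility is None:
        raise ConsistencyError("accessibility track required for buried filtering")
    kept = []
    for w in windows:
        if w.chain_id != tracks.chain_id:
            raise ConsistencyError(
                f"window chain {w.chain_id!r} does not match tracks for "
                f"{tracks.chain_id!r}"
            )
        if tracks.accessibility[w.center_pos - 1] == "exposed":
            kept.append(w)
    return kept


def min_length_filter(chains: Sequence[Chain], min_len: int = 50) -> list[Chain]:
    """Keep chains of length >= ``min_len`` (default 50), order preserved."""
    return [c for c in chains if c.length >= min_len]


def write_windows_tsv(windows: Sequence[PeptideWindow], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chain_id\tcenter_pos\tresidues\tpad_mask\tlabel\n")
        for w in windows:
            mask = "".join("1" if p else "0" for p in w.pad_mask)
            fh.write(f"{w.chain_id}\t{w.center_pos}\t{w.residues}\t{mask}\t{w.label}\n")


def read_windows_tsv(path) -> list[PeptideWindow]:
    windows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("chain_id"):
            raise ValueError(f"{path}: not a windows TSV")
        for line in fh:
            cid, pos, residues, mask, label = line.rstrip("\n").split("\t")
            windows.append(
                PeptideWindow(cid, int(pos), residues,
                              tuple(c == "1" for c in mask), label)
            )
    return windows
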