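"""Summaries of an optimal feature set by category and by window site.

Given the metadata of a selected feature set, count features per
category (all nine categories, plus the merged CX+DPX and AS+MS+SC
panels), per window site 1..21, per PSSM target amino acid, and per
amino-acid factor.  These distributions show which information sources
and which positions around the candidate residue drive the predictor.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

from .encoding import CATEGORIES, FeatureMeta
from .mrmr import RankedFeature, RankedFeatureList


@dataclasses.dataclass(frozen=True)
class FeatureDistribution:
    by_category: dict[str, int]          # all nine categories
    by_category_grouped: dict[str, int]  # CX+DPX and AS+MS+SC merged
    by_site: dict[int, int]
    by_pssm_target: dict[str, int]       # PSSM columns only
    by_factor: dict[str, int]            # AAFactor columns only

    @property
    def total(self) -> int:
        return sum(self.by_category.values())

    def to_json(self) -> str:
        payload = {
            "total": self.total,
            "by_category": self.by_category,
            "by_category_grouped": self.by_category_grouped,
            "by_site": {str(k): v for k, v in self.by_site.items()},
            "by_pssm_target": self.by_pssm_target,
            "by_factor": self.by_factor,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


_GROUPS = {
    "CX": "CX+DPX", "DPX": "CX+DPX",
    "AS": "AS+MS+SC", "MS": "AS+MS+SC", "SC": "AS+MS+SC",
}


def summarize(optimal: Sequence[FeatureMeta]) -> FeatureDistribution:
    """Count a feature set's columns by category, site, PSSM target, factor.

    Pure metadata bookkeeping: independent of feature values.  The
    category counts partition the set (sum over categories == sum over
    sites == set size).
    """
    by_category = {c: 0 for c in CATEGORIES}
    by_grouped: dict[str, int] = {}
    by_site: dict[int, int] = {}
    by_pssm: dict[str, int] = {}
    by_factor: dict[str, int] = {}
    for m in optimal:
        if m.category not in by_category:
            raise ValueError(f"unknown feature category {m.category!r}")
        by_category[m.category] += 1
        group = _GROUPS.get(m.category, m.category)
        by_grouped[group] = by_grouped.get(group, 0) + 1
        by_site[m.site] = by_site.get(m.site, 0) + 1
        if m.category == "PSSM":
            by_pssm[m.subname] = by_pssm.get(m.subname, 0) + 1
        elif m.category == "AAFactor":
            by_factor[m.subname] = by_factor.get(m.subname, 0) + 1
    return FeatureDistribution(by_category, by_grouped, by_site, by_pssm, by_factor)


def rank_positions(
    prefix: RankedFeatureList | Sequence[RankedFeature],
) -> list[tuple[str, int]]:
    """(feature name, selection round h) pairs of a ranking prefix, by h."""
    entries = prefix.entries if isinstance(prefix, RankedFeatureList) else prefix
    return sorted(((e.name, e.h) for e in entries), key=lambda p: p[1])


def write_distribution_tsv(dist: FeatureDistribution, path) -> None:
    """Long-format TSV (grouping, key, count) for external bar plotting."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("grouping\tkey\tcount\n")
        for key, v in dist.by_category.items():
            fh.write(f"category\t{key}\t{v}\n")
        for key, v in dist.by_category_grouped.items():
            fh.write(f"category_grouped\t{key}\t{v}\n")
        for site in sorted(dist.by_site):
            fh.write(f"site\t{site}\t{dist.by_site[site]}\n")
        for key, v in sorted(dist.by_pssm_target.items()):
            fh.write(f"pssm_target\t{key}\t{v}\n")
        for key, v in sorted(dist.by_factor.items()):
            fh.write(f"factor\t{key}\t{v}\n")
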