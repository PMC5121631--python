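"""OTU retention rules and descriptive prevalence/partition summaries.

Two successive column filters reduce a raw OTU table to the putative orchid
mycorrhizal community analysed downstream:

1. *rare-OTU removal* — OTUs represented by only one or two reads in the
   whole dataset (global singletons/doubletons) are discarded;
2. *mycorrhizal subsetting* — only OTUs assigned to a whitelist of known
   orchid-associating mycorrhizal families/clades with best-hit percent
   identity strictly above a threshold (default 90%) are retained.

Both filters delete columns only; retained counts are never altered, so the
two commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Set

import numpy as np

from .data_model import (
    DataValidationError,
    OtuTable,
    Ploidy,
    SampleMetadata,
    TaxonomyRecord,
)

__all__ = [
    "DEFAULT_WHITELIST",
    "FilterReport",
    "VennPartition",
    "remove_rare_otus",
    "flag_mycorrhizal",
    "subset_mycorrhizal",
    "apply_filters",
    "prevalence_by_group",
    "prevalence_summary",
    "venn_by_ploidy",
]

#: Families/clades treated as orchid mycorrhizal by default: the rhizoctonia
#: families plus ectomycorrhizal Thelephoraceae. Sebacinales clades A and B
#: are listed separately because taxonomy tables label them as such.
DEFAULT_WHITELIST: frozenset[str] = frozenset(
    {
        "Tulasnellaceae",
        "Ceratobasidiaceae",
        "Sebacinales",
        "Sebacinales_A",
        "Sebacinales_B",
        "Thelephoraceae",
    }
)


@dataclass
class FilterReport:
    """Bookkeeping for one (or a combined) column filter."""

    n_input_otus: int
    n_removed_rare: int
    n_removed_nonmycorrhizal: int
    n_retained: int
    removed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input_otus != (
            self.n_removed_rare + self.n_removed_nonmycorrhizal + self.n_retained
        ):
            raise DataValidationError("filter report counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_input_otus": self.n_input_otus,
            "n_removed_rare": self.n_removed_rare,
            "n_removed_nonmycorrhizal": self.n_removed_nonmycorrhizal,
            "n_retained": self.n_retained,
            "removed_ids": list(self.removed_ids),
        }


@dataclass
class VennPartition:
    """OTU counts per non-empty subset of the ploidy classes {2x, 3x, 4x}."""

    subset_counts: dict[frozenset[str], int]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        for p, total in self.totals.items():
            s = sum(c for sub, c in self.subset_counts.items() if p in sub)
            if s != total:
                raise DataValidationError(
                    f"venn totals inconsistent for {p}: {total} != {s}"
                )

    def to_dict(self) -> dict:
        return {
            "subsets": {
                "+".join(sorted(sub)): c for sub, c in sorted(
                    self.subset_counts.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "totals": dict(sorted(self.totals.items())),
        }


def remove_rare_otus(
    table: OtuTable, min_total_count: int = 3
) -> tuple[OtuTable, FilterReport]:
    """Drop OTUs whose whole-dataset read total is below ``min_total_count``.

    With the default threshold of 3 this removes exactly the global
    singletons and doubletons.
    """
    if min_total_count < 1:
        raise ValueError("min_total_count must be >= 1")
    totals = table.otu_totals()
    keep = [o for o, t in zip(table.otu_ids, totals) if t >= min_total_count]
    removed = [o for o, t in zip(table.otu_ids, totals) if t < min_total_count]
    report = FilterReport(
        n_input_otus=table.n_otus,
        n_removed_rare=len(removed),
        n_removed_nonmycorrhizal=0,
        n_retained=len(keep),
        removed_ids=removed,
    )
    return table.select_otus(keep), report


def flag_mycorrhizal(
    taxonomy: Iterable[TaxonomyRecord],
    whitelist: Set[str] = DEFAULT_WHITELIST,
    min_identity: float = 90.0,
) -> list[TaxonomyRecord]:
    """Set ``putative_mycorrhizal`` on each record.

    An OTU counts as putatively mycorrhizal iff its family/clade is in the
    whitelist AND its percent identity is strictly greater than
    ``min_identity`` (an identity of exactly 90.0 fails the default rule).
    """
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    out = []
    for r in taxonomy:
        flag = (r.family_or_clade in whitelist) and (r.percent_identity > min_identity)
        out.append(
            TaxonomyRecord(
                otu_id=r.otu_id,
                family_or_clade=r.family_or_clade,
                percent_identity=r.percent_identity,
                putative_mycorrhizal=flag,
            )
        )
    return out


def subset_mycorrhizal(
    table: OtuTable, taxonomy: Sequence[TaxonomyRecord]
) -> tuple[OtuTable, FilterReport]:
    """Retain exactly the OTUs flagged putatively mycorrhizal.

    Every OTU in the table must carry a taxonomy record (flag already set,
    e.g. by :func:`flag_mycorrhizal`).
    """
    by_id = {r.otu_id: r for r in taxonomy}
    missing = [o for o in table.otu_ids if o not in by_id]
    if missing:
        raise DataValidationError(f"no taxonomy record for OTUs {missing[:5]}")
    keep = [o for o in table.otu_ids if by_id[o].putative_mycorrhizal]
    removed = [o for o in table.otu_ids if not by_id[o].putative_mycorrhizal]
    report = FilterReport(
        n_input_otus=table.n_otus,
        n_removed_rare=0,
        n_removed_nonmycorrhizal=len(removed),
        n_retained=len(keep),
        removed_ids=removed,
    )
    return table.select_otus(keep), report


def apply_filters(
    table: OtuTable,
    taxonomy: Sequence[TaxonomyRecord],
    min_total_count: int = 3,
    whitelist: Set[str] = DEFAULT_WHITELIST,
    min_identity: float = 90.0,
) -> tuple[OtuTable, FilterReport, list[TaxonomyRecord]]:
    """Rare-OTU removal followed by mycorrhizal subsetting, one report."""
    flagged = flag_mycorrhizal(taxonomy, whitelist=whitelist, min_identity=min_identity)
    t1, rep1 = remove_rare_otus(table, min_total_count=min_total_count)
    t2, rep2 = subset_mycorrhizal(t1, flagged)
    report = FilterReport(
        n_input_otus=table.n_otus,
        n_removed_rare=rep1.n_removed_rare,
        n_removed_nonmycorrhizal=rep2.n_removed_nonmycorrhizal,
        n_retained=t2.n_otus,
        removed_ids=rep1.removed_ids + rep2.removed_ids,
    )
    return t2, report, flagged


def prevalence_by_group(
    table: OtuTable,
    meta: Sequence[SampleMetadata],
    group_by: str = "species",
) -> dict[str, set[str]]:
    """Per-group sets of OTUs present (count >= 1 in any sample of the group).

    ``group_by`` is ``"species"`` or ``"population"``. Groups with no sample
    in the table are silently absent from the result.
    """
    if group_by not in ("species", "population"):
        raise ValueError("group_by must be 'species' or 'population'")
    attr = "species" if group_by == "species" else "population_id"
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    groups: dict[str, list[int]] = {}
    for m in meta:
        if m.sample_id in pos:
            groups.setdefault(getattr(m, attr), []).append(pos[m.sample_id])
    otu_arr = np.asarray(table.otu_ids, dtype=object)
    out: dict[str, set[str]] = {}
    for g, idx in groups.items():
        present = table.counts[idx, :].sum(axis=0) >= 1
        out[g] = set(otu_arr[present])
    return out


def prevalence_summary(prevalence: Mapping[str, Set[str]]) -> dict:
    """Min/max/mean number of OTUs per group, with the extreme groups named."""
    sizes = {g: len(s) for g, s in prevalence.items()}
    if not sizes:
        return {"n_groups": 0, "min": 0, "max": 0, "mean": 0.0}
    gmin = min(sizes, key=lambda g: (sizes[g], g))
    gmax = max(sizes, key=lambda g: (sizes[g], g))
    return {
        "n_groups": len(sizes),
        "min": sizes[gmin],
        "min_group": gmin,
        "max": sizes[gmax],
        "max_group": gmax,
        "mean": float(np.mean(list(sizes.values()))),
    }


def venn_by_ploidy(
    prevalence: Mapping[str, Set[str]],
    meta: Sequence[SampleMetadata],
) -> VennPartition:
    """Partition OTUs by the exact set of ploidy classes they occur in.

    ``prevalence`` maps species → OTU set (species-level presence); each
    species' ploidy is looked up in the metadata.
    """
    sp_ploidy: dict[str, str] = {}
    for m in meta:
        prev = sp_ploidy.setdefault(m.species, m.ploidy.value)
        if prev != m.ploidy.value:
            raise DataValidationError(
                f"species {m.species!r} mapped to both ploidy {prev} and {m.ploidy.value}"
            )
    missing = [sp for sp in prevalence if sp not in sp_ploidy]
    if missing:
        raise DataValidationError(f"no ploidy for species {missing[:5]}")
    otu_ploidies: dict[str, set[str]] = {}
    for sp, otus in prevalence.items():
        for o in otus:
            otu_ploidies.setdefault(o, set()).add(sp_ploidy[sp])
    subset_counts: dict[frozenset[str], int] = {}
    for o, ps in otu_ploidies.items():
        key = frozenset(ps)
        subset_counts[key] = subset_counts.get(key, 0) + 1
    totals = {p.value: 0 for p in Ploidy}
    for sub, c in subset_counts.items():
        for p in sub:
            totals[p] += c
    return VennPartition(subset_counts=subset_counts, totals=totals)
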