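"""Error-correcting barcode collapse and confidence filtering.

Sequencing and PCR errors surround each true barcode with a cloud of
low-count variants one edit away.  ``collapse_barcodes`` merges every
barcode within Levenshtein distance 1 of a more abundant, already
finalized parent into that parent (single-pass greedy by descending
cross-sample total, ties broken lexicographically), adding the child's
per-sample counts to the parent's so the grand total is conserved
exactly.  ``filter_counts`` then applies the per-class read thresholds
(fish: a barcode needs >= 3 reads in a given fish, else that fish's cell
is zeroed; source library: barcodes with < 2 reads are dropped), and
``remove_template_artifacts`` discards barcodes within Levenshtein
distance 2 of any conserved region of the read template — sequences that
plausibly arose from mis-anchored extraction rather than a real random
insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Literal, Set, Tuple

import edlib
import pandas as pd

from .extract import ReadTemplate


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterPolicy:
    """Read-count and artifact thresholds (defaults follow common practice
    for amplicon barcode data: 3 reads per fish, 2 for the deeper-sampled
    source library, artifact distance 2)."""

    min_reads_per_fish: int = 3
    min_reads_library: int = 2
    template_artifact_max_dist: int = 2

    def __post_init__(self) -> None:
        if min(
            self.min_reads_per_fish,
            self.min_reads_library,
            self.template_artifact_max_dist,
        ) < 0:
            raise ConfigurationError("thresholds must be >= 0")


@dataclass
class CollapseMap:
    """Child -> parent assignments; parents map to themselves."""

    assignments: Dict[str, str]
    parents: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.parents:
            self.parents = {p for p in self.assignments.values()}
        for p in self.parents:
            assert self.assignments.get(p, p) == p, "parent must map to itself"


def levenshtein1_neighborhood(barcode: str) -> Iterator[str]:
    """All strings within Levenshtein distance 1 of ``barcode`` (itself included).

    Enumerates substitutions, deletions and insertions explicitly; for a
    15-mer this is ~124 strings, which makes collapse a hash lookup per
    barcode instead of an all-pairs distance scan.
    """
    yield barcode
    n = len(barcode)
    for i in range(n):
        prefix, old, suffix = barcode[:i], barcode[i], barcode[i + 1 :]
        yield prefix + suffix  # deletion
        for b in "ACGT":
            if b != old:
                yield prefix + b + suffix  # substitution
    for i in range(n + 1):
        for b in "ACGT":
            yield barcode[:i] + b + barcode[i:]  # insertion


def collapse_barcodes(table: pd.DataFrame) -> Tuple[pd.DataFrame, CollapseMap]:
    """Collapse Levenshtein-1 variant clouds into their most abundant member.

    Barcodes are visited in decreasing cross-sample total (ties:
    lexicographic).  A barcode becomes a parent if no finalized parent
    lies within distance 1; otherwise it merges into the most abundant
    such parent.  Children never become parents, so distance-2 chains are
    not transitively merged.  Per-sample counts are preserved through
    merging and the grand total is conserved exactly.
    """
    if table.empty:
        return table.copy(), CollapseMap(assignments={}, parents=set())
    totals = table.sum(axis=1)
    order = totals.sort_values(ascending=False, kind="stable").index
    # stable sort on descending counts, then lexicographic within ties
    order = sorted(order, key=lambda bc: (-totals[bc], bc))

    claimed: Dict[str, str] = {}  # neighborhood string -> most abundant parent
    assignments: Dict[str, str] = {}
    parents: List[str] = []
    for bc in order:
        parent = claimed.get(bc)
        if parent is not None:
            assignments[bc] = parent
        else:
            assignments[bc] = bc
            parents.append(bc)
            for neighbor in levenshtein1_neighborhood(bc):
                # first writer wins: parents are finalized in decreasing
                # abundance, so the earliest claim is the most abundant
                claimed.setdefault(neighbor, bc)

    parent_index = pd.Index([assignments[bc] for bc in table.index], name="barcode")
    collapsed = table.groupby(parent_index, sort=False).sum()
    collapsed = collapsed.loc[[p for p in parents]]
    return collapsed, CollapseMap(assignments=assignments, parents=set(parents))


def filter_counts(
    table: pd.DataFrame,
    policy: FilterPolicy,
    sample_class: Literal["fish", "source_library"],
) -> pd.DataFrame:
    """Zero out low-evidence cells per the sample class; drop empty rows.

    Fish samples: each cell below ``min_reads_per_fish`` is set to zero
    independently per fish.  Source library: barcodes below
    ``min_reads_library`` are removed.
    """
    if sample_class == "fish":
        threshold = policy.min_reads_per_fish
    elif sample_class == "source_library":
        threshold = policy.min_reads_library
    else:
        raise ConfigurationError(f"unknown sample_class {sample_class!r}")
    if table.empty:
        return table.copy()
    filtered = table.where(table >= threshold, 0)
    return filtered.loc[filtered.sum(axis=1) > 0]


def remove_template_artifacts(
    table: pd.DataFrame,
    template: ReadTemplate,
    max_dist: int | None = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop barcodes within ``max_dist`` edits of any conserved template region.

    A barcode is removed iff the minimum Levenshtein distance between it
    and any substring of any conserved region (infix alignment, which
    covers all windows of the barcode length +/- the distance budget) is
    <= ``max_dist``.  Returns the filtered table and a removal log
    (barcode, region index, distance).
    """
    if max_dist is None:
        max_dist = FilterPolicy().template_artifact_max_dist
    log_rows = []
    if not template.conserved_regions:
        import warnings

        warnings.warn("template has no conserved regions; artifact filter is a no-op")
        return table.copy(), pd.DataFrame(columns=["barcode", "region", "distance"])
    keep = []
    for bc in table.index:
        hit = None
        for ri, region in enumerate(template.conserved_regions):
            res = edlib.align(bc, region, mode="HW", task="distance", k=max_dist)
            if res["editDistance"] != -1:
                hit = (bc, ri, res["editDistance"])
                break
        if hit is None:
            keep.append(bc)
        else:
            log_rows.append(hit)
    log = pd.DataFrame(log_rows, columns=["barcode", "region", "distance"])
    return table.loc[keep], log
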