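"""Demultiplexing and anchored barcode extraction.

Pooled amplicon reads carry a 5-nt sample index at a fixed offset near
the read start.  After demultiplexing (Hamming tolerance, ambiguous
assignments rejected) reads are reverse-complemented into template
orientation and the 15-nt random barcode is located between two
conserved anchors: a 12-nt upstream anchor matched with progressively
relaxed stringency (exact substring -> Hamming distance <= 2 ->
Levenshtein distance <= 2, each with position validation against the
expected anchor offset) and a 5-nt downstream anchor that must match
exactly.  Reads whose candidate barcode contains ``N`` or whose
downstream anchor fails are counted as unextractable, never fatal.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import edlib
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")

#: Matching stages, from most to least stringent.
STAGES = ("exact", "hamming", "levenshtein")


class TemplateError(ValueError):
    """Raised for invalid read-template or sample-sheet configuration."""


@dataclass(frozen=True)
class SequencingRead:
    """A single read: identifier, sequence over {A,C,G,T,N}, optional qualities."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


def reverse_complement(read: SequencingRead) -> SequencingRead:
    """Watson-Crick reverse complement; N maps to N; an involution.

    Raises
    ------
    ValueError
        If the sequence contains a non-nucleotide character; the message
        names the offending read.
    """
    bad = set(read.sequence.upper()) - _VALID_BASES
    if bad:
        raise ValueError(
            f"read {read.read_id!r}: non-nucleotide character(s) {sorted(bad)}"
        )
    rc = read.sequence.translate(_COMPLEMENT)[::-1]
    qual = read.quality[::-1] if read.quality is not None else None
    return replace(read, sequence=rc, quality=qual)


def revcomp(sequence: str) -> str:
    """Reverse complement of a plain nucleotide string."""
    return sequence.translate(_COMPLEMENT)[::-1]


# --------------------------------------------------------------------------
# Read template
# --------------------------------------------------------------------------

# Synthetic conserved flanks standing in for the amplicon context around the
# barcode slot (insulator-embedded in the real construct).  Fixed arbitrary
# sequences with no secondary near-match of the upstream anchor.
SYNTHETIC_PREFIX = "ATTGTTTAGCCTTATACCTTTGTAGTTCTG"
SYNTHETIC_SUFFIX = "CTTTAATCCTATCGTCACATAAGGACCGCCTTACACACAT"


@dataclass(frozen=True)
class ReadTemplate:
    """Conserved amplicon structure around the random barcode.

    In template orientation the read is::

        [conserved prefix][upstream anchor][barcode][downstream anchor][conserved suffix]

    ``expected_anchor_offset`` is the start of the upstream anchor in an
    error-free read (after any reverse complementing); anchor matches are
    accepted only within ``position_tolerance`` of it, widened by the
    permitted indel count at the Levenshtein stage.
    """

    upstream_anchor: str = "AGCCCCCAGGGA"
    downstream_anchor: str = "CACGC"
    barcode_length: int = 15
    max_anchor_hamming: int = 2
    max_anchor_levenshtein: int = 2
    expected_anchor_offset: int = len(SYNTHETIC_PREFIX)
    position_tolerance: int = 5
    conserved_regions: Tuple[str, ...] = (
        SYNTHETIC_PREFIX + "AGCCCCCAGGGA",
        "CACGC" + SYNTHETIC_SUFFIX,
    )
    sample_barcode_offset: int = 0
    sample_barcode_length: int = 5
    reverse_complement_reads: bool = True

    def __post_init__(self) -> None:
        if not self.upstream_anchor or not self.downstream_anchor:
            raise TemplateError("anchors must be non-empty")
        if self.barcode_length < 1:
            raise TemplateError("barcode_length must be >= 1")
        for region in self.conserved_regions:
            if "N" in region:
                raise TemplateError("conserved regions must not contain the barcode slot")


DEFAULT_TEMPLATE = ReadTemplate()


@dataclass(frozen=True)
class BarcodeObservation:
    """One successfully extracted barcode.

    ``match_stage`` records the first (most stringent) stage of the
    anchor-search ladder that succeeded; ``anchor_position`` is the start
    of the matched upstream anchor in the oriented read.
    """

    sample_id: str
    barcode: str
    match_stage: str
    anchor_position: int


# --------------------------------------------------------------------------
# Sample sheet and demultiplexing
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Mapping of sample IDs to multiplexing barcodes with a mismatch budget."""

    entries: Mapping[str, str]
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        barcodes = list(self.entries.values())
        if not barcodes:
            raise TemplateError("sample sheet is empty")
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise TemplateError(f"multiplex barcodes differ in length: {sorted(lengths)}")
        if len(set(barcodes)) != len(barcodes):
            dupes = [b for b, k in Counter(barcodes).items() if k > 1]
            raise TemplateError(f"duplicate multiplex barcodes: {dupes}")
        items = sorted(self.entries.items())
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                d = hamming_distance(items[i][1], items[j][1])
                if d <= 2 * self.max_mismatch:
                    warnings.warn(
                        f"multiplex barcodes {items[i][0]}={items[i][1]} and "
                        f"{items[j][0]}={items[j][1]} are only Hamming distance "
                        f"{d} apart (<= 2 x max_mismatch); reads may be "
                        "ambiguous and discarded",
                        stacklevel=2,
                    )

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.entries.values())))


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[SequencingRead],
    sheet: SampleSheet,
    template: ReadTemplate = DEFAULT_TEMPLATE,
) -> Tuple[Dict[str, List[SequencingRead]], List[SequencingRead]]:
    """Assign pooled reads to samples by their multiplex-barcode region.

    A read is assigned to a sample iff exactly one sheet entry lies within
    Hamming distance ``sheet.max_mismatch`` of the read's barcode region;
    reads matching zero or several entries are returned as unassigned.
    Counts are conserved: assigned + unassigned == input.
    """
    start = template.sample_barcode_offset
    blen = sheet.barcode_length
    assigned: Dict[str, List[SequencingRead]] = {s: [] for s in sheet.entries}
    unassigned: List[SequencingRead] = []
    entries = sorted(sheet.entries.items())
    for read in reads:
        region = read.sequence[start : start + blen]
        if len(region) < blen:
            unassigned.append(read)
            continue
        hits = [
            sid
            for sid, bc in entries
            if hamming_distance(region, bc) <= sheet.max_mismatch
        ]
        if len(hits) == 1:
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


# --------------------------------------------------------------------------
# Anchored barcode extraction
# --------------------------------------------------------------------------


def _levenshtein(a: str, b: str) -> int:
    result = edlib.align(a, b, mode="NW", task="distance")
    return result["editDistance"]


def _find_anchor(
    seq: str, template: ReadTemplate
) -> Optional[Tuple[int, int, str]]:
    """Locate the upstream anchor; return (start, end, stage) or None.

    Stage ladder with position validation at every stage.  Ties are broken
    by minimal distance, then leftmost start, then window length closest to
    the anchor length (shorter preferred on equal deviation).
    """
    anchor = template.upstream_anchor
    alen = len(anchor)
    lo = max(0, template.expected_anchor_offset - template.position_tolerance)
    hi = min(
        template.expected_anchor_offset + template.position_tolerance,
        len(seq) - alen,
    )

    # Stage 1: exact substring, leftmost within the position window.
    pos = seq.find(anchor, lo)
    if pos != -1 and pos <= hi:
        return pos, pos + alen, "exact"
    # (a find past `hi` fails position validation; fall through)

    # Stage 2: minimal Hamming distance <= cap, leftmost minimal.
    best_d: Optional[int] = None
    best_s = -1
    for s in range(lo, hi + 1):
        window = seq[s : s + alen]
        d = sum(x != y for x, y in zip(window, anchor))
        if d <= template.max_anchor_hamming and (best_d is None or d < best_d):
            best_d, best_s = d, s
            if d == 0:  # cannot improve
                break
    if best_d is not None:
        return best_s, best_s + alen, "hamming"

    # Stage 3: Levenshtein <= cap over windows of length anchor +/- cap,
    # position window widened by the permitted indel count.
    cap = template.max_anchor_levenshtein
    lo3 = max(0, template.expected_anchor_offset - template.position_tolerance - cap)
    hi3 = min(
        template.expected_anchor_offset + template.position_tolerance + cap,
        len(seq) - (alen - cap),
    )
    lengths = sorted(
        range(alen - cap, alen + cap + 1), key=lambda L: (abs(L - alen), L)
    )
    best: Optional[Tuple[int, int, int]] = None  # (distance, start, end)
    for s in range(lo3, hi3 + 1):
        for wlen in lengths:
            window = seq[s : s + wlen]
            if len(window) < wlen:
                continue
            d = _levenshtein(anchor, window)
            if d <= cap and (best is None or d < best[0]):
                best = (d, s, s + wlen)
    if best is not None:
        return best[1], best[2], "levenshtein"
    return None


def extract_barcode(
    read: SequencingRead,
    template: ReadTemplate = DEFAULT_TEMPLATE,
    sample_id: str = "",
    max_stage: str = "levenshtein",
) -> Optional[BarcodeObservation]:
    """Extract the random barcode from a template-oriented read.

    The candidate barcode is the ``barcode_length`` bases following the
    matched upstream anchor; the bases immediately after it must equal the
    downstream anchor exactly.  Returns ``None`` for unextractable reads
    (no anchor in the position window, short read, ``N`` in the barcode,
    or downstream-anchor failure).  ``max_stage`` truncates the ladder
    (used for stage-monotonicity checks).
    """
    seq = read.sequence
    found = _find_anchor(seq, template)
    if found is None:
        return None
    start, end, stage = found
    if STAGES.index(stage) > STAGES.index(max_stage):
        return None
    bc = seq[end : end + template.barcode_length]
    if len(bc) < template.barcode_length or "N" in bc:
        return None
    down = seq[
        end + template.barcode_length : end
        + template.barcode_length
        + len(template.downstream_anchor)
    ]
    if down != template.downstream_anchor:
        return None
    return BarcodeObservation(
        sample_id=sample_id, barcode=bc, match_stage=stage, anchor_position=start
    )


def tally_observations(observations: Iterable[BarcodeObservation]) -> pd.DataFrame:
    """Integer read counts per (barcode, sample): barcodes x samples table."""
    counts: Counter = Counter()
    samples: Dict[str, None] = {}
    for obs in observations:
        counts[(obs.barcode, obs.sample_id)] += 1
        samples.setdefault(obs.sample_id)
    if not counts:
        return pd.DataFrame(dtype="int64")
    table = pd.Series(counts).unstack(fill_value=0).astype("int64")
    table.index.name = "barcode"
    return table[list(samples)]
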