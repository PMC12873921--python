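"""Abundance normalization, diversity statistics and cell-tally estimators.

Counts are depth-normalized to reads per million (RPM).  Per-sample
diversity is summarized by the count of unique barcodes, the coefficient
of variation (population SD / mean over nonzero abundances), the Shannon
index in bits (-sum p log2 p) and the quartile ratio Q3/Q1 — a uniform
library gives CV ~ 0, Shannon ~ log2 N and Q3/Q1 ~ 1, while clonal
expansion inflates CV and Q3/Q1 and depresses Shannon.  Sequence-level
diversity uses positional nucleotide frequencies and the mean Hamming
distance over randomly sampled barcode pairs (expectation 3L/4 for
uniform-random length-L sequences, 11.25 for L=15).  Two small
estimators translate imaging tallies into biology: the double-positive
fraction of a two-colour experiment bounds the multi-transgene rate at
twice its value (a 50:50 colour mix hides same-colour double integrants
with probability 1/2), and mean per-hindbrain fluorescent-neuron counts
against a total-neuron estimate give the labelled fraction of the brain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

RPM_SCALE = 1_000_000


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (printed-report convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Normalization and diversity
# --------------------------------------------------------------------------


def rpm_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization per sample (column).

    Each count becomes ``1e6 * count / column_total``.  All-zero columns
    cannot be normalized; they are left at zero and flagged via an
    ``attrs['zero_depth_samples']`` annotation rather than divided.
    """
    totals = table.sum(axis=0)
    zero = [c for c in table.columns if totals[c] == 0]
    safe = totals.replace(0, np.nan)
    rpm = table.div(safe, axis=1) * RPM_SCALE
    rpm = rpm.fillna(0.0)
    rpm.attrs["zero_depth_samples"] = zero
    return rpm


def shannon_bits(abundances: Sequence[float]) -> float:
    """Shannon diversity in bits over nonzero relative abundances."""
    v = np.asarray(abundances, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        return float("nan")
    p = v / v.sum()
    return float(-(p * np.log2(p)).sum())


def diversity_metrics(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample diversity summary of an abundance (or count) table.

    Returns a DataFrame indexed by sample with columns
    ``unique_barcodes``, ``cv``, ``shannon_bits`` and ``quartile_ratio``.
    CV is population SD over mean of the nonzero abundances; quartiles
    use linear interpolation.  Samples with no nonzero barcode get NaN
    metrics (undefined, not zero).
    """
    rows = {}
    for sample in abundance.columns:
        v = abundance[sample].to_numpy(dtype=float)
        v = v[v > 0]
        if v.size == 0:
            rows[sample] = dict(
                unique_barcodes=0,
                cv=float("nan"),
                shannon_bits=float("nan"),
                quartile_ratio=float("nan"),
            )
            continue
        q1, q3 = np.percentile(v, [25, 75])
        rows[sample] = dict(
            unique_barcodes=int(v.size),
            cv=float(v.std(ddof=0) / v.mean()),
            shannon_bits=shannon_bits(v),
            quartile_ratio=float(q3 / q1) if q1 > 0 else float("nan"),
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def positional_composition(barcodes: Sequence[str]) -> pd.DataFrame:
    """4 x L positional nucleotide frequency matrix (rows A,C,G,T; columns sum to 1)."""
    if not barcodes:
        raise ValueError("no barcodes given")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        offenders = sorted(b for b in barcodes if len(b) != len(barcodes[0]))[:5]
        raise ValueError(f"mixed barcode lengths {sorted(lengths)}; e.g. {offenders}")
    arr = np.frombuffer("".join(barcodes).encode("ascii"), dtype=np.uint8).reshape(
        len(barcodes), -1
    )
    freqs = {
        base: (arr == ord(base)).mean(axis=0) for base in "ACGT"
    }
    out = pd.DataFrame(freqs).T
    out.index.name = "base"
    out.columns = pd.RangeIndex(out.shape[1], name="position")
    return out


def expected_pairwise_hamming(length: int) -> float:
    """Expected Hamming distance between two uniform-random sequences: 3L/4."""
    return length * 3.0 / 4.0


def _sample_distinct_pairs(
    n: int, n_pairs: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform unordered distinct-index pairs, without replacement when the
    pair space allows, else with replacement."""
    total = n * (n - 1) // 2
    i = rng.integers(0, n, size=n_pairs * 2)
    j = rng.integers(0, n, size=n_pairs * 2)
    if total < n_pairs:
        # pair space too small for distinct sampling: with replacement
        out_i, out_j = [], []
        while len(out_i) < n_pairs:
            a, b = int(rng.integers(0, n)), int(rng.integers(0, n))
            if a != b:
                out_i.append(min(a, b))
                out_j.append(max(a, b))
        return np.array(out_i), np.array(out_j)
    seen = set()
    out_i, out_j = [], []
    k = 0
    while len(out_i) < n_pairs:
        if k >= len(i):
            i = rng.integers(0, n, size=n_pairs * 2)
            j = rng.integers(0, n, size=n_pairs * 2)
            k = 0
        a, b = int(i[k]), int(j[k])
        k += 1
        if a == b:
            continue
        pair = (a, b) if a < b else (b, a)
        if pair in seen:
            continue
        seen.add(pair)
        out_i.append(pair[0])
        out_j.append(pair[1])
    return np.array(out_i), np.array(out_j)


def mean_pairwise_hamming(
    barcodes: Sequence[str], n_pairs: int = 20_000, seed: int = 0
) -> float:
    """Mean Hamming distance over randomly sampled barcode pairs.

    Pairs are drawn uniformly over unordered distinct-index pairs,
    without replacement when the pair space exceeds ``n_pairs`` (falling
    back to with-replacement sampling otherwise); reproducible under
    ``seed``.  Returns NaN for fewer than two barcodes.
    """
    if len(barcodes) < 2:
        return float("nan")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"mixed barcode lengths {sorted(lengths)}")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer("".join(barcodes).encode("ascii"), dtype=np.uint8).reshape(
        len(barcodes), -1
    )
    idx_i, idx_j = _sample_distinct_pairs(len(barcodes), n_pairs, rng)
    return float((arr[idx_i] != arr[idx_j]).sum(axis=1).mean())


def unique_barcode_summary(table: pd.DataFrame) -> Dict[str, object]:
    """Per-sample unique (nonzero) barcode counts with mean/median/SD/range.

    SD is the sample standard deviation (n-1); with a single sample it is
    reported as NaN and the range degenerates to (count, count).
    """
    uniques = (table > 0).sum(axis=0).astype(int)
    values = uniques.to_numpy(dtype=float)
    return {
        "per_sample": uniques.to_dict(),
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        "range": (int(values.min()), int(values.max())),
    }


# --------------------------------------------------------------------------
# Cell-tally estimators
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoColorTally:
    """Cell counts from a two-colour mosaic experiment."""

    green_only: int
    red_only: int
    double_positive: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.green_only, self.red_only, self.double_positive) < 0:
            raise ValueError("tally counts must be >= 0")

    @property
    def total(self) -> int:
        return self.green_only + self.red_only + self.double_positive


@dataclass(frozen=True)
class MutualExclusivity:
    """Mutual-exclusivity summary of a two-colour tally.

    ``pct_multi_upper_bound`` doubles the double-positive percentage: with
    an equal colour mix, a cell carrying two transgenes shows both colours
    with probability 1/2, so observed double positives undercount
    multi-transgene cells by at most a factor of two.
    """

    pct_double: float
    pct_exclusive: float
    pct_multi_upper_bound: float

    def formatted(self) -> Dict[str, float]:
        """Report-precision rounding: percentages to 2 decimals, bound to 1."""
        return {
            "pct_double": round_half_up(self.pct_double, 2),
            "pct_exclusive": round_half_up(self.pct_exclusive, 2),
            "pct_multi_upper_bound": round_half_up(self.pct_multi_upper_bound, 1),
        }


def mutual_exclusivity_stats(tally: TwoColorTally) -> MutualExclusivity:
    """Double-positive / exclusive percentages and the x2 multi-transgene bound."""
    if tally.total == 0:
        return MutualExclusivity(float("nan"), float("nan"), float("nan"))
    pct_double = 100.0 * tally.double_positive / tally.total
    return MutualExclusivity(
        pct_double=pct_double,
        pct_exclusive=100.0 - pct_double,
        pct_multi_upper_bound=2.0 * pct_double,
    )


@dataclass(frozen=True)
class BrainCoverage:
    """Mean labelled-neuron count per brain region and fraction of the region."""

    mean_count: float
    pct_of_total: float

    def formatted(self) -> Dict[str, float]:
        """Report convention: mean truncated toward zero, percent to nearest integer."""
        return {
            "mean_count": float(math.trunc(self.mean_count)),
            "pct_of_total": round_half_up(self.pct_of_total, 0),
        }


def brain_coverage(
    counts: Sequence[int], hindbrain_total_estimate: int = 25_000
) -> BrainCoverage:
    """Mean fluorescent-neuron count and percent of the estimated region total."""
    if not counts:
        raise ValueError("at least one per-fish count is required")
    if hindbrain_total_estimate <= 0:
        raise ValueError("hindbrain_total_estimate must be positive")
    mean_count = float(np.mean(counts))
    return BrainCoverage(
        mean_count=mean_count,
        pct_of_total=100.0 * mean_count / hindbrain_total_estimate,
    )
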