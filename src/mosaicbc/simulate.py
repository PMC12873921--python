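"""Synthetic mosaic-transgenesis data: library, fish, reads, two-colour tallies.

The generative model mirrors delayed integrase-mediated mosaic
transgenesis: a high-complexity plasmid library of uniform-random
barcodes is injected at the 1-cell stage; each integration event during
early cleavage places exactly one randomly drawn library member into one
founder cell (the landing site is consumed, so a founder carries one
barcode); founders then expand clonally, so barcode read abundance is
proportional to clone size.  Amplicon reads reproduce the conserved
template structure (sample index + conserved flanks + anchored barcode)
with independent per-base substitution and indel errors, emitted in the
reverse complement of template orientation so the pipeline's
reorientation step is exercised.  A separate two-colour model simulates
landing-site integration of a 50:50 green/red library with rare
enzyme-independent co-integration, the observable basis of the
mutual-exclusivity estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Tuple

import numpy as np

from .extract import ReadTemplate, DEFAULT_TEMPLATE, SYNTHETIC_PREFIX, SYNTHETIC_SUFFIX, revcomp
from .stats import TwoColorTally

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


# --------------------------------------------------------------------------
# Library
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LibrarySpec:
    """A plasmid library of i.i.d. uniform-random barcodes.

    ``abundance_model`` is ``"uniform"`` (equimolar pool) or
    ``"lognormal"`` with shape ``sigma`` (cloning-bottleneck skew).
    Duplicate barcode draws are permitted; their probability follows the
    birthday problem and is negligible at the complexities used here.
    """

    n_members: int
    barcode_length: int = 15
    abundance_model: Literal["uniform", "lognormal"] = "uniform"
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ConfigurationError(f"n_members must be >= 1, got {self.n_members}")
        if self.barcode_length < 1:
            raise ConfigurationError(
                f"barcode_length must be >= 1, got {self.barcode_length}"
            )
        if self.abundance_model not in ("uniform", "lognormal"):
            raise ConfigurationError(
                f"unknown abundance_model {self.abundance_model!r}"
            )


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> List[str]:
    """``n`` i.i.d. uniform-random DNA strings of the given length."""
    codes = _BASES[rng.integers(0, 4, size=(n, length), dtype=np.uint8)]
    flat = codes.tobytes().decode("ascii")
    return [flat[i * length : (i + 1) * length] for i in range(n)]


def generate_library(spec: LibrarySpec) -> List[Tuple[str, float]]:
    """Draw the library: list of (barcode, relative abundance), summing to 1."""
    rng = np.random.default_rng(spec.seed)
    barcodes = random_barcodes(spec.n_members, spec.barcode_length, rng)
    if spec.abundance_model == "uniform":
        weights = np.full(spec.n_members, 1.0 / spec.n_members)
    else:
        raw = rng.lognormal(mean=0.0, sigma=spec.sigma, size=spec.n_members)
        weights = raw / raw.sum()
    return list(zip(barcodes, weights.tolist()))


# --------------------------------------------------------------------------
# Mosaic fish
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneSizeModel:
    """Distribution of post-integration clone sizes, in cells.

    ``fixed``: every clone has ``size`` cells.  ``geometric``: shifted
    geometric with success probability ``p`` (support >= 1).
    ``lognormal``: ``round(lognormal(mu, sigma))`` clipped to >= 1 — the
    default, capturing the long-tailed abundance produced by variable
    integration timing during cleavage (each missed cell cycle halves the
    final clone; ``sigma=0.8`` ~ a +/-1-cycle spread).
    """

    kind: Literal["fixed", "geometric", "lognormal"] = "lognormal"
    size: int = 1
    p: float = 0.5
    mu: float = math.log(32.0)
    sigma: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "geometric", "lognormal"):
            raise ConfigurationError(f"unknown clone_size_model {self.kind!r}")
        if self.kind == "fixed" and self.size < 1:
            raise ConfigurationError("fixed clone size must be >= 1")
        if self.kind == "geometric" and not 0 < self.p <= 1:
            raise ConfigurationError("geometric p must be in (0, 1]")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.size, dtype=np.int64)
        if self.kind == "geometric":
            return rng.geometric(self.p, size=n).astype(np.int64)
        sizes = np.rint(rng.lognormal(self.mu, self.sigma, size=n)).astype(np.int64)
        return np.maximum(sizes, 1)

    @property
    def mean(self) -> float:
        """Analytic mean of the underlying (pre-rounding) distribution."""
        if self.kind == "fixed":
            return float(self.size)
        if self.kind == "geometric":
            return 1.0 / self.p
        return math.exp(self.mu + self.sigma**2 / 2)

    @property
    def cv(self) -> float:
        """Analytic coefficient of variation of the underlying distribution."""
        if self.kind == "fixed":
            return 0.0
        if self.kind == "geometric":
            return math.sqrt(1.0 - self.p)
        return math.sqrt(math.exp(self.sigma**2) - 1.0)


@dataclass(frozen=True)
class MosaicSimConfig:
    """Per-fish integration model: independent events drawing one library member each."""

    library: LibrarySpec
    n_integrations: int = 1600
    clone_size_model: CloneSizeModel = field(default_factory=CloneSizeModel)
    n_fish: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_integrations < 1:
            raise ConfigurationError("n_integrations must be >= 1")
        if self.n_fish < 0:
            raise ConfigurationError("n_fish must be >= 0")


@dataclass
class FishTruth:
    """Ground truth for one simulated fish.

    ``barcode_to_cells`` maps each integrated barcode to its clone size;
    distinct barcodes can be fewer than ``founder_count`` when two
    integration events drew the same library member (collision), in which
    case clone sizes add.
    """

    fish_id: str
    barcode_to_cells: Dict[str, int]
    founder_count: int

    @property
    def total_cells(self) -> int:
        return sum(self.barcode_to_cells.values())

    @property
    def n_distinct(self) -> int:
        return len(self.barcode_to_cells)


def simulate_mosaic_fish(config: MosaicSimConfig) -> List[FishTruth]:
    """Simulate ``n_fish`` mosaic animals from one library draw."""
    library = generate_library(config.library)
    barcodes = [b for b, _ in library]
    weights = np.array([w for _, w in library])
    rng = np.random.default_rng(config.seed)
    uniform = config.library.abundance_model == "uniform"
    fish: List[FishTruth] = []
    for i in range(config.n_fish):
        if uniform:
            idx = rng.integers(0, len(barcodes), size=config.n_integrations)
        else:
            idx = rng.choice(len(barcodes), size=config.n_integrations, p=weights)
        sizes = config.clone_size_model.sample(config.n_integrations, rng)
        clones: Dict[str, int] = {}
        for j, s in zip(idx.tolist(), sizes.tolist()):
            bc = barcodes[j]
            clones[bc] = clones.get(bc, 0) + s
        fish.append(
            FishTruth(
                fish_id=f"fish{i + 1}",
                barcode_to_cells=clones,
                founder_count=config.n_integrations,
            )
        )
    return fish


# --------------------------------------------------------------------------
# Amplicon reads
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon read generation for one sample.

    Reads are sampled from clones proportionally to clone size
    (multinomial at the given depth).  Errors are independent per base:
    substitutions to a uniformly chosen different base, then deletions,
    then single-base insertions.  When the template demands reverse
    complementing, the emitted read is ``sample_barcode +
    revcomp(template sequence)`` so demultiplexing happens on the raw
    read and extraction on the reoriented one.
    """

    template: ReadTemplate = DEFAULT_TEMPLATE
    sample_barcode: str = ""
    depth: int = 10_000
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ConfigurationError(f"depth must be positive, got {self.depth}")
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {rate}")


def _mutate(seq: str, cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    """Apply per-base substitution, deletion and insertion errors."""
    n = len(seq)
    n_sub = rng.binomial(n, cfg.substitution_rate) if cfg.substitution_rate else 0
    n_del = rng.binomial(n, cfg.deletion_rate) if cfg.deletion_rate else 0
    n_ins = rng.binomial(n + 1, cfg.insertion_rate) if cfg.insertion_rate else 0
    if not (n_sub or n_del or n_ins):
        return seq
    chars = list(seq)
    if n_sub:
        for pos in rng.choice(n, size=n_sub, replace=False):
            old = chars[pos]
            alternatives = [b for b in "ACGT" if b != old]
            chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    if n_del:
        for pos in sorted(
            rng.choice(len(chars), size=min(n_del, len(chars)), replace=False),
            reverse=True,
        ):
            del chars[pos]
    if n_ins:
        for pos in sorted(
            rng.choice(len(chars) + 1, size=n_ins, replace=False), reverse=True
        ):
            chars.insert(pos, "ACGT"[rng.integers(0, 4)])
    return "".join(chars)


def simulate_reads(
    truth: FishTruth, config: ReadSimConfig
) -> List[Tuple[str, str, str]]:
    """FASTQ records (id, sequence, quality) for one fish or library sample.

    Exactly ``depth`` reads; with all error rates zero every read carries
    its source barcode between exact anchors, preceded (on the raw read)
    by the correct sample barcode.
    """
    template = config.template
    rng = np.random.default_rng(config.seed)
    barcodes = list(truth.barcode_to_cells)
    sizes = np.array([truth.barcode_to_cells[b] for b in barcodes], dtype=float)
    counts = rng.multinomial(config.depth, sizes / sizes.sum())
    records: List[Tuple[str, str, str]] = []
    i = 0
    for bc, k in zip(barcodes, counts.tolist()):
        if k == 0:
            continue
        core = (
            SYNTHETIC_PREFIX
            + template.upstream_anchor
            + bc
            + template.downstream_anchor
            + SYNTHETIC_SUFFIX
        )
        oriented = (
            config.sample_barcode + revcomp(core)
            if template.reverse_complement_reads
            else config.sample_barcode + core
        )
        for _ in range(k):
            seq = _mutate(oriented, config, rng)
            records.append((f"{truth.fish_id}:{i}", seq, "I" * len(seq)))
            i += 1
    return records


# --------------------------------------------------------------------------
# Two-colour mutual exclusivity
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoColorSimConfig:
    """Two-member (green/red) library injected into a landing-site line.

    Each cell integrates at the landing site with probability
    ``p_landing_integration`` (at most once: recombination consumes the
    site) and independently acquires at most one spontaneous,
    enzyme-independent integration with probability ``p_spontaneous``.
    Colours are drawn with ``color_mix`` green.  Double positives
    therefore arise only from spontaneous co-integration of the opposite
    colour.
    """

    n_cells: int = 25_000
    p_landing_integration: float = 0.05
    color_mix: float = 0.5
    p_spontaneous: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_landing_integration", "color_mix", "p_spontaneous"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")


@dataclass(frozen=True)
class TwoColorResult:
    """Simulated tally plus the hidden truth the tally is used to estimate."""

    tally: TwoColorTally
    n_multi_transgene: int  # fluorescent cells carrying >= 2 integrations
    n_fluorescent: int
    n_landing_integrated: int


def simulate_two_color(config: TwoColorSimConfig) -> TwoColorResult:
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    landing = rng.random(n) < config.p_landing_integration
    landing_green = rng.random(n) < config.color_mix
    spont = rng.random(n) < config.p_spontaneous
    spont_green = rng.random(n) < config.color_mix

    has_green = (landing & landing_green) | (spont & spont_green)
    has_red = (landing & ~landing_green) | (spont & ~spont_green)
    fluorescent = has_green | has_red
    double = has_green & has_red
    multi = landing & spont

    tally = TwoColorTally(
        green_only=int((has_green & ~has_red).sum()),
        red_only=int((has_red & ~has_green).sum()),
        double_positive=int(double.sum()),
    )
    return TwoColorResult(
        tally=tally,
        n_multi_transgene=int(multi.sum()),
        n_fluorescent=int(fluorescent.sum()),
        n_landing_integrated=int(landing.sum()),
    )
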