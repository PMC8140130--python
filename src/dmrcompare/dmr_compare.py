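"""Recurrence-based DMR calling and the two-cancer comparison.

Per-sample 500-bp differential-methylation calls come in from an upstream
caller; this module applies the recurrence rule (a bin must be called in the
same direction in at least ``min_support`` samples), partitions the two
cancers' consensus sets into six shared/unique categories, and quantifies the
shared overlap against the eligible-bin background with an upper-tail
hypergeometric test whose expected count is

    expected shared = (n_A / n_background) * n_B.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Sequence, Set, Tuple

from .genome_model import BinKey
from .stats import hypergeom_log10_sf, underflows_double

logger = logging.getLogger(__name__)

DIRECTIONS = ("hyper", "hypo")


@dataclass(frozen=True)
class SampleDMRCall:
    sample_id: str
    bin: BinKey
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class RecurrentDMRSet:
    """Consensus DMRs of one cancer: (bin, direction, support count)."""

    cancer_id: str
    dmrs: List[Tuple[BinKey, str, int]]
    min_support: int

    def bins(self, direction: str) -> Set[BinKey]:
        return {b for b, d, _ in self.dmrs if d == direction}

    def count(self, direction: str) -> int:
        return sum(1 for _, d, _ in self.dmrs if d == direction)

    @property
    def n_total(self) -> int:
        return len(self.dmrs)


@dataclass
class DMRCategories:
    a_unique_hyper: Set[BinKey]
    a_unique_hypo: Set[BinKey]
    b_unique_hyper: Set[BinKey]
    b_unique_hypo: Set[BinKey]
    shared_hyper: Set[BinKey]
    shared_hypo: Set[BinKey]

    def sizes(self) -> Dict[str, int]:
        return {
            "a_unique_hyper": len(self.a_unique_hyper),
            "a_unique_hypo": len(self.a_unique_hypo),
            "b_unique_hyper": len(self.b_unique_hyper),
            "b_unique_hypo": len(self.b_unique_hypo),
            "shared_hyper": len(self.shared_hyper),
            "shared_hypo": len(self.shared_hypo),
        }


@dataclass
class OverlapTest:
    n_a: int
    n_b: int
    n_background: int
    observed: int
    expected: float
    log10_p: float
    p_underflows_double: bool


def call_recurrent(
    calls: Sequence[SampleDMRCall],
    n_samples: int,
    min_support: int,
    cancer_id: str = "",
) -> RecurrentDMRSet:
    """Keep (bin, direction) pairs supported by >= min_support distinct samples.

    A (sample, bin) pair carrying both directions is a malformed input and
    raises; a bin whose *consensus* meets min_support in both directions
    across different samples is contradictory and is dropped with a warning.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    seen: Dict[Tuple[str, BinKey], str] = {}
    support: Dict[Tuple[BinKey, str], Set[str]] = {}
    for c in calls:
        prev = seen.get((c.sample_id, c.bin))
        if prev is not None and prev != c.direction:
            raise ValueError(
                f"sample {c.sample_id} calls bin {c.bin} both hyper and hypo"
            )
        seen[(c.sample_id, c.bin)] = c.direction
        support.setdefault((c.bin, c.direction), set()).add(c.sample_id)

    passing = {
        (b, d): sorted(s) for (b, d), s in support.items() if len(s) >= min_support
    }
    conflicted = {b for (b, d) in passing} & {
        b for (b, d) in passing if (b, "hyper" if d == "hypo" else "hypo") in passing
    }
    if conflicted:
        logger.warning(
            "%s: dropping %d direction-conflicted bins (both directions met "
            "min_support)", cancer_id or "recurrence", len(conflicted)
        )
    dmrs = sorted(
        (b, d, len(s))
        for (b, d), s in support.items()
        if len(s) >= min_support and b not in conflicted
    )
    return RecurrentDMRSet(cancer_id=cancer_id, dmrs=dmrs, min_support=min_support)


def categorize(a: RecurrentDMRSet, b: RecurrentDMRSet) -> DMRCategories:
    """Six-way partition; sharing requires identical bin AND identical direction."""
    a_hyper, a_hypo = a.bins("hyper"), a.bins("hypo")
    b_hyper, b_hypo = b.bins("hyper"), b.bins("hypo")
    shared_hyper = a_hyper & b_hyper
    shared_hypo = a_hypo & b_hypo
    return DMRCategories(
        a_unique_hyper=a_hyper - shared_hyper,
        a_unique_hypo=a_hypo - shared_hypo,
        b_unique_hyper=b_hyper - shared_hyper,
        b_unique_hypo=b_hypo - shared_hypo,
        shared_hyper=shared_hyper,
        shared_hypo=shared_hypo,
    )


def hyper_hypo_ratio(n_hyper: int, n_hypo: int) -> float:
    """count(hyper)/count(hypo), rounded half-up to 3 decimals.

    Raises on zero hypoDMRs (the ratio is undefined).
    """
    if n_hypo <= 0:
        raise ValueError("hyper:hypo ratio undefined for zero hypoDMRs")
    exact = Decimal(n_hyper) / Decimal(n_hypo)
    return float(exact.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def ratio_of_set(s: RecurrentDMRSet) -> float:
    return hyper_hypo_ratio(s.count("hyper"), s.count("hypo"))


def expected_shared(n_a: int, n_b: int, n_background: int) -> float:
    """Expected shared-DMR count under independence: (n_A/n_background) * n_B."""
    if n_background <= 0:
        raise ValueError("n_background must be positive")
    if n_a > n_background or n_b > n_background:
        raise ValueError("DMR counts exceed background size")
    return (n_a / n_background) * n_b


def shared_overlap_test(
    n_a: int, n_b: int, n_background: int, observed: int
) -> OverlapTest:
    """Upper-tail hypergeometric test of the observed shared-DMR count.

    X ~ Hypergeometric(population n_background, successes n_A, draws n_B);
    reports log10 P(X >= observed) computed in log space so that tails far
    beyond double underflow stay finite.
    """
    if observed < 0 or observed > min(n_a, n_b):
        raise ValueError("observed must satisfy 0 <= observed <= min(n_A, n_B)")
    exp = expected_shared(n_a, n_b, n_background)
    log10_p = hypergeom_log10_sf(observed, n_background, n_a, n_b)
    return OverlapTest(
        n_a=n_a,
        n_b=n_b,
        n_background=n_background,
        observed=observed,
        expected=exp,
        log10_p=log10_p,
        p_underflows_double=underflows_double(log10_p),
    )


def overlap_test_from_sets(
    a_bins: Set[BinKey], b_bins: Set[BinKey], n_background: int
) -> OverlapTest:
    return shared_overlap_test(
        len(a_bins), len(b_bins), n_background, len(a_bins & b_bins)
    )
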