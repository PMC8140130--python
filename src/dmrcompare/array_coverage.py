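"""Methylation-array coverage of DMRs and region-level beta shifts.

A DMR is identifiable on a platform iff >= 1 probe position falls inside it
(half-open membership on the probe's single CpG coordinate).  Region-level
methylation is the unweighted mean beta over probes inside the region set,
per sample; group shifts are tested tumor vs normal with a two-sided test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_model import GenomicInterval, ProbeSet

logger = logging.getLogger(__name__)


@dataclass
class CoverageReport:
    platform: str
    fractions: Dict[str, float]          # DMR group -> fraction identifiable
    identifiable: Dict[str, int]
    totals: Dict[str, int]


def probe_coverage(
    dmr_groups: Mapping[str, Sequence[GenomicInterval]],
    probes: ProbeSet,
) -> CoverageReport:
    """Fraction of DMRs per group containing >= 1 probe of the platform."""
    ident: Dict[str, int] = {}
    totals: Dict[str, int] = {}
    for group, dmrs in dmr_groups.items():
        n_hit = 0
        for d in dmrs:
            pos = probes.positions.get(d.chrom)
            if pos is None or not len(pos):
                continue
            lo = np.searchsorted(pos, d.start, side="left")
            hi = np.searchsorted(pos, d.end, side="left")
            if hi > lo:
                n_hit += 1
        ident[group] = n_hit
        totals[group] = len(dmrs)
    fractions = {
        g: (ident[g] / totals[g]) if totals[g] else 0.0 for g in dmr_groups
    }
    return CoverageReport(
        platform=probes.platform, fractions=fractions, identifiable=ident, totals=totals
    )


def collapse_patients(
    betas: pd.DataFrame, sample_to_patient: Mapping[str, str]
) -> pd.DataFrame:
    """Average samples of the same patient per probe, ignoring missing values."""
    unknown = [s for s in betas.columns if s not in sample_to_patient]
    if unknown:
        raise ValueError(f"samples without patient metadata: {unknown[:10]}")
    patients = pd.Series({s: sample_to_patient[s] for s in betas.columns})
    return betas.T.groupby(patients).mean().T


def region_methylation(
    dmrs: Sequence[GenomicInterval],
    betas: pd.DataFrame,
    probes: ProbeSet,
) -> pd.Series:
    """Per-sample mean beta over probes falling inside the region set.

    Missing betas are ignored probe-wise (pairwise-complete means).  Raises
    when the region set contains no probe at all.
    """
    hit_ids = []
    for d in dmrs:
        pos = probes.positions.get(d.chrom)
        if pos is None or not len(pos):
            continue
        lo = np.searchsorted(pos, d.start, side="left")
        hi = np.searchsorted(pos, d.end, side="left")
        hit_ids.extend(probes.probe_ids[d.chrom][lo:hi])
    hit_ids = [p for p in hit_ids if p in betas.index]
    if not hit_ids:
        raise ValueError("region set contains no probe with beta values")
    return betas.loc[sorted(set(hit_ids))].mean(axis=0, skipna=True)


@dataclass
class ShiftTestResult:
    statistic: float
    p_value: float
    mean_tumor: float
    mean_normal: float
    sign_matches: bool


def group_shift_test(
    region_means_tumor: Sequence[float],
    region_means_normal: Sequence[float],
    expected_sign: int,
    method: str = "welch",
) -> ShiftTestResult:
    """Two-sided tumor-vs-normal test on per-sample region methylation means.

    ``expected_sign`` is +1 for an expected gain of methylation in tumor and
    -1 for a loss; the result flags whether the observed shift matches.
    ``method`` is 'welch' (default), 'student' or 'wilcoxon' (rank-sum).
    """
    t = np.asarray(region_means_tumor, dtype=float)
    n = np.asarray(region_means_normal, dtype=float)
    if len(t) < 2 or len(n) < 2:
        raise ValueError("each group needs >= 2 samples")
    if expected_sign not in (-1, 1):
        raise ValueError("expected_sign must be +1 or -1")
    if method == "wilcoxon":
        res = sps.mannwhitneyu(t, n, alternative="two-sided")
    elif method in ("welch", "student"):
        res = sps.ttest_ind(t, n, equal_var=(method == "student"))
    else:
        raise ValueError(f"unknown method {method!r}")
    stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    diff = float(t.mean() - n.mean())
    return ShiftTestResult(
        statistic=stat,
        p_value=p,
        mean_tumor=float(t.mean()),
        mean_normal=float(n.mean()),
        sign_matches=bool(diff != 0.0 and np.sign(diff) == expected_sign),
    )
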