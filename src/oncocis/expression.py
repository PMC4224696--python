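"""Mutation-linked differential expression.

Only mutations that fall in a DHS *and* have an assigned gene take part.
For one such mutation, every sample carrying any mutation inside that
DHS is "mutant"; all remaining expression samples — including flagged
normal (non-cancer) samples, which by construction carry no mutation —
are "non-mutant". Each mutant sample's expression is compared with the
non-mutant distribution:

* fold change = mutant value / median of non-mutant values;
* p-value from a two-sided one-sample t-test of the non-mutant values
  against the mutant value as hypothesized mean (with a single mutant
  sample, a two-group test is undefined; this is the per-sample reading
  that yields one p per mutant);
* Bonferroni adjustment by the number of DHS-associated (mutation, gene)
  records in the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, GenomicInterval, Mutation

logger = logging.getLogger("oncocis")

__all__ = ["DeResult", "classify_samples", "fold_change", "de_test", "adjust"]


@dataclass(frozen=True)
class DeResult:
    gene: str
    sample_id: str
    fold_change: Optional[float]
    p_value: Optional[float]
    adj_p_value: Optional[float]
    n_non_mutant: int
    degenerate_variance: bool = False


def classify_samples(dhs_interval: GenomicInterval,
                     all_mutations: Sequence[Mutation],
                     expr: ExpressionMatrix) -> tuple[list[str], list[str]]:
    """Split expression samples into (mutant, non-mutant) for one DHS.

    Mutant = samples with >= 1 mutation whose affected span overlaps the
    DHS; mutant samples absent from the expression matrix are dropped
    with a warning. Everything else (normals included) is non-mutant.
    """
    mutant: set[str] = set()
    for m in all_mutations:
        if m.chrom != dhs_interval.chrom:
            continue
        s1, e1 = m.affected_span
        if s1 <= dhs_interval.end and e1 > dhs_interval.start:
            mutant.add(m.sample_id)
    present = [s for s in sorted(mutant) if s in expr.samples]
    for missing in sorted(mutant.difference(expr.samples)):
        logger.warning("mutant sample %s absent from expression matrix", missing)
    non_mutant = [s for s in expr.samples if s not in mutant]
    return present, non_mutant


def fold_change(mutant_value: float,
                non_mutant_values: Sequence[float]) -> Optional[float]:
    """Mutant expression over the median of non-mutant expression; None
    (flagged undefined) when the median is zero or nothing to compare."""
    if len(non_mutant_values) == 0:
        return None
    med = float(np.median(non_mutant_values))
    if med == 0:
        logger.warning("non-mutant median is zero; fold change undefined")
        return None
    return float(mutant_value) / med


def de_test(mutant_value: float,
            non_mutant_values: Sequence[float]) -> tuple[Optional[float], bool]:
    """Two-sided p for one mutant value vs the non-mutant distribution.

    One-sample t-test: t = (mean(non) - mutant) / (sd(non)/sqrt(n)),
    df = n - 1. Returns (p, degenerate_flag). Degenerate variance gives
    p = 1 when the mutant equals the common non-mutant value, else p = 0
    with the flag set; fewer than 3 non-mutant values give (None, False).
    """
    x = np.asarray(non_mutant_values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        return None, False
    sd = x.std(ddof=1)
    if sd == 0:
        if math.isclose(float(x[0]), float(mutant_value), rel_tol=0, abs_tol=0):
            return 1.0, True
        return 0.0, True
    res = stats.ttest_1samp(x, popmean=float(mutant_value))
    return float(res.pvalue), False


def adjust(p: float, n_tests: int) -> float:
    """Bonferroni: min(1, p * n_tests); ``n_tests`` is the number of
    DHS-associated (mutation, gene) records in the run."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)
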