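"""Bootstrap test for interval-overlap enrichment.

Given a universe of mutations, an observed subset size and a membership
predicate (e.g. "falls in any DHS annotated by another tool"), each
replicate draws ``subset_size`` mutations without replacement and counts
how many satisfy the predicate. The replicate counts follow a
hypergeometric null; the observed overlap is compared with them by a
two-sided one-sample t-test, with an empirical rank p-value alongside
for robustness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

__all__ = ["BootstrapResult", "bootstrap_overlap"]


@dataclass(frozen=True)
class BootstrapResult:
    observed_overlap: int
    replicate_overlaps: np.ndarray
    mean: float
    sd: float
    p_value: Optional[float]
    empirical_p: float

    @property
    def n_reps(self) -> int:
        return len(self.replicate_overlaps)


def bootstrap_overlap(universe: Sequence,
                      subset_size: int,
                      annotation: Callable[[object], bool],
                      n_reps: int = 1000,
                      seed: int = 0,
                      observed_overlap: Optional[int] = None) -> BootstrapResult:
    """Null distribution of overlap counts under random subsetting.

    ``observed_overlap`` defaults to the predicate count over the first
    ``subset_size`` members of the universe only when the caller does not
    supply the real observed count. Identical seed and inputs give a
    bit-identical replicate vector; sd is the sample sd (ddof=1).
    """
    n = len(universe)
    if subset_size > n:
        raise ValueError(f"subset_size {subset_size} exceeds universe size {n}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    member = np.fromiter((bool(annotation(m)) for m in universe),
                         dtype=bool, count=n)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps, dtype=np.int64)
    for i in range(n_reps):
        idx = rng.choice(n, size=subset_size, replace=False)
        reps[i] = int(member[idx].sum())
    if observed_overlap is None:
        observed_overlap = int(member[:subset_size].sum())
    mean = float(reps.mean())
    sd = float(reps.std(ddof=1)) if n_reps > 1 else 0.0
    if sd == 0:
        p = 1.0 if mean == observed_overlap else 0.0
    else:
        p = float(stats.ttest_1samp(reps, popmean=observed_overlap).pvalue)
    # two-sided empirical rank p with add-one correction
    more_extreme = int(np.sum(np.abs(reps - mean) >= abs(observed_overlap - mean)))
    empirical_p = (more_extreme + 1) / (n_reps + 1)
    return BootstrapResult(int(observed_overlap), reps, mean, sd, p, empirical_p)
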