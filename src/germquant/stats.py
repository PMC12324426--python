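"""Resampling inference and phenotype-distribution divergence.

Two tools make up the inferential layer:

* :func:`bootstrap_diff_means` — a pooled-bootstrap test of no difference in
  group means. Both groups are pooled, resampled with replacement at their
  original sizes ``B`` times, and the two-sided p-value is the +1-corrected
  fraction of resampled |mean differences| at least as large as the observed
  one: ``p = (1 + #{|d_b| >= |d_obs|}) / (B + 1)``. The floor is therefore
  ``1/(B+1)``; p-values are never 0.
* :func:`jensen_shannon_divergence` — base-2 JSD between categorical count
  tables, bounded in [0, 1]: 0 iff the proportions are identical, 1 iff the
  supports are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, InsufficientDataError, ParameterError

__all__ = [
    "BootstrapTest",
    "PhenotypeCounts",
    "JSDResult",
    "bootstrap_diff_means",
    "jensen_shannon_divergence",
    "compare_groups",
    "DEFAULT_CATEGORIES",
]

DEFAULT_B = 100_000
DEFAULT_CATEGORIES = ("WT", "partial AP defects", "strong AP defects")


@dataclass(frozen=True)
class BootstrapTest:
    observed_diff: float        # mean(sample) - mean(control)
    p_value: float
    n_resamples: int
    seed: int
    n_sample: int
    n_control: int


@dataclass(frozen=True)
class PhenotypeCounts:
    """Ordered category labels with nonnegative integer counts."""

    counts: Tuple[int, ...]
    categories: Tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self):
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != len(self.categories):
            raise ConsistencyError(
                f"{len(counts)} counts for {len(self.categories)} categories"
            )
        if any(c < 0 for c in counts):
            raise ParameterError("counts: must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def total(self) -> int:
        return sum(self.counts)

    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ParameterError("zero-total phenotype table has no proportions")
        return np.asarray(self.counts, dtype=np.float64) / self.total


@dataclass(frozen=True)
class JSDResult:
    jsd: float
    vs: str = ""


def bootstrap_diff_means(
    sample: Sequence[float],
    control: Sequence[float],
    B: int = DEFAULT_B,
    seed: int = 0,
) -> BootstrapTest:
    """Pooled-bootstrap two-sided test of equal means."""
    sample = np.asarray(sample, dtype=np.float64)
    control = np.asarray(control, dtype=np.float64)
    if sample.size < 2 or control.size < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group, got {sample.size} and {control.size}"
        )
    if B < 100:
        raise ParameterError(f"B: need >= 100 resamples, got {B}")
    observed = float(sample.mean() - control.mean())
    pooled = np.concatenate([sample, control])
    rng = np.random.default_rng(seed)
    n1, n2 = sample.size, control.size
    # draw all resamples at once; memory ~ B*(n1+n2)*8 bytes
    draws = rng.choice(pooled, size=(B, n1 + n2), replace=True)
    d = draws[:, :n1].mean(axis=1) - draws[:, n1:].mean(axis=1)
    count = int(np.sum(np.abs(d) >= abs(observed)))
    p = (1 + count) / (B + 1)
    return BootstrapTest(
        observed_diff=observed,
        p_value=p,
        n_resamples=B,
        seed=seed,
        n_sample=n1,
        n_control=n2,
    )


def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def jensen_shannon_divergence(P: PhenotypeCounts, Q: PhenotypeCounts) -> JSDResult:
    """Base-2 JSD between two phenotype count tables.

    Counts are converted to proportions; ``JSD = KL(p||m)/2 + KL(q||m)/2``
    with ``m = (p+q)/2`` and ``0 * log 0 := 0``.
    """
    if P.categories != Q.categories:
        raise ConsistencyError(
            f"category mismatch: {P.categories} vs {Q.categories}"
        )
    p = P.proportions()
    q = Q.proportions()
    m = (p + q) / 2.0
    jsd = 0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m)
    # clamp tiny float excursions outside [0, 1]
    return JSDResult(jsd=float(min(max(jsd, 0.0), 1.0)))


def _derive_seed(master: int, i: int) -> int:
    return int(np.random.SeedSequence([master, i]).generate_state(1)[0] % (2**31))


def compare_groups(
    table: pd.DataFrame,
    positive_label: str,
    negative_label: Optional[str] = None,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = 0.05,
    group_col: str = "genotype",
    value_col: str = "value",
) -> pd.DataFrame:
    """Bootstrap every non-control group against each control.

    Returns one row per (genotype, comparator) pair with the observed mean
    difference, p-value and significance flag at ``alpha``. Per-row seeds are
    derived deterministically from ``seed``.
    """
    controls = [c for c in (positive_label, negative_label) if c is not None]
    groups = {g: df[value_col].to_numpy() for g, df in table.groupby(group_col)}
    for c in controls:
        if c not in groups:
            raise ConsistencyError(f"control group {c!r} missing from table")
        if len(groups[c]) < 2:
            raise InsufficientDataError(f"control group {c!r} has < 2 samples")
    rows = []
    i = 0
    for g in sorted(k for k in groups if k not in controls):
        for c in controls:
            test = bootstrap_diff_means(groups[g], groups[c], B=B, seed=_derive_seed(seed, i))
            rows.append(
                {
                    "genotype": g,
                    "comparator": c,
                    "n": len(groups[g]),
                    "n_control": len(groups[c]),
                    "observed_diff": test.observed_diff,
                    "p_value": test.p_value,
                    "significant": test.p_value < alpha,
                }
            )
            i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "genotype", "comparator", "n", "n_control",
            "observed_diff", "p_value", "significant",
        ],
    )
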