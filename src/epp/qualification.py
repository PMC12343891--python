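"""Dimension qualification by divergence from fitted references.

A dimension whose marginal looks like a single normal (a uniformly positive
or negative stain) carries no gating information for the current population
and is omitted.  In mass-cytometry mode the non-zero values of a negative
dimension are roughly exponential, so an exponential reference is tested as
well and a dimension must depart from *both* references to qualify.

The divergence estimator discretises the sample onto 256 equal-probability
bins of the moment-matched reference and computes sum p log(p/q) in nats
with a +0.5 pseudo-count; it is O(n log n) and calibrated so that a clean
normal sample at n = 20,000 scores well below the 0.04 working threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .io import EventMatrix

__all__ = ["QualificationConfig", "DimensionQualification",
           "kld_from_reference", "qualify_and_pair"]

_N_BINS = 256


@dataclass(frozen=True)
class QualificationConfig:
    kld_normal_threshold: float = 0.04
    kld_exponential_threshold: float = 0.2
    test_exponential: bool = False     # mass-cytometry mode
    min_events: int = 50

    def __post_init__(self):
        if self.kld_normal_threshold < 0 or self.kld_exponential_threshold < 0:
            raise ConfigurationError("KLD thresholds must be nonnegative")


@dataclass(frozen=True)
class DimensionQualification:
    dim_index: int
    kld_normal: float
    kld_exponential: float | None
    qualified: bool


def kld_from_reference(values, reference: str = "normal",
                       min_events: int = 50) -> float:
    """KL divergence of the empirical distribution from a moment-matched
    reference (``normal`` or ``exponential``); the exponential reference is
    fitted to the non-zero values only.  Returns 0.0 for degenerate input
    (too few events or zero variance), which never qualifies a dimension.
    """
    v = np.asarray(values, dtype=float)
    if reference == "exponential":
        v = v[v > 0]
    n = v.size
    if n < min_events:
        return 0.0
    probs = np.linspace(0.0, 1.0, _N_BINS + 1)[1:-1]
    if reference == "normal":
        mu = v.mean()
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            return 0.0
        edges = stats.norm.ppf(probs, loc=mu, scale=sd)
    elif reference == "exponential":
        mean = v.mean()
        if mean <= 0:
            return 0.0
        edges = stats.expon.ppf(probs, scale=mean)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    counts = np.bincount(np.searchsorted(edges, v), minlength=_N_BINS)
    p = (counts + 0.5) / (n + 0.5 * _N_BINS)
    q = 1.0 / _N_BINS
    return float(np.sum(p * np.log(p / q)))


def qualify_and_pair(events: EventMatrix, config: QualificationConfig
                     ) -> tuple[list[DimensionQualification],
                                list[tuple[int, int]]]:
    """Score every phenotyping dimension and enumerate the dimension pairs
    to examine.

    All unordered pairs of qualified dimensions are returned, sorted by
    index.  If exactly one dimension qualifies it is paired with the
    unqualified dimension of highest normal divergence; if none qualify the
    two highest-divergence dimensions form the single pair — so at least the
    most promising pair is always tried.
    """
    dims = events.phenotyping_indices
    if dims.size < 2:
        raise ConfigurationError("need at least 2 phenotyping dimensions")
    quals = []
    for d in dims:
        col = events.values[:, d]
        kn = kld_from_reference(col, "normal", config.min_events)
        ke = None
        ok = kn >= config.kld_normal_threshold
        if config.test_exponential:
            ke = kld_from_reference(col, "exponential", config.min_events)
            ok = ok and ke >= config.kld_exponential_threshold
        quals.append(DimensionQualification(int(d), kn, ke, bool(ok)))

    qualified = [q.dim_index for q in quals if q.qualified]
    by_kld = sorted(quals, key=lambda q: (-q.kld_normal, q.dim_index))
    if len(qualified) >= 2:
        pairs = sorted(combinations(qualified, 2))
    elif len(qualified) == 1:
        best_other = next(q.dim_index for q in by_kld if not q.qualified)
        pairs = [tuple(sorted((qualified[0], best_other)))]
    else:
        pairs = [tuple(sorted((by_kld[0].dim_index, by_kld[1].dim_index)))]
    return quals, pairs
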