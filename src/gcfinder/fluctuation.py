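"""Expression-ratio fluctuation classification.

For each gene i with wild-type level x_i and mutant level y_i the change
rate is R_i = y_i / x_i. One median M and one quartile deviation
Q = (Q3 − Q1)/2 are computed over the whole ratio distribution, and genes
are classified by strict inequalities:

* fluctuating:  R_i < M − Q  or  M + Q < R_i
* stable:       M − Q < R_i < M + Q

A gene whose ratio lands exactly on a bound satisfies neither strict
inequality and is reported in an explicit ``boundary`` class; a gene with
x_i = 0 has an undefined ratio and is reported as ``undefined`` (it is
also excluded from the M/Q estimation). Statistics are computed on the raw
ratio scale; bounds are additionally reported in log2 because fluctuation
windows are conventionally quoted as log2 expression-ratio intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionRecord

__all__ = [
    "RatioRecord",
    "FluctuationStats",
    "FluctuationClassification",
    "compute_ratios",
    "fluctuation_stats",
    "classify_genes",
]

#: numpy.percentile interpolation methods accepted for the quartiles.
QUARTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint")


@dataclass(frozen=True)
class RatioRecord:
    """Mutant/wild-type expression ratio for one gene.

    ``ratio`` is None when the wild-type level is zero (division by zero);
    ``log2_ratio`` is None whenever the ratio is undefined or zero.
    """

    gene_id: str
    ratio: float | None
    log2_ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass(frozen=True)
class FluctuationStats:
    """Distribution summary of the ratio sample and the derived bounds."""

    n_total: int
    n_defined: int
    median: float
    quartile_dev: float
    lower_bound: float
    upper_bound: float

    def __post_init__(self) -> None:
        if self.quartile_dev < 0:
            raise ValueError("quartile deviation must be non-negative")
        if not self.lower_bound <= self.median <= self.upper_bound:
            raise ValueError("bounds must bracket the median")

    @property
    def lower_bound_log2(self) -> float:
        return math.log2(self.lower_bound) if self.lower_bound > 0 else -math.inf

    @property
    def upper_bound_log2(self) -> float:
        return math.log2(self.upper_bound) if self.upper_bound > 0 else -math.inf


@dataclass(frozen=True)
class FluctuationClassification:
    """Disjoint partition of the input genes by ratio behaviour."""

    stable: frozenset[str]
    fluctuating: frozenset[str]
    boundary: frozenset[str]
    undefined: frozenset[str]

    @property
    def all_genes(self) -> frozenset[str]:
        return self.stable | self.fluctuating | self.boundary | self.undefined


def compute_ratios(
    records: list[ExpressionRecord], pseudocount: float = 0.0
) -> list[RatioRecord]:
    """Compute R_i = y_i / x_i for every record.

    ``pseudocount`` (off by default) is added to both levels before
    division, which makes every ratio defined; with the default 0.0 a gene
    with x_i = 0 gets an undefined ratio.
    """
    if not records:
        raise ValueError("no expression records supplied")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    out = []
    for rec in records:
        x = rec.wt_level + pseudocount
        y = rec.mut_level + pseudocount
        if x > 0:
            ratio = y / x
            log2_ratio = math.log2(ratio) if ratio > 0 else None
        else:
            ratio = None
            log2_ratio = None
        out.append(RatioRecord(rec.gene_id, ratio, log2_ratio))
    return out


def fluctuation_stats(
    ratios: list[RatioRecord], quartile_method: str = "linear"
) -> FluctuationStats:
    """Median and quartile deviation of the defined ratios.

    The quartile deviation is the semi-interquartile range (Q3 − Q1)/2.
    ``quartile_method`` selects the order-statistic interpolation used for
    Q1/Q3 (numpy.percentile semantics); the default linear interpolation is
    the common inclusive convention. At least 4 defined ratios are
    required, otherwise the quartiles are ill-defined.
    """
    if quartile_method not in QUARTILE_METHODS:
        raise ValueError(f"unknown quartile method {quartile_method!r}")
    values = np.array([r.ratio for r in ratios if r.defined], dtype=float)
    if values.size < 4:
        raise ValueError(
            f"need at least 4 defined ratios to estimate quartiles, got {values.size}"
        )
    median = float(np.median(values))
    q1, q3 = (
        float(np.percentile(values, q, method=quartile_method)) for q in (25, 75)
    )
    qd = (q3 - q1) / 2.0
    return FluctuationStats(
        n_total=len(ratios),
        n_defined=int(values.size),
        median=median,
        quartile_dev=qd,
        lower_bound=median - qd,
        upper_bound=median + qd,
    )


def classify_genes(
    ratios: list[RatioRecord], stats: FluctuationStats
) -> FluctuationClassification:
    """Partition genes into stable / fluctuating / boundary / undefined.

    Both inequalities are strict, so a ratio exactly equal to M − Q or
    M + Q is assigned to ``boundary`` rather than silently dropped.
    """
    stable, fluct, boundary, undefined = set(), set(), set(), set()
    lo, hi = stats.lower_bound, stats.upper_bound
    for r in ratios:
        if not r.defined:
            undefined.add(r.gene_id)
        elif lo < r.ratio < hi:
            stable.add(r.gene_id)
        elif r.ratio < lo or hi < r.ratio:
            fluct.add(r.gene_id)
        else:
            boundary.add(r.gene_id)
    return FluctuationClassification(
        stable=frozenset(stable),
        fluctuating=frozenset(fluct),
        boundary=frozenset(boundary),
        undefined=frozenset(undefined),
    )
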