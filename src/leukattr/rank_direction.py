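"""Gene-set construction from the ranked list, cumulative rank-median
curves, and direction-of-change binomial tests.

The ranked list orders age-associated genes by strength of association
(a meta-analysis Z-score); gene sets are cut from it either by rank
(top-k), by a fraction of the top score (the half-maximum rule that
yields the 20-gene headline set), or by direction of change followed by
rank (the increase-only subset analysis).  The cumulative median curve
tracks how the median combined attribution of the top-k genes decays as
lower-ranked genes are admitted.  Direction-of-change counts are tested
against a null proportion with the exact two-tailed binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .atlas_io import DECREASE, INCREASE, RankedGene, RankedGeneList
from .attribution import CombinedAttribution

__all__ = [
    "GeneSetSpec",
    "CumulativeMedianCurve",
    "DirectionTestResult",
    "select_gene_set",
    "cumulative_median_curve",
    "binomial_direction_test",
    "direction_test_for",
]


@dataclass(frozen=True)
class GeneSetSpec:
    """How to cut a gene set from the ranked list.

    Modes
    -----
    ``top_k``
        First ``k`` genes by rank.
    ``score_threshold_fraction``
        All genes whose score is at least ``threshold_fraction`` of the
        top-ranked gene's score (default fraction 0.5, the half-maximum
        rule).
    ``direction_filtered_top_k``
        Filter to ``direction_filter`` first, then take the first ``k``
        by rank.
    ``all``
        Every entry.
    """

    mode: str = "all"
    k: int | None = None
    threshold_fraction: float = 0.5
    direction_filter: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("top_k", "score_threshold_fraction", "all", "direction_filtered_top_k"):
            raise ValueError(f"unknown gene-set mode {self.mode!r}")
        if self.mode in ("top_k", "direction_filtered_top_k"):
            if self.k is None or self.k < 1:
                raise ValueError(f"mode {self.mode!r} requires a positive k")
        if self.mode == "direction_filtered_top_k":
            if self.direction_filter not in (DECREASE, INCREASE):
                raise ValueError("direction_filter must be decrease or increase")
        if self.mode == "score_threshold_fraction":
            if not 0.0 < self.threshold_fraction <= 1.0:
                raise ValueError("threshold_fraction must lie in (0, 1]")

    @classmethod
    def parse(cls, text: str) -> "GeneSetSpec":
        """Parse a compact spec string: ``top:20``, ``frac:0.5``,
        ``all``, ``top:20:increase``."""
        parts = text.split(":")
        if parts[0] == "all" and len(parts) == 1:
            return cls(mode="all")
        if parts[0] == "top" and len(parts) == 2:
            return cls(mode="top_k", k=int(parts[1]))
        if parts[0] == "top" and len(parts) == 3:
            return cls(mode="direction_filtered_top_k", k=int(parts[1]),
                       direction_filter=parts[2])
        if parts[0] == "frac" and len(parts) == 2:
            return cls(mode="score_threshold_fraction", threshold_fraction=float(parts[1]))
        raise ValueError(f"cannot parse gene-set spec {text!r}")

    @property
    def label(self) -> str:
        if self.mode == "all":
            return "all"
        if self.mode == "top_k":
            return f"top{self.k}"
        if self.mode == "score_threshold_fraction":
            return f"frac{self.threshold_fraction:g}"
        return f"top{self.k}_{self.direction_filter}"


@dataclass
class CumulativeMedianCurve:
    """Median combined attribution (percent) of the top-k genes, as a
    function of k."""

    k_values: np.ndarray
    median_pct: np.ndarray
    subset_label: str
    background_median_pct: float

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.median_pct = np.asarray(self.median_pct, dtype=float)
        if np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k values must be strictly increasing")
        if len(self.k_values) != len(self.median_pct):
            raise ValueError("k and median arrays must align")

    def at(self, k: int) -> float:
        i = np.searchsorted(self.k_values, k)
        if i >= len(self.k_values) or self.k_values[i] != k:
            raise KeyError(f"k={k} not on curve")
        return float(self.median_pct[i])


@dataclass(frozen=True)
class DirectionTestResult:
    """Exact two-tailed binomial test of a decrease count against a
    null proportion."""

    n: int
    k_decrease: int
    proportion_decrease: float
    p_two_tailed: float
    null_proportion: float = 0.5


def select_gene_set(genes: RankedGeneList, spec: GeneSetSpec) -> list[RankedGene]:
    """Cut an ordered gene subset from the ranked list per ``spec``."""
    entries = list(genes)
    if not entries:
        raise ValueError("ranked list is empty")
    if spec.mode == "all":
        return entries
    if spec.mode == "top_k":
        if spec.k > len(entries):
            raise ValueError(
                f"k={spec.k} exceeds the {len(entries)} available entries"
            )
        return entries[: spec.k]
    if spec.mode == "direction_filtered_top_k":
        filtered = [e for e in entries if e.direction == spec.direction_filter]
        if spec.k > len(filtered):
            raise ValueError(
                f"k={spec.k} exceeds the {len(filtered)} entries with "
                f"direction {spec.direction_filter}"
            )
        return filtered[: spec.k]
    # score_threshold_fraction
    top_score = entries[0].score
    if top_score is None:
        raise ValueError("score threshold mode requires scores on the list")
    cutoff = spec.threshold_fraction * top_score
    return [e for e in entries if e.score is not None and e.score >= cutoff]


def cumulative_median_curve(
    mapped_ranks: Sequence[int],
    mapping: dict[int, int],
    combined: CombinedAttribution,
    k_min: int = 5,
    k_max: int | None = None,
    subset_label: str | None = None,
    background_median: float | None = None,
) -> CumulativeMedianCurve:
    """Median combined attribution of the top-k mapped genes for each k.

    ``mapped_ranks`` lists the ranks (ascending) whose genes mapped to
    the atlas; ranks of unmapped genes are simply absent, so k counts
    mapped genes.  ``mapping`` sends each rank to its row in
    ``combined``.
    """
    ranks = sorted(mapped_ranks)
    if not ranks:
        raise ValueError("no mapped genes")
    n = len(ranks)
    if k_max is None:
        k_max = n
    if not (1 <= k_min <= k_max <= n):
        raise ValueError(f"need 1 <= k_min <= k_max <= {n}")
    values = np.array([combined.values[mapping[r]] for r in ranks])
    ks = np.arange(k_min, k_max + 1)
    medians = np.array([np.median(values[:k]) for k in ks])
    return CumulativeMedianCurve(
        k_values=ks,
        median_pct=100.0 * medians,
        subset_label=subset_label or "+".join(combined.subset),
        background_median_pct=100.0 * (background_median if background_median is not None else float("nan")),
    )


def binomial_direction_test(
    k_decrease: int, n: int, null_proportion: float = 0.5
) -> DirectionTestResult:
    """Exact two-tailed binomial test of ``k_decrease`` successes in
    ``n`` trials.

    The two-tailed p-value is the minimum-likelihood sum: the total
    probability of all outcomes no more likely than the observed count.
    At null 0.5 this coincides with doubling the smaller tail, capped
    at 1.
    """
    if not 0 < null_proportion < 1:
        raise ValueError("null_proportion must lie in (0, 1)")
    if n < 1 or not 0 <= k_decrease <= n:
        raise ValueError("need n >= 1 and 0 <= k_decrease <= n")
    res = stats.binomtest(k_decrease, n, null_proportion, alternative="two-sided")
    return DirectionTestResult(
        n=n,
        k_decrease=k_decrease,
        proportion_decrease=k_decrease / n,
        p_two_tailed=float(min(res.pvalue, 1.0)),
        null_proportion=null_proportion,
    )


def direction_test_for(
    genes: Sequence[RankedGene], null_proportion: float = 0.5
) -> DirectionTestResult:
    """Direction test for a gene set: count decreases and test vs null."""
    entries = list(genes)
    k = sum(e.direction == DECREASE for e in entries)
    return binomial_direction_test(k, len(entries), null_proportion)
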