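"""Evaluation: recall@k, confidence-bin tables, length-stratified impact.

Candidate generation is evaluated by recall@k — the fraction of mentions
whose gold concept appears among the top-k retrieved candidates.  Because
prediction always emits exactly one code per mention (no NIL), recall@1 is
identical to precision and accuracy.  Two decompositions localize where a
preprocessing step (e.g. mention simplification) helps or hurts:

* binning mentions by the baseline candidate generator's top confidence
  score, reporting per-bin counts and recalls before/after;
* stratifying by mention token length, separating gold concepts *gained*
  (entering the top-k only after the step) from *lost* (leaving it), and —
  among mentions retrieved on both sides — strict rank improvements and
  degradations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .retrieve import CandidateList

__all__ = [
    "BinRow",
    "BinReport",
    "LengthImpactRow",
    "LengthImpactReport",
    "DeltaReport",
    "DEFAULT_BIN_EDGES",
    "recall_at_k",
    "bin_by_confidence",
    "impact_by_length",
    "compare",
]

_ONE_TOL = 1e-9

#: Half-open bin edges (lo, hi] above the catch-all [0, 0.5] bin; exact 1.0
#: forms its own singleton bin.
DEFAULT_BIN_EDGES: tuple[tuple[float, float], ...] = (
    (0.5, 0.6),
    (0.6, 0.7),
    (0.7, 0.8),
    (0.8, 0.9),
    (0.9, 1.0),
)


def _hit(clist: CandidateList, gold: str | None, k: int) -> bool:
    if gold is None:
        return False
    return gold in clist.codes[: min(k, len(clist))]


def recall_at_k(
    results: Sequence[CandidateList], golds: Sequence[str | None], k: int
) -> float:
    """Fraction of mentions whose gold code is among the top-k candidates."""
    if len(results) == 0:
        raise ValueError("cannot evaluate an empty result set")
    if len(results) != len(golds):
        raise ValueError("results and golds are misaligned")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return float(np.mean([_hit(c, g, k) for c, g in zip(results, golds)]))


@dataclass(frozen=True)
class BinRow:
    label: str
    n_mentions: int
    recall_at_1: float
    recall_at_64: float


@dataclass(frozen=True)
class BinReport:
    rows: tuple[BinRow, ...]

    @property
    def total(self) -> int:
        return sum(r.n_mentions for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


def _bin_label(score: float, edges: Sequence[tuple[float, float]]) -> str:
    if score >= 1.0 - _ONE_TOL:
        return "1.0"
    lowest = edges[0][0]
    if score <= lowest:
        return f"[0.0,{lowest}]"
    for lo, hi in edges:
        if lo < score <= hi:
            return f"({lo},{hi}]"
    raise AssertionError(f"score {score} fell through the bin partition")


def bin_by_confidence(
    results: Sequence[CandidateList],
    golds: Sequence[str | None],
    confidences: Sequence[float],
    edges: Sequence[tuple[float, float]] = DEFAULT_BIN_EDGES,
    ks: tuple[int, int] = (1, 64),
) -> BinReport:
    """Per-confidence-bin mention counts and recalls.

    ``confidences`` is the binning key — by convention the *baseline*
    candidate generator's top score, so before/after tables stay aligned.
    Bins are disjoint and exhaustive over [0, 1]: a catch-all ``[0, lo]``
    bin below the configured edges, half-open ``(lo, hi]`` bins, and a
    singleton bin for exact 1.0 (score >= 1 - 1e-9).
    """
    if not (len(results) == len(golds) == len(confidences)):
        raise ValueError("results, golds and confidences are misaligned")
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if hi1 != lo2:
            raise ValueError(f"bins ({lo1},{hi1}] and ({lo2},{hi2}] do not abut")
    order = [f"[0.0,{edges[0][0]}]"] + [f"({lo},{hi}]" for lo, hi in edges] + ["1.0"]
    buckets: dict[str, list[int]] = {label: [] for label in order}
    for i, conf in enumerate(confidences):
        buckets[_bin_label(float(conf), edges)].append(i)

    k1, k64 = ks
    rows = []
    for label in order:
        idx = buckets[label]
        if idx:
            sub_results = [results[i] for i in idx]
            sub_golds = [golds[i] for i in idx]
            r1 = recall_at_k(sub_results, sub_golds, k1)
            r64 = recall_at_k(sub_results, sub_golds, k64)
        else:
            r1 = r64 = 0.0
        rows.append(BinRow(label, len(idx), r1, r64))
    return BinReport(tuple(rows))


@dataclass(frozen=True)
class LengthImpactRow:
    length: int  # token length of the original mention text
    n_mentions: int
    gained: float  # fraction whose gold entered the top-k after the step
    lost: float  # fraction whose gold left the top-k
    rank_up: float  # among both-retrieved: strictly better gold rank
    rank_down: float  # among both-retrieved: strictly worse gold rank


@dataclass(frozen=True)
class LengthImpactReport:
    rows: tuple[LengthImpactRow, ...]
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def net_delta(self) -> float:
        """Aggregate Δrecall@k implied by the per-stratum gains and losses."""
        total = sum(r.n_mentions for r in self.rows)
        return sum((r.gained - r.lost) * r.n_mentions for r in self.rows) / total


def impact_by_length(
    before: Sequence[CandidateList],
    after: Sequence[CandidateList],
    golds: Sequence[str | None],
    k: int = 64,
    lengths: Sequence[int] | None = None,
    pool_from: int | None = None,
) -> LengthImpactReport:
    """Decompose a before/after comparison by mention token length.

    ``before`` and ``after`` must be aligned one-to-one by mention; the
    stratum key is the whitespace-token count of the *original* mention text
    (taken from ``before`` unless ``lengths`` is given).  ``pool_from`` pools
    all lengths >= its value into one stratum.  Rank comparisons use strict
    inequality: equal gold ranks count as neither up nor down.
    """
    if not (len(before) == len(after) == len(golds)):
        raise ValueError("before, after and golds are misaligned")
    if lengths is None:
        lengths = [len(b.mention_text.split()) for b in before]
    if pool_from is not None:
        lengths = [min(l, pool_from) for l in lengths]

    strata: dict[int, list[int]] = {}
    for i, length in enumerate(lengths):
        strata.setdefault(length, []).append(i)

    rows = []
    for length in sorted(strata):
        idx = strata[length]
        gained = lost = rank_up = rank_down = 0
        both = 0
        for i in idx:
            hit_before = _hit(before[i], golds[i], k)
            hit_after = _hit(after[i], golds[i], k)
            if hit_after and not hit_before:
                gained += 1
            elif hit_before and not hit_after:
                lost += 1
            elif hit_before and hit_after:
                both += 1
                rank_before = before[i].rank_of(golds[i])
                rank_after = after[i].rank_of(golds[i])
                if rank_after < rank_before:
                    rank_up += 1
                elif rank_after > rank_before:
                    rank_down += 1
        n = len(idx)
        rows.append(
            LengthImpactRow(
                length=length,
                n_mentions=n,
                gained=gained / n,
                lost=lost / n,
                rank_up=rank_up / both if both else 0.0,
                rank_down=rank_down / both if both else 0.0,
            )
        )
    return LengthImpactReport(tuple(rows), k=k)


@dataclass(frozen=True)
class DeltaReport:
    """Before/after recall comparison with exact deltas."""

    n_mentions: int
    recall_before: dict[int, float]
    recall_after: dict[int, float]

    def delta(self, k: int) -> float:
        return self.recall_after[k] - self.recall_before[k]


def compare(
    before: Sequence[CandidateList],
    after: Sequence[CandidateList],
    golds: Sequence[str | None],
    ks: Sequence[int] = (1, 64),
) -> DeltaReport:
    """Recall@k before and after a pipeline step, aligned by mention."""
    if not (len(before) == len(after) == len(golds)):
        raise ValueError("before, after and golds are misaligned")
    return DeltaReport(
        n_mentions=len(golds),
        recall_before={k: recall_at_k(before, golds, k) for k in ks},
        recall_after={k: recall_at_k(after, golds, k) for k in ks},
    )
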