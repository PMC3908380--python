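"""Evaluation against a known-interaction reference and between methods.

The protocol: take each method's ranked interaction list, cut it at
increasing depths k, and count (a) overlap of the top-k with a reference
set of known interactions, (b) pairwise agreement between methods'
top-k lists, and (c) the full intersection structure (Venn regions) of
several methods' top-k sets.  Interactions are compared as unordered
gene-symbol pairs, so reciprocal detections (A purified with B, B purified
with A) count as the same underlying interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

from .datamodel import (
    KnownInteractionSet,
    ScoreTable,
    ValidationError,
    canonical_pair,
    split_group_id,
)


@dataclass
class MethodScores:
    """One method's ranking of an experiment's bait-prey pairs.

    ``entries`` is strictly ordered: descending score, ties broken by the
    (bait, prey) key so the ordering is deterministic.  ``bait`` here is
    the bait protein name (condition stripped), so the same entry can be
    matched against an unordered reference pair.
    """

    name: str
    entries: list[tuple[str, str, float]]  # (bait, prey, score)

    def __post_init__(self) -> None:
        seen = set()
        for bait, prey, _ in self.entries:
            if (bait, prey) in seen:
                raise ValidationError(f"duplicate scored pair ({bait!r}, {prey!r})")
            seen.add((bait, prey))
        ordered = sorted(self.entries, key=lambda e: (-e[2], e[0], e[1]))
        self.entries = ordered

    def __len__(self) -> int:
        return len(self.entries)

    def top_pairs(self, k: int, symbol_map: Optional[Mapping[str, str]] = None) -> list[tuple[str, str]]:
        """Unordered symbol pairs of the first k entries (exactly k rows)."""
        if k > len(self.entries):
            raise ValidationError(
                f"k={k} exceeds the {len(self.entries)} scored pairs of {self.name!r}"
            )
        mapper = symbol_map or {}
        return [
            canonical_pair(mapper.get(b, b), mapper.get(p, p))
            for b, p, _ in self.entries[:k]
        ]


def method_scores_from_table(
    scores: ScoreTable,
    column: str = "ppirank",
    name: Optional[str] = None,
    include_filtered: bool = False,
    include_self: bool = False,
) -> MethodScores:
    """Extract one score column of a ScoreTable as a method ranking.

    Bait-group ids collapse to bait names (condition stripped); when the
    same (bait, prey) pair is scored under several conditions the best
    score is kept, matching per-condition calls rolled up to one
    interaction list.
    """
    df = scores.frame
    if column not in df.columns:
        raise ValidationError(f"no score column {column!r}")
    if not include_filtered:
        df = df[~df["filtered"]]
    if not include_self and "is_bait_self" in df.columns:
        df = df[~df["is_bait_self"].astype(bool)]
    best: dict[tuple[str, str], float] = {}
    for bait_group, prey, value in zip(df["bait"], df["prey"], df[column]):
        bait, _ = split_group_id(bait_group)
        key = (bait, prey)
        if key not in best or value > best[key]:
            best[key] = float(value)
    entries = [(b, p, s) for (b, p), s in best.items()]
    return MethodScores(name=name or column, entries=entries)


def topk_overlap_curve(
    scores: MethodScores,
    known: KnownInteractionSet,
    ks: Sequence[int],
    symbol_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[int, int]]:
    """Count known interactions among the top-k pairs, for each k.

    Returns (k, overlap) points; the curve is non-decreasing in k.
    """
    ks = list(ks)
    if any(k2 < k1 for k1, k2 in zip(ks, ks[1:])):
        raise ValidationError("ks must be sorted ascending")
    curve = []
    for k in ks:
        pairs = set(scores.top_pairs(k, symbol_map))
        curve.append((k, sum(1 for pair in pairs if pair in known)))
    return curve


def pairwise_agreement(
    a: MethodScores,
    b: MethodScores,
    ks: Sequence[int],
    symbol_map: Optional[Mapping[str, str]] = None,
) -> list[tuple[int, int]]:
    """|top-k(a) ∩ top-k(b)| as unordered pairs, for each k. Symmetric."""
    curve = []
    for k in ks:
        common = set(a.top_pairs(k, symbol_map)) & set(b.top_pairs(k, symbol_map))
        curve.append((k, len(common)))
    return curve


def multiway_intersection(
    methods: Sequence[MethodScores],
    k: int,
    symbol_map: Optional[Mapping[str, str]] = None,
) -> dict[frozenset[str], int]:
    """Venn-region counts of the methods' top-k sets.

    Every non-empty subset of method names maps to the number of pairs
    found by exactly that subset; region counts sum to the union size.
    """
    if len(methods) < 2:
        raise ValidationError("multiway intersection needs at least two methods")
    names = [m.name for m in methods]
    if len(set(names)) != len(names):
        raise ValidationError("method names must be distinct")
    tops = {m.name: set(m.top_pairs(k, symbol_map)) for m in methods}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            regions[frozenset(subset)] = 0
    union = set().union(*tops.values())
    for pair in union:
        membership = frozenset(n for n in names if pair in tops[n])
        regions[membership] += 1
    return regions


def cutoff_from_reference(
    scores: MethodScores,
    known: KnownInteractionSet,
    objective: str = "f1",
    min_recall: float = 0.5,
    symbol_map: Optional[Mapping[str, str]] = None,
) -> float:
    """Pick a score cutoff by reference to known interactions.

    Sweeps every achievable threshold over the ranked list and returns the
    score of the last retained entry under the best prefix.  Objectives:

    * ``"f1"`` (default) — maximise F1 of known-pair recovery, where
      recall is over the known pairs present anywhere in the scored list.
    * ``"precision_at_recall"`` — highest threshold whose prefix reaches
      ``min_recall``, i.e. best precision at that recall.
    """
    mapper = symbol_map or {}
    # collapse the ranked entries to unordered pairs, first (best) occurrence wins
    seen: set[tuple[str, str]] = set()
    ranked: list[tuple[tuple[str, str], float]] = []
    for bait, prey, score in scores.entries:
        pair = canonical_pair(mapper.get(bait, bait), mapper.get(prey, prey))
        if pair not in seen:
            seen.add(pair)
            ranked.append((pair, score))
    n_known = sum(1 for pair, _ in ranked if pair in known)
    if n_known == 0:
        raise ValidationError("no known interactions among the scored pairs")

    best_cut, best_value = ranked[0][1], -1.0
    hits = 0
    for depth, (pair, score) in enumerate(ranked, start=1):
        hits += pair in known
        precision = hits / depth
        recall = hits / n_known
        if objective == "f1":
            value = 0.0 if hits == 0 else 2 * precision * recall / (precision + recall)
            if value > best_value:
                best_value, best_cut = value, score
        elif objective == "precision_at_recall":
            if recall >= min_recall:
                return score
        else:
            raise ValidationError(f"unknown objective {objective!r}")
    if objective == "precision_at_recall":
        return ranked[-1][1]
    return best_cut
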