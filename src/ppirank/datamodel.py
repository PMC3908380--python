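"""Core data model for TAP/MS spectral-count experiments.

A purification experiment is a set of runs: *test* runs belong to a bait
group (one bait protein purified under one condition, with biological
replicates) and *control* runs come from a cell line expressing no tagged
bait.  The only measurement is the spectral count (SC) of each prey protein
in each run; an absent (run, prey) entry means SC = 0 — spectral counting
has no notion of missing data distinct from non-detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import pandas as pd

#: Reserved bait-group label for negative-control runs.
CONTROL_GROUP = "__control__"

#: Separator joining bait name and condition into a bait-group id.
GROUP_SEP = "|"


class PPIRankError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PPIRankError):
    """A file does not conform to its declared format."""


class ValidationError(PPIRankError):
    """Data violates an invariant of the data model."""


def make_group_id(bait: str, condition: str = "") -> str:
    """Bait-group id for one bait purified under one condition.

    Each (bait, condition) combination is a distinct purification: time
    points are scored independently, so the same bait at 0 and 30 min are
    two bait groups.
    """
    if not condition:
        return bait
    return f"{bait}{GROUP_SEP}{condition}"


def split_group_id(group_id: str) -> tuple[str, str]:
    """Inverse of :func:`make_group_id`; returns (bait, condition)."""
    if GROUP_SEP in group_id:
        bait, _, condition = group_id.partition(GROUP_SEP)
        return bait, condition
    return group_id, ""


@dataclass(frozen=True)
class Run:
    """One purification run (a single MS sample).

    ``bait_group_id`` is :data:`CONTROL_GROUP` exactly when ``is_control``
    is true; ``bait`` and ``condition`` are then empty.
    """

    run_id: str
    bait_group_id: str
    is_control: bool = False
    bait: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.is_control != (self.bait_group_id == CONTROL_GROUP):
            raise ValidationError(
                f"run {self.run_id!r}: is_control={self.is_control} inconsistent "
                f"with bait_group_id={self.bait_group_id!r}"
            )


class PurificationTable:
    """A full TAP/MS experiment: runs, spectral counts, prey lengths.

    Parameters
    ----------
    runs
        All runs, test and control, in acquisition order.  Replicate order
        within a bait group is the order of appearance here.
    counts
        Mapping ``(run_id, prey_id) -> SC``.  Zero entries are dropped;
        absent keys mean SC = 0.
    prey_lengths
        Mapping ``prey_id -> length`` in residues (positive).  Must cover
        every prey with a count; may declare additional never-detected preys.
    """

    def __init__(
        self,
        runs: Iterable[Run],
        counts: Mapping[tuple[str, str], int],
        prey_lengths: Mapping[str, int],
    ) -> None:
        self.runs: list[Run] = list(runs)
        seen: set[str] = set()
        for run in self.runs:
            if run.run_id in seen:
                raise ValidationError(f"duplicate run_id {run.run_id!r}")
            seen.add(run.run_id)

        self.prey_lengths: dict[str, int] = dict(prey_lengths)
        for prey, length in self.prey_lengths.items():
            if int(length) <= 0:
                raise ValidationError(f"prey {prey!r} has non-positive length {length}")
            self.prey_lengths[prey] = int(length)

        # nested per-run counts; zero entries normalised away
        self._run_counts: dict[str, dict[str, int]] = {r.run_id: {} for r in self.runs}
        for (run_id, prey), sc in counts.items():
            if run_id not in self._run_counts:
                raise ValidationError(f"count references undeclared run {run_id!r}")
            if prey not in self.prey_lengths:
                raise ValidationError(f"count references prey {prey!r} with unknown length")
            sc = int(sc)
            if sc < 0:
                raise ValidationError(
                    f"negative spectral count {sc} for ({run_id!r}, {prey!r})"
                )
            if sc > 0:
                self._run_counts[run_id][prey] = sc

        # ordered bait groups (test runs only)
        self._group_runs: dict[str, list[str]] = {}
        self._control_runs: list[str] = []
        for run in self.runs:
            if run.is_control:
                self._control_runs.append(run.run_id)
            else:
                self._group_runs.setdefault(run.bait_group_id, []).append(run.run_id)
        if not self._group_runs:
            raise ValidationError("experiment declares no bait groups (K = 0)")

        self._group_meta: dict[str, Run] = {}
        for run in self.runs:
            if not run.is_control and run.bait_group_id not in self._group_meta:
                self._group_meta[run.bait_group_id] = run

        # prey -> set of bait groups with >=1 detection
        self._detected_groups: dict[str, set[str]] = {}
        for run in self.runs:
            if run.is_control:
                continue
            for prey in self._run_counts[run.run_id]:
                self._detected_groups.setdefault(prey, set()).add(run.bait_group_id)

    # -- structure ---------------------------------------------------------

    @property
    def bait_groups(self) -> dict[str, list[str]]:
        """Ordered mapping bait_group_id -> replicate run ids."""
        return self._group_runs

    @property
    def control_runs(self) -> list[str]:
        return self._control_runs

    @property
    def n_bait_groups(self) -> int:
        """K, the total number of purifications (bait groups)."""
        return len(self._group_runs)

    @property
    def preys(self) -> list[str]:
        return sorted(self.prey_lengths)

    def bait_of(self, bait_group_id: str) -> str:
        return self._group_meta[bait_group_id].bait

    def condition_of(self, bait_group_id: str) -> str:
        return self._group_meta[bait_group_id].condition

    def replicate_count(self, bait_group_id: str) -> int:
        """T, the number of biological replicates of a bait group."""
        return len(self._require_group(bait_group_id))

    def _require_group(self, bait_group_id: str) -> list[str]:
        try:
            return self._group_runs[bait_group_id]
        except KeyError:
            raise ValidationError(f"unknown bait group {bait_group_id!r}") from None

    # -- counts ------------------------------------------------------------

    def sc(self, run_id: str, prey_id: str) -> int:
        return self._run_counts[run_id].get(prey_id, 0)

    def run_counts(self, run_id: str) -> dict[str, int]:
        """Nonzero spectral counts of one run (prey -> SC)."""
        return self._run_counts[run_id]

    def group_scs(self, bait_group_id: str, prey_id: str) -> list[int]:
        """Per-replicate SCs of a prey in a bait group, zero-filled."""
        return [self.sc(r, prey_id) for r in self._require_group(bait_group_id)]

    def control_scs(self, prey_id: str) -> list[int]:
        """SCs of a prey across all control runs, zero-filled."""
        return [self.sc(r, prey_id) for r in self._control_runs]

    def group_mean_sc(self, bait_group_id: str, prey_id: str) -> float:
        scs = self.group_scs(bait_group_id, prey_id)
        return sum(scs) / len(scs)

    def detected_groups(self, prey_id: str) -> set[str]:
        """Bait groups in which the prey was detected at least once (Σf)."""
        return self._detected_groups.get(prey_id, set())

    def detected_preys(self, bait_group_id: str) -> list[str]:
        """Preys detected in >=1 replicate of the group, sorted."""
        found: set[str] = set()
        for run_id in self._require_group(bait_group_id):
            found.update(self._run_counts[run_id])
        return sorted(found)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PurificationTable):
            return NotImplemented
        return (
            self.runs == other.runs
            and self._run_counts == other._run_counts
            and self.prey_lengths == other.prey_lengths
        )

    def __repr__(self) -> str:
        return (
            f"<PurificationTable: {self.n_bait_groups} bait groups, "
            f"{len(self._control_runs)} controls, {len(self.prey_lengths)} preys>"
        )


@dataclass
class PairEvidence:
    """Aggregate evidence for one (bait group, prey) pair.

    ``sc_replicates`` is aligned to the bait group's replicate order and
    zero-filled; ``sc_controls`` likewise over all control runs.
    """

    bait_group_id: str
    prey_id: str
    sc_replicates: tuple[int, ...]
    sc_controls: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sc_replicates) or any(s < 0 for s in self.sc_controls):
            raise ValidationError("spectral counts must be non-negative")

    @property
    def detect_count(self) -> int:
        """N, the number of replicates in which the interaction is detected."""
        return sum(1 for s in self.sc_replicates if s > 0)

    @property
    def detected_any(self) -> bool:
        return self.detect_count > 0

    @property
    def mean_sc(self) -> float:
        return sum(self.sc_replicates) / len(self.sc_replicates)


def collect_pair_evidence(
    table: PurificationTable, bait_group_id: str, prey_id: str
) -> PairEvidence:
    """Gather the zero-filled replicate and control SC vectors of a pair."""
    return PairEvidence(
        bait_group_id=bait_group_id,
        prey_id=prey_id,
        sc_replicates=tuple(table.group_scs(bait_group_id, prey_id)),
        sc_controls=tuple(table.control_scs(prey_id)),
    )


#: Fixed column order of the externally written score table.
SCORE_COLUMNS = [
    "bait",
    "prey",
    "nsaf",
    "w",
    "z",
    "wd",
    "p",
    "fdr",
    "ppirank",
    "rank",
    "filtered",
    "filter_reason",
]

#: Internal columns kept alongside the external ones.
INTERNAL_COLUMNS = ["bait_name", "condition", "r", "freq", "n_detect", "is_bait_self"]


@dataclass
class ScoreTable:
    """Per-(bait group, prey) computed quantities, one row per scored pair.

    ``frame`` columns: the external :data:`SCORE_COLUMNS` (``bait`` is the
    bait-group id) plus :data:`INTERNAL_COLUMNS` when produced by
    :func:`ppirank.scoring.score_all`.  Filters flag rows (``filtered`` /
    ``filter_reason``), they never delete them; ranks cover unfiltered rows
    only.
    """

    frame: pd.DataFrame
    config: Any = None

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"score table missing columns: {missing}")

    def assign_ranks(self) -> None:
        """(Re)assign ranks 1..n over unfiltered rows, descending score.

        Ties are broken lexicographically by (bait group, prey) so the
        ordering is fully deterministic.  Filtered rows get a null rank and
        sort after the ranked block.
        """
        df = self.frame
        order = df.sort_values(
            by=["filtered", "ppirank", "bait", "prey"],
            ascending=[True, False, True, True],
            kind="mergesort",
        ).index
        df = df.loc[order].reset_index(drop=True)
        n_keep = int((~df["filtered"]).sum())
        rank = pd.array([pd.NA] * len(df), dtype="Int64")
        rank[:n_keep] = range(1, n_keep + 1)
        df["rank"] = rank
        self.frame = df

    @property
    def n_unfiltered(self) -> int:
        return int((~self.frame["filtered"]).sum())

    def top(self, k: int) -> pd.DataFrame:
        """First k unfiltered rows by rank."""
        kept = self.frame[~self.frame["filtered"]]
        return kept.nsmallest(k, "rank")

    def copy(self) -> "ScoreTable":
        return ScoreTable(frame=self.frame.copy(), config=self.config)


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered protein pair in canonical (lexicographic) order."""
    return (a, b) if a <= b else (b, a)


@dataclass
class KnownInteractionSet:
    """Reference set of known interactions as unordered symbol pairs.

    ``tags`` records the experimental-system types seen for each pair
    (e.g. ``physical``, ``genetic``).  Self-pairs are retained but
    reported by :attr:`self_pairs`.
    """

    tags: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(self.tags)

    @property
    def self_pairs(self) -> set[tuple[str, str]]:
        return {p for p in self.tags if p[0] == p[1]}

    def add(self, a: str, b: str, tag: str = "") -> None:
        key = canonical_pair(a, b)
        bucket = self.tags.setdefault(key, set())
        if tag:
            bucket.add(tag)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self.tags

    def __len__(self) -> int:
        return len(self.tags)
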