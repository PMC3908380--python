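"""Model/Results interface over the scoring pipeline.

``PPIRankModel`` is constructed from an experiment (a
:class:`~ppirank.datamodel.PurificationTable`, a long-format DataFrame, or
one of the supported files) plus a :class:`~ppirank.scoring.ScoringConfig`;
``fit()`` runs the full pipeline — NSAF, cross-purification weights,
rank-sum/FDR against the negative controls, composite scoring, singleton
flagging, ranking — and returns a :class:`PPIRankResults` holding the
score table with ``summary()``, export and evaluation helpers.
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from . import io as ppio
from .datamodel import PurificationTable, ScoreTable, ValidationError
from .evaluation import MethodScores, method_scores_from_table
from .filters import ExclusionList, exclusion_filter
from .scoring import ScoringConfig, score_all


class PPIRankModel:
    """Interaction-scoring model for one TAP/MS experiment."""

    def __init__(
        self, table: PurificationTable, config: Optional[ScoringConfig] = None
    ) -> None:
        self.table = table
        self.config = config or ScoringConfig()

    @classmethod
    def from_long_tsv(cls, path: str, config: Optional[ScoringConfig] = None) -> "PPIRankModel":
        return cls(ppio.read_long_tsv(path), config)

    @classmethod
    def from_saint(
        cls,
        interaction_path: str,
        bait_path: str,
        prey_path: str,
        config: Optional[ScoringConfig] = None,
    ) -> "PPIRankModel":
        return cls(ppio.read_saint_triple(interaction_path, bait_path, prey_path), config)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, config: Optional[ScoringConfig] = None
    ) -> "PPIRankModel":
        """Build from a long-format DataFrame (columns as the long TSV)."""
        missing = [c for c in ppio.LONG_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"long-format frame missing column(s) {missing}")
        import tempfile

        with tempfile.NamedTemporaryFile(
            "w", suffix=".tsv", delete=False, encoding="utf-8"
        ) as fh:
            frame.to_csv(fh, sep="\t", index=False)
            tmp = fh.name
        try:
            return cls(ppio.read_long_tsv(tmp), config)
        finally:
            os.unlink(tmp)

    def fit(self) -> "PPIRankResults":
        """Score every detected bait-prey pair and rank the experiment."""
        return PPIRankResults(self, score_all(self.table, self.config))


class PPIRankResults:
    """Fitted scores of one experiment, with export and evaluation helpers."""

    def __init__(self, model: PPIRankModel, scores: ScoreTable) -> None:
        self.model = model
        self.scores = scores

    @property
    def frame(self) -> pd.DataFrame:
        return self.scores.frame

    def apply_exclusions(self, exclusions: ExclusionList) -> "PPIRankResults":
        """Flag contaminant-class preys/baits; returns new results."""
        return PPIRankResults(self.model, exclusion_filter(self.scores, exclusions))

    def method_scores(self, column: str = "ppirank", name: Optional[str] = None) -> MethodScores:
        return method_scores_from_table(self.scores, column, name)

    def save(self, path: str) -> None:
        ppio.write_score_table(self.scores, path)

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.scores.top(k)

    def summary(self, top: int = 10) -> str:
        """Human-readable account of the experiment and its best pairs."""
        table = self.model.table
        cfg = self.model.config
        df = self.frame
        kept = df[~df["filtered"]]
        lines = [
            "PPIRank scoring summary",
            "=" * 59,
            f"bait groups (K):          {table.n_bait_groups}",
            f"control runs:             {len(table.control_runs)}",
            f"scored pairs:             {len(df)}",
            f"flagged by filters:       {int(df['filtered'].sum())}",
            f"std convention:           {cfg.std_convention}",
            f"rank-sum alternative:     {cfg.ranksum_alternative}",
            f"exact enumeration cap:    {cfg.exact_cap}",
            "-" * 59,
            f"{'rank':>4}  {'bait':<14} {'prey':<10} {'score':>10} {'fdr':>6} {'p':>8}",
        ]
        for row in kept.nsmallest(min(top, len(kept)), "rank").itertuples(index=False):
            lines.append(
                f"{int(row.rank):>4}  {row.bait:<14} {row.prey:<10} "
                f"{row.ppirank:>10.4g} {row.fdr:>6.3f} {row.p:>8.3g}"
            )
        lines.append("=" * 59)
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<PPIRankResults: {len(self.frame)} pairs, {self.scores.n_unfiltered} ranked>"
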