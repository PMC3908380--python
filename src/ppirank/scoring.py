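"""Spectral-count scoring: NSAF, CompPASS-style Z/WD, and the composite score.

The composite score for a bait-prey pair (i, j) is

    score_ij = NSAF_ij × (1 − FDR_ij)^T × W_j × (K / Σ_i f_ij)^R

where NSAF_ij is the replicate-averaged normalized spectral abundance
factor, FDR_ij the negative-control calibration of the pair's rank-sum
p-value, T the number of biological replicates, W_j the coefficient-of-
variation weight of the prey across all K purifications, K/Σf the
uniqueness of the prey across purifications, and R = N/T the fraction of
replicates detecting the pair.  Higher scores mean stronger evidence for a
specific, reproducible interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    PairEvidence,
    PurificationTable,
    ScoreTable,
    SCORE_COLUMNS,
    ValidationError,
    collect_pair_evidence,
)
from . import control_stats
from .filters import singleton_filter


@dataclass
class ScoringConfig:
    """Tunable scoring conventions.

    w_threshold
        W_j = std/mean only when that ratio exceeds this threshold,
        otherwise W_j = 1.  Default 0 (any positive coefficient of
        variation is used); 1 reproduces the original CompPASS convention
        of only boosting high-variance preys.
    std_convention
        "population" (divide by K; keeps Z well defined at K=2) or
        "sample" (K−1).  Applied consistently in W and Z.
    exponent_mode
        "freq_only": W × (K/Σf)^R (default — the reproducibility exponent
        acts on the frequency ratio); "joint": (W × K/Σf)^R.
    singleton_rule
        "le_one": filter pairs whose every replicate SC is 0 or 1;
        "strict_ones": only filter when every replicate SC is exactly 1.
    ranksum_alternative / exact_cap
        Passed to the rank-sum test against negative controls.
    min_replicates_warn
        Warn when a bait group has fewer replicates than this; the method
        is designed for at least three biological replicates.
    """

    w_threshold: float = 0.0
    std_convention: str = "population"
    exponent_mode: str = "freq_only"
    singleton_rule: str = "le_one"
    ranksum_alternative: str = "greater"
    exact_cap: int = control_stats.EXACT_ENUMERATION_CAP
    min_replicates_warn: int = 3
    averaging: str = "mean"
    tie_break: str = "by_prey_id"

    def __post_init__(self) -> None:
        if self.std_convention not in ("population", "sample"):
            raise ValidationError(f"unknown std_convention {self.std_convention!r}")
        if self.exponent_mode not in ("freq_only", "joint"):
            raise ValidationError(f"unknown exponent_mode {self.exponent_mode!r}")
        if self.singleton_rule not in ("le_one", "strict_ones"):
            raise ValidationError(f"unknown singleton_rule {self.singleton_rule!r}")
        if self.averaging != "mean":
            raise ValidationError("only mean aggregation of replicate NSAF is supported")
        if self.w_threshold not in (0.0, 1.0):
            warnings.warn(
                f"w_threshold={self.w_threshold} is outside the conventional {{0, 1}}",
                stacklevel=2,
            )

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "ScoringConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


DEFAULT_CONFIG = ScoringConfig()


def nsaf(table: PurificationTable, run_id: str) -> dict[str, float]:
    """Normalized spectral abundance factors of one run.

    NSAF_j = (SC_j / L_j) / Σ_k (SC_k / L_k), over the preys detected in
    the run; values sum to 1.  Preys with SC = 0 are absent from the
    mapping (their NSAF is 0).  A run with no detections yields an empty
    mapping with a warning.
    """
    counts = table.run_counts(run_id)
    if not counts:
        warnings.warn(f"run {run_id!r} has no detected preys; NSAF undefined", stacklevel=2)
        return {}
    saf = {prey: sc / table.prey_lengths[prey] for prey, sc in counts.items()}
    total = sum(saf.values())
    return {prey: v / total for prey, v in saf.items()}


def nsaf_mean(table: PurificationTable, bait_group_id: str, prey_id: str) -> float:
    """Replicate-averaged NSAF of a pair (zero for undetected replicates)."""
    run_ids = table.bait_groups.get(bait_group_id)
    if run_ids is None:
        raise ValidationError(f"unknown bait group {bait_group_id!r}")
    values = []
    for run_id in run_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_run = nsaf(table, run_id)
        values.append(per_run.get(prey_id, 0.0))
    return sum(values) / len(values)


def _group_mean_vector(table: PurificationTable, prey_id: str) -> np.ndarray:
    """Per-bait-group mean SC of a prey across all K groups (zeros included)."""
    return np.array(
        [table.group_mean_sc(g, prey_id) for g in table.bait_groups], dtype=float
    )


def _std(x: np.ndarray, convention: str) -> float:
    if convention == "sample":
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return float(np.std(x))


def variance_weight(
    table: PurificationTable, prey_id: str, config: ScoringConfig = DEFAULT_CONFIG
) -> float:
    """CompPASS weight W_j = std_j / mean_j of the prey across purifications.

    The cross-purification vector collapses each bait group's replicates to
    their mean SC (zeros included).  When the coefficient of variation does
    not exceed ``config.w_threshold`` — including the degenerate mean = 0
    case — W_j is 1.  Preys whose SC varies strongly across baits are more
    likely specific interactors of some bait than uniform background.
    """
    x = _group_mean_vector(table, prey_id)
    mean = float(x.mean())
    if mean == 0.0:
        return 1.0
    ratio = _std(x, config.std_convention) / mean
    return ratio if ratio > config.w_threshold else 1.0


def compass_z(
    table: PurificationTable,
    bait_group_id: str,
    prey_id: str,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Z-score of the prey's SC in this purification vs all purifications.

    Z = (s − mean_j) / std_j with s the prey's mean SC in the bait group
    and mean/std taken over all K bait groups.  Zero when std_j = 0.
    """
    x = _group_mean_vector(table, prey_id)
    s = table.group_mean_sc(bait_group_id, prey_id)
    sd = _std(x, config.std_convention)
    if sd == 0.0:
        return 0.0
    return (s - float(x.mean())) / sd


def compass_wd(
    table: PurificationTable,
    bait_group_id: str,
    prey_id: str,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """CompPASS weighted D-score: sqrt(SC × ((K/Σf) · W_j)^N).

    SC is the pair's mean spectral count over its replicates, Σf the number
    of purifications detecting the prey, and N the number of replicates
    detecting the pair.  Zero when the pair is undetected.
    """
    pair = collect_pair_evidence(table, bait_group_id, prey_id)
    s = pair.mean_sc
    if s == 0.0:
        return 0.0
    k = table.n_bait_groups
    sigma_f = len(table.detected_groups(prey_id))
    w = variance_weight(table, prey_id, config)
    return float(np.sqrt(s * ((k / sigma_f) * w) ** pair.detect_count))


def freq_repro_term(
    pair: PairEvidence,
    table: PurificationTable,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Reproducibility-weighted frequency term W_j × (K/Σf)^R.

    R = N/T ∈ (0, 1] replaces CompPASS's raw detection count N: a pair seen
    in every replicate gets the full uniqueness boost K/Σf, while a pair
    seen once in T replicates gets only its T-th root.  Requires the pair
    to be detected somewhere (Σf >= 1).
    """
    if not pair.detected_any:
        raise ValidationError(
            f"frequency term undefined for undetected pair "
            f"({pair.bait_group_id!r}, {pair.prey_id!r})"
        )
    k = table.n_bait_groups
    sigma_f = len(table.detected_groups(pair.prey_id))
    if sigma_f == 0:
        raise ValidationError(f"prey {pair.prey_id!r} detected in no purification")
    t = len(pair.sc_replicates)
    r = pair.detect_count / t
    base = k / sigma_f
    w = variance_weight(table, pair.prey_id, config)
    if config.exponent_mode == "joint":
        return float((base * w) ** r)
    return float(w * base**r)


def ppirank_score(
    pair: PairEvidence,
    table: PurificationTable,
    fdr: float,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> float:
    """Composite score NSAF̄ × (1−FDR)^T × W_j × (K/Σf)^R for one pair."""
    if not (0.0 <= fdr <= 0.5):
        raise ValidationError(f"fdr must lie in [0, 0.5], got {fdr}")
    if not pair.detected_any:
        return 0.0
    t = len(pair.sc_replicates)
    abundance = nsaf_mean(table, pair.bait_group_id, pair.prey_id)
    return abundance * (1.0 - fdr) ** t * freq_repro_term(pair, table, config)


def score_all(
    table: PurificationTable, config: Optional[ScoringConfig] = None
) -> ScoreTable:
    """Score every detected (bait group, prey) pair in the experiment.

    Produces one row per pair with ``detected_any`` true, with all
    component columns (NSAF, W, Z, WD, p, FDR, composite score).  The
    all-singleton filter is applied as a flag, never a deletion; ranks run
    1..n over unfiltered rows by descending score with deterministic
    lexicographic tie-breaking.

    Raises an error when no control runs are present — the FDR calibration
    requires negative controls.
    """
    config = config or DEFAULT_CONFIG
    if not table.control_runs:
        raise ValidationError(
            "scoring requires negative controls: add at least one control run "
            "(a purification from cells expressing no tagged bait)"
        )
    for group, run_ids in table.bait_groups.items():
        if len(run_ids) < config.min_replicates_warn:
            warnings.warn(
                f"bait group {group!r} has {len(run_ids)} replicate(s); the method "
                f"is designed for at least three biological replicates",
                stacklevel=2,
            )

    rows = []
    for group in table.bait_groups:
        bait, condition = table.bait_of(group), table.condition_of(group)
        for prey in table.detected_preys(group):
            pair = collect_pair_evidence(table, group, prey)
            result = control_stats.ranksum_p(
                pair.sc_replicates,
                pair.sc_controls,
                config.ranksum_alternative,
                config.exact_cap,
            )
            fdr = control_stats.fdr_from_p(result.p_value)
            is_singleton = singleton_filter(pair, config.singleton_rule)
            rows.append(
                {
                    "bait": group,
                    "prey": prey,
                    "nsaf": nsaf_mean(table, group, prey),
                    "w": variance_weight(table, prey, config),
                    "z": compass_z(table, group, prey, config),
                    "wd": compass_wd(table, group, prey, config),
                    "p": result.p_value,
                    "fdr": fdr,
                    "ppirank": ppirank_score(pair, table, fdr, config),
                    "rank": pd.NA,
                    "filtered": is_singleton,
                    "filter_reason": "singleton" if is_singleton else "",
                    "bait_name": bait,
                    "condition": condition,
                    "r": pair.detect_count / len(pair.sc_replicates),
                    "freq": table.n_bait_groups / len(table.detected_groups(prey)),
                    "n_detect": pair.detect_count,
                    "is_bait_self": prey == bait,
                }
            )
    columns = SCORE_COLUMNS + ["bait_name", "condition", "r", "freq", "n_detect", "is_bait_self"]
    frame = pd.DataFrame(rows, columns=columns)
    frame["rank"] = frame["rank"].astype("Int64")
    scores = ScoreTable(frame=frame, config=config)
    scores.assign_ranks()
    return scores
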