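"""Synthetic TAP/MS experiments with planted ground truth.

The generator emulates the design the scoring method assumes: several
baits, each purified under several conditions (e.g. stimulation time
points) with three biological replicates, alongside a shared pool of
negative-control runs.  Four prey classes are planted:

* **true interactors** — high, reproducible spectral counts in the runs of
  their bait (Poisson around ``lambda_true``), subject to per-replicate
  dropout, absent from controls;
* **sticky binders** — promiscuous preys appearing across many baits and
  carried over into controls at low abundance;
* **contaminants** — heat-shock/ribosomal-style preys behaving like sticky
  binders but carrying recognisable names (Hsp…/RpL…) so the exclusion
  filter can be exercised;
* **background** — sparse low-count noise in test runs.

Bait self-detection rows are always generated (a purification always
contains its own bait) and flagged in the truth so benchmarks can exclude
them.  Output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datamodel import (
    CONTROL_GROUP,
    PurificationTable,
    Run,
    ValidationError,
    make_group_id,
)
from .scoring import ScoringConfig, score_all


@dataclass
class SimulationConfig:
    """Generator parameters; defaults mirror the assumed study design.

    Six baits over three time points with three biological replicates and
    six shared negative controls, 300 preys.  ``lambda_true`` /
    ``lambda_background`` are the Poisson mean SCs of planted edges and of
    nuisance detections; ``dropout_prob`` is the per-replicate missed-
    detection probability of a true edge; ``control_carryover_prob`` is the
    per-control-run detection probability of sticky/contaminant preys.
    """

    n_baits: int = 6
    conditions: tuple[str, ...] = ("0", "10", "30")
    n_replicates: int = 3
    n_controls: int = 6
    n_preys: int = 300
    true_edges_per_bait: int = 8
    lambda_true: float = 10.0
    lambda_background: float = 2.0
    dropout_prob: float = 0.2
    sticky_fraction: float = 0.05
    control_carryover_prob: float = 0.3
    contaminant_fraction: float = 0.05
    prey_length_range: tuple[int, int] = (100, 1000)
    seed: int = 0
    # secondary design constants
    sticky_bait_prob: float = 0.7  # chance a sticky prey attaches to a given bait
    background_detect_prob: float = 0.02  # per (run, background prey) detection
    self_sc_scale: float = 5.0  # bait self-SC mean = scale * lambda_true
    dispersion: float = 0.0  # negative-binomial overdispersion; 0 = Poisson

    def validate(self) -> None:
        problems = []
        if self.n_baits < 1 or self.n_replicates < 1 or self.n_controls < 1:
            problems.append("n_baits, n_replicates, n_controls must be >= 1")
        if not self.conditions:
            problems.append("at least one condition label is required")
        if self.n_preys < 1:
            problems.append("n_preys must be >= 1")
        if not (0.0 <= self.dropout_prob < 1.0):
            problems.append(f"dropout_prob must lie in [0, 1), got {self.dropout_prob}")
        for name in ("control_carryover_prob", "sticky_bait_prob", "background_detect_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must be a probability, got {v}")
        for name in ("lambda_true", "lambda_background", "sticky_fraction",
                     "contaminant_fraction", "dispersion"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        lo, hi = self.prey_length_range
        if not (0 < lo <= hi):
            problems.append(f"prey_length_range must be a positive pair, got {lo, hi}")
        if self.true_edges_per_bait * self.n_baits > self.n_preys:
            problems.append("not enough preys to plant the requested true edges")
        if problems:
            raise ValidationError("invalid simulation config: " + "; ".join(problems))


@dataclass
class SimulationTruth:
    """Planted edges and prey classes emitted alongside a simulation."""

    edges: set[tuple[str, str]]  # (bait_group_id, prey_id)
    self_pairs: set[tuple[str, str]]
    prey_class: dict[str, str]  # prey -> true|sticky|contaminant|background|bait
    edge_rate: dict[tuple[str, str], float]
    config: SimulationConfig


def _draw_count(rng: np.random.Generator, lam: float, dispersion: float) -> int:
    if lam <= 0:
        return 0
    if dispersion > 0:  # negative binomial with mean lam, extra variance lam*(1+d*lam)
        size = 1.0 / dispersion
        p = size / (size + lam)
        return int(rng.negative_binomial(size, p))
    return int(rng.poisson(lam))


def simulate_experiment(
    config: Optional[SimulationConfig] = None,
) -> tuple[PurificationTable, SimulationTruth]:
    """Generate a synthetic experiment and its ground truth."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    baits = [f"BAIT{i + 1}" for i in range(config.n_baits)]
    preys = [f"P{i + 1:04d}" for i in range(config.n_preys)]

    n_cont = round(config.contaminant_fraction * config.n_preys)
    n_sticky = round(config.sticky_fraction * config.n_preys)
    prey_class: dict[str, str] = {}
    renamed: list[str] = []
    for i, prey in enumerate(preys):
        if i < n_cont:
            name = f"Hsp{i + 1:02d}" if i % 2 == 0 else f"RpL{i + 1:02d}"
            prey_class[name] = "contaminant"
        elif i < n_cont + n_sticky:
            name = prey
            prey_class[name] = "sticky"
        else:
            name = prey
            prey_class[name] = "background"
        renamed.append(name)
    preys = renamed
    contaminants = [p for p in preys if prey_class[p] == "contaminant"]
    sticky = [p for p in preys if prey_class[p] == "sticky"]
    pool = [p for p in preys if prey_class[p] == "background"]

    lo, hi = config.prey_length_range
    lengths = {p: int(rng.integers(lo, hi + 1)) for p in preys}
    for bait in baits:
        lengths[bait] = int(rng.integers(lo, hi + 1))
        prey_class[bait] = "bait"

    # plant true edges: disjoint prey blocks per bait, shared across conditions
    shuffled = list(rng.permutation(pool))
    true_edges_by_bait: dict[str, list[str]] = {}
    for i, bait in enumerate(baits):
        block = shuffled[i * config.true_edges_per_bait : (i + 1) * config.true_edges_per_bait]
        true_edges_by_bait[bait] = block
        for prey in block:
            prey_class[prey] = "true"

    # sticky/contaminant attachment to baits, drawn once per prey
    nuisance = sticky + contaminants
    attachment = {
        prey: {b for b in baits if rng.random() < config.sticky_bait_prob}
        for prey in nuisance
    }

    runs: list[Run] = []
    counts: dict[tuple[str, str], int] = {}
    edges: set[tuple[str, str]] = set()
    self_pairs: set[tuple[str, str]] = set()
    edge_rate: dict[tuple[str, str], float] = {}
    background_pool = [p for p in preys if prey_class[p] in ("background", "true")]

    for bait in baits:
        for condition in config.conditions:
            group = make_group_id(bait, condition)
            for prey in true_edges_by_bait[bait]:
                edges.add((group, prey))
                edge_rate[(group, prey)] = config.lambda_true
            self_pairs.add((group, bait))
            for rep in range(1, config.n_replicates + 1):
                run_id = f"{group}|r{rep}"
                runs.append(Run(run_id, group, False, bait, condition))
                # bait self-detection
                sc = _draw_count(
                    rng, config.self_sc_scale * config.lambda_true, config.dispersion
                )
                if sc > 0:
                    counts[(run_id, bait)] = sc
                # planted true edges with dropout
                for prey in true_edges_by_bait[bait]:
                    if rng.random() < config.dropout_prob:
                        continue
                    sc = _draw_count(rng, config.lambda_true, config.dispersion)
                    if sc > 0:
                        counts[(run_id, prey)] = sc
                # sticky / contaminant attachments
                for prey in nuisance:
                    if bait in attachment[prey]:
                        sc = _draw_count(rng, config.lambda_background, config.dispersion)
                        if sc > 0:
                            counts[(run_id, prey)] = sc
                # sparse background noise (true preys of other baits included)
                mask = rng.random(len(background_pool)) < config.background_detect_prob
                for prey, hit in zip(background_pool, mask):
                    if not hit or (run_id, prey) in counts:
                        continue
                    sc = _draw_count(rng, config.lambda_background, config.dispersion)
                    if sc > 0:
                        counts[(run_id, prey)] = sc

    for rep in range(1, config.n_controls + 1):
        run_id = f"CTRL|r{rep}"
        runs.append(Run(run_id, CONTROL_GROUP, True))
        for prey in nuisance:
            if rng.random() < config.control_carryover_prob:
                sc = _draw_count(rng, config.lambda_background, config.dispersion)
                if sc > 0:
                    counts[(run_id, prey)] = sc

    table = PurificationTable(runs, counts, lengths)
    truth = SimulationTruth(
        edges=edges,
        self_pairs=self_pairs,
        prey_class=prey_class,
        edge_rate=edge_rate,
        config=config,
    )
    return table, truth


def write_truth_tsv(truth: SimulationTruth, path: str) -> None:
    """Write the planted edges and prey classes as TSV.

    Columns: bait_group, prey, rate, prey_class, is_self.  Generator
    parameters are echoed as '#' comment lines.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in sorted(asdict(truth.config).items()):
            fh.write(f"# {key} = {value}\n")
        fh.write("bait_group\tprey\trate\tprey_class\tis_self\n")
        rows = [
            (g, p, truth.edge_rate.get((g, p), 0.0), truth.prey_class.get(p, ""), 0)
            for (g, p) in truth.edges
        ] + [(g, p, 0.0, "bait", 1) for (g, p) in truth.self_pairs]
        for g, p, rate, cls, is_self in sorted(rows):
            fh.write(f"{g}\t{p}\t{rate:g}\t{cls}\t{is_self}\n")


def noise_free_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Separable configuration with every stochastic noise channel off.

    True edges are fully reproducible (no dropout), controls catch every
    nuisance binder (carryover probability 1), and there are no sporadic
    background detections.  Sticky and contaminant preys remain, so scored
    negatives exist, but a correct scorer separates the planted edges from
    them perfectly.
    """
    params = dict(
        dropout_prob=0.0,
        control_carryover_prob=1.0,
        background_detect_prob=0.0,
        seed=seed,
    )
    params.update(overrides)
    return SimulationConfig(**params)


_METHOD_COLUMNS = {
    "ppirank": "ppirank",
    "nsaf": "nsaf",
    "compass_z": "z",
    "compass_wd": "wd",
}


def _auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the Mann–Whitney rank identity (ties mid-ranked)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def benchmark_methods(
    table: PurificationTable,
    truth: SimulationTruth,
    methods: Sequence[str] = ("ppirank", "nsaf", "compass_z", "compass_wd"),
    config: Optional[ScoringConfig] = None,
    recall_ks: int = 10,
) -> dict[str, dict]:
    """Rank-recovery metrics of each scoring method against planted truth.

    Scores the experiment once, drops bait self-rows, labels the remaining
    detected pairs by membership in the planted edge set, and reports per
    method: AUROC, precision at k = number of planted positives among the
    scored pairs, and a recall-at-k curve.  AUROC is ``None`` (with a
    warning) when the labels are degenerate.
    """
    import warnings

    unknown = set(methods) - set(_METHOD_COLUMNS)
    if unknown:
        raise ValidationError(f"unknown methods: {sorted(unknown)}")
    scored = score_all(table, config)
    df = scored.frame
    df = df[~df["is_bait_self"].astype(bool)]
    keys = list(zip(df["bait"], df["prey"]))
    labels = np.array([key in truth.edges for key in keys], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos

    out: dict[str, dict] = {}
    for method in methods:
        col = _METHOD_COLUMNS[method]
        values = df[col].to_numpy(dtype=float)
        if n_pos == 0 or n_neg == 0:
            warnings.warn(
                "AUROC undefined: planted truth covers all or none of the scored pairs",
                stacklevel=2,
            )
            auroc = None
        else:
            auroc = _auroc(values, labels)
        # deterministic ranking: descending score, then (bait, prey)
        order = sorted(range(len(keys)), key=lambda i: (-values[i], keys[i]))
        k = n_pos
        precision_at_k = (
            float(labels[order[:k]].sum() / k) if 0 < k <= len(order) else None
        )
        recall_curve = []
        if n_pos > 0:
            for frac in np.linspace(1 / recall_ks, 1.0, recall_ks):
                depth = max(1, int(round(frac * len(order))))
                recall_curve.append(
                    (depth, float(labels[order[:depth]].sum() / n_pos))
                )
        out[method] = {
            "auroc": auroc,
            "precision_at_k": precision_at_k,
            "k": k,
            "recall_curve": recall_curve,
            "n_scored": len(keys),
        }
    return out
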