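"""Readers and writers for the external formats.

Supported formats:

* **long-format TSV** — one row per (run, prey) observation with columns
  ``run_id  bait  prey  sc  prey_length  is_control  condition``.  Rows
  with SC = 0 act as declarations: they register the run and the prey
  length without recording a count, which lets the format carry runs with
  no detections and preys never detected.
* **SAINT-style triple** — the interaction/bait/prey file trio used by the
  SAINT ecosystem (headerless, tab-separated).
* **BioGRID TAB 2.0/3.0** — the known-interaction reference, read into
  canonical unordered symbol pairs.
* **score-table TSV** — the tool's own output, with a fixed column order
  and '#' comment lines echoing the effective configuration.

All TSV dialects: tab separator, '.' decimal, UTF-8, '#' comment lines.
"""

from __future__ import annotations

import dataclasses
import warnings

import pandas as pd

from .datamodel import (
    CONTROL_GROUP,
    FormatError,
    KnownInteractionSet,
    PurificationTable,
    Run,
    SCORE_COLUMNS,
    ScoreTable,
    ValidationError,
    make_group_id,
    split_group_id,
)

LONG_COLUMNS = ["run_id", "bait", "prey", "sc", "prey_length", "is_control", "condition"]

_FLOAT_FMT = "%.10g"


def _read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs
    )


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in ("1", "true", "t", "yes"):
        return True
    if v in ("0", "false", "f", "no", ""):
        return False
    raise FormatError(f"{where}: cannot interpret {value!r} as a boolean")


def read_long_tsv(path: str) -> PurificationTable:
    """Load an experiment from the long-format TSV."""
    df = _read_tsv(path)
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    runs: dict[str, Run] = {}
    counts: dict[tuple[str, str], int] = {}
    lengths: dict[str, int] = {}
    for row in df.itertuples(index=False):
        run_id = row.run_id
        is_control = _parse_bool(row.is_control, f"{path} run {run_id!r}")
        bait = "" if is_control else row.bait
        condition = "" if is_control else row.condition
        group = CONTROL_GROUP if is_control else make_group_id(bait, condition)
        run = Run(run_id, group, is_control, bait, condition)
        if run_id in runs:
            if runs[run_id] != run:
                raise ValidationError(
                    f"{path}: run {run_id!r} declared with inconsistent bait/"
                    f"condition/control fields"
                )
        else:
            runs[run_id] = run

        prey = row.prey
        try:
            length = int(row.prey_length)
        except ValueError:
            raise FormatError(f"{path}: non-integer prey_length {row.prey_length!r}") from None
        if prey in lengths and lengths[prey] != length:
            raise ValidationError(
                f"{path}: prey {prey!r} has inconsistent lengths "
                f"({lengths[prey]} vs {length})"
            )
        lengths[prey] = length

        try:
            sc = int(row.sc)
        except ValueError:
            raise FormatError(f"{path}: non-integer spectral count {row.sc!r}") from None
        if sc < 0:
            raise ValidationError(f"{path}: negative spectral count for ({run_id!r}, {prey!r})")
        if sc > 0:
            if (run_id, prey) in counts:
                raise ValidationError(f"{path}: duplicate entry for ({run_id!r}, {prey!r})")
            counts[(run_id, prey)] = sc

    return PurificationTable(runs.values(), counts, lengths)


def write_long_tsv(table: PurificationTable, path: str) -> None:
    """Write an experiment as long-format TSV (inverse of read_long_tsv).

    Runs without detections and preys never detected are emitted as SC = 0
    declaration rows so the round trip is lossless.
    """
    rows = []

    def emit(run: Run, prey: str, sc: int) -> None:
        rows.append(
            {
                "run_id": run.run_id,
                "bait": run.bait,
                "prey": prey,
                "sc": sc,
                "prey_length": table.prey_lengths[prey],
                "is_control": int(run.is_control),
                "condition": run.condition,
            }
        )

    detected: set[str] = set()
    for run in table.runs:
        run_counts = table.run_counts(run.run_id)
        for prey in sorted(run_counts):
            emit(run, prey, run_counts[prey])
            detected.add(prey)
        if not run_counts:  # declaration row for an empty run
            emit(run, min(table.prey_lengths), 0)
    first = table.runs[0]
    for prey in sorted(set(table.prey_lengths) - detected):
        emit(first, prey, 0)

    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_saint_triple(
    interaction_path: str, bait_path: str, prey_path: str
) -> PurificationTable:
    """Load an experiment from SAINT-style interaction/bait/prey files.

    Bait-file rows are ``run_id  bait_name  T|C``; runs flagged C become
    negative controls.  The bait name of a test run becomes its bait-group
    id; a ``bait|condition`` suffix convention is split back into bait and
    condition labels.
    """
    baits = _read_tsv(bait_path, header=None)
    if baits.shape[1] < 3:
        raise FormatError(f"{bait_path}: expected 3 columns (run_id, bait, T/C)")
    runs: dict[str, Run] = {}
    bait_name_of: dict[str, str] = {}
    for row in baits.itertuples(index=False):
        run_id, bait_name, flag = row[0], row[1], row[2].strip()
        if flag not in ("T", "C"):
            raise FormatError(f"{bait_path}: test/control flag must be T or C, got {flag!r}")
        if run_id in runs:
            raise ValidationError(f"{bait_path}: duplicate run {run_id!r}")
        if flag == "C":
            runs[run_id] = Run(run_id, CONTROL_GROUP, True)
        else:
            bait, condition = split_group_id(bait_name)
            runs[run_id] = Run(run_id, bait_name, False, bait, condition)
        bait_name_of[run_id] = bait_name

    preys = _read_tsv(prey_path, header=None)
    if preys.shape[1] < 2:
        raise FormatError(f"{prey_path}: expected >=2 columns (prey, length)")
    lengths: dict[str, int] = {}
    for row in preys.itertuples(index=False):
        prey, length = row[0], row[1]
        try:
            lengths[prey] = int(length)
        except ValueError:
            raise FormatError(f"{prey_path}: non-integer length {length!r} for {prey!r}") from None

    counts: dict[tuple[str, str], int] = {}
    try:
        inter = pd.read_csv(
            interaction_path, sep="\t", comment="#", dtype=str,
            keep_default_na=False, header=None,
        )
    except pd.errors.EmptyDataError:
        inter = pd.DataFrame()
    if len(inter) and inter.shape[1] < 4:
        raise FormatError(
            f"{interaction_path}: expected 4 columns (run_id, bait, prey, sc)"
        )
    for row in inter.itertuples(index=False):
        run_id, bait_name, prey, sc = row[0], row[1], row[2], row[3]
        if run_id not in runs:
            raise FormatError(
                f"{interaction_path}: run {run_id!r} not declared in the bait file"
            )
        if bait_name != bait_name_of[run_id]:
            raise ValidationError(
                f"{interaction_path}: run {run_id!r} listed under bait {bait_name!r} "
                f"but the bait file declares {bait_name_of[run_id]!r}"
            )
        if prey not in lengths:
            raise ValidationError(
                f"{interaction_path}: prey {prey!r} has no entry in the prey file"
            )
        sc = int(sc)
        if sc < 0:
            raise ValidationError(f"{interaction_path}: negative SC for ({run_id!r}, {prey!r})")
        if sc > 0:
            if (run_id, prey) in counts:
                raise ValidationError(
                    f"{interaction_path}: duplicate entry for ({run_id!r}, {prey!r})"
                )
            counts[(run_id, prey)] = sc

    return PurificationTable(runs.values(), counts, lengths)


def write_saint_triple(
    table: PurificationTable, interaction_path: str, bait_path: str, prey_path: str
) -> None:
    """Write an experiment as a SAINT-style triple (inverse of the reader)."""
    with open(bait_path, "w", encoding="utf-8") as fh:
        for run in table.runs:
            name = "CTRL" if run.is_control else run.bait_group_id
            flag = "C" if run.is_control else "T"
            fh.write(f"{run.run_id}\t{name}\t{flag}\n")
    with open(prey_path, "w", encoding="utf-8") as fh:
        for prey in sorted(table.prey_lengths):
            fh.write(f"{prey}\t{table.prey_lengths[prey]}\n")
    with open(interaction_path, "w", encoding="utf-8") as fh:
        for run in table.runs:
            name = "CTRL" if run.is_control else run.bait_group_id
            run_counts = table.run_counts(run.run_id)
            for prey in sorted(run_counts):
                fh.write(f"{run.run_id}\t{name}\t{prey}\t{run_counts[prey]}\n")


_BIOGRID_SYMBOL_A = "official symbol interactor a"
_BIOGRID_SYMBOL_B = "official symbol interactor b"
_BIOGRID_SYSTEM_TYPE = "experimental system type"


def read_biogrid_tab(path: str, physical_only: bool = True) -> KnownInteractionSet:
    """Load a BioGRID TAB 2.0/3.0 file into canonical unordered pairs.

    With ``physical_only`` (the default), rows whose experimental system
    type is ``genetic`` are dropped — indirect genetic interactions are a
    source of false reference positives.  Duplicate and reciprocal rows
    collapse onto one canonical pair.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as tab-separated table: {exc}") from exc
    colmap = {c.lower().lstrip("#").strip(): c for c in df.columns}
    try:
        col_a = colmap[_BIOGRID_SYMBOL_A]
        col_b = colmap[_BIOGRID_SYMBOL_B]
        col_type = colmap[_BIOGRID_SYSTEM_TYPE]
    except KeyError as exc:
        raise FormatError(
            f"{path}: header lacks a BioGRID TAB column: {exc.args[0]!r}"
        ) from None

    known = KnownInteractionSet()
    # column names contain spaces; index rows positionally
    a_idx = df.columns.get_loc(col_a)
    b_idx = df.columns.get_loc(col_b)
    t_idx = df.columns.get_loc(col_type)
    for row in df.itertuples(index=False, name=None):
        system_type = row[t_idx].strip().lower()
        if physical_only and system_type == "genetic":
            continue
        known.add(row[a_idx].strip(), row[b_idx].strip(), system_type)
    if len(known) == 0:
        warnings.warn(f"{path}: no interactions retained after filtering", stacklevel=2)
    return known


def write_score_table(scores: ScoreTable, path: str) -> None:
    """Write a score table as TSV with the fixed external column order.

    Rows are sorted by rank (unfiltered first), filtered rows follow by
    descending score.  The effective scoring configuration is echoed in
    '#' comment lines for provenance.
    """
    df = scores.frame
    order = df.sort_values(
        by=["filtered", "ppirank", "bait", "prey"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    out = order[SCORE_COLUMNS].copy()
    out["filtered"] = out["filtered"].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        if scores.config is not None:
            for key, value in sorted(dataclasses.asdict(scores.config).items()):
                fh.write(f"# {key} = {value}\n")
        out.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_score_table(path: str) -> ScoreTable:
    """Read back a score-table TSV written by :func:`write_score_table`."""
    df = _read_tsv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing score-table column(s) {missing}")
    for col in ("nsaf", "w", "z", "wd", "p", "fdr", "ppirank"):
        df[col] = pd.to_numeric(df[col])
    df["rank"] = pd.to_numeric(df["rank"].replace("", pd.NA)).astype("Int64")
    df["filtered"] = df["filtered"].map(lambda v: _parse_bool(v, path))
    df["filter_reason"] = df["filter_reason"].fillna("")
    return ScoreTable(frame=df[SCORE_COLUMNS].copy())


def write_edge_list(scores: ScoreTable, path: str, include_filtered: bool = False) -> None:
    """Export (bait, prey, score) edges for network tools, best first."""
    df = scores.frame
    if not include_filtered:
        df = df[~df["filtered"]]
    df = df.sort_values(
        by=["ppirank", "bait", "prey"], ascending=[False, True, True], kind="mergesort"
    )
    df[["bait", "prey", "ppirank"]].to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )
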