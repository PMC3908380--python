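"""Pre/post-scoring filters: all-singleton spectral counts and contaminants.

Filters flag rows, they never delete them: the score table keeps its row
count and records a reason code, and ranks are recomputed over the
survivors.  Flagging is idempotent and the two filters commute.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

from .datamodel import PairEvidence, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .datamodel import ScoreTable


def singleton_filter(pair: PairEvidence, rule: str = "le_one") -> bool:
    """True when the pair's evidence is all singleton spectral counts.

    A single spectral count per replicate is prone to experimental error or
    noise, so an interaction supported only by SC <= 1 in every replicate
    is flagged.  ``rule="le_one"`` (default) flags any pair whose replicate
    SCs all lie in {0, 1}; ``rule="strict_ones"`` only flags the literal
    one-SC-in-every-replicate case (all SCs exactly 1), which is the
    behaviour for exactly three replicates the rule generalises.
    """
    if not pair.detected_any:
        return False
    if rule == "strict_ones":
        return all(s == 1 for s in pair.sc_replicates)
    if rule == "le_one":
        return max(pair.sc_replicates) <= 1
    raise ValidationError(f"unknown singleton rule {rule!r}")


@dataclass
class ExclusionList:
    """Glob patterns of prey/bait identifiers to exclude, by category.

    Typical categories are ``heat_shock`` and ``ribosomal`` — abundant
    contaminant classes of affinity purifications — plus free-form ``user``
    entries.  Ships as an editable text file, not a hardcoded gene list.
    """

    patterns: list[tuple[str, str]] = field(default_factory=list)  # (pattern, category)

    def __post_init__(self) -> None:
        for pattern, category in self.patterns:
            if not category:
                raise ValidationError(f"pattern {pattern!r} has an empty category")

    @classmethod
    def from_file(cls, path: str) -> "ExclusionList":
        """Parse a plain-text list: ``[category]`` headers, one glob per line."""
        patterns: list[tuple[str, str]] = []
        category = "user"
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if line.startswith("[") and line.endswith("]"):
                    category = line[1:-1].strip()
                    if not category:
                        raise ValidationError(f"{path}:{lineno}: empty category header")
                    continue
                patterns.append((line, category))
        return cls(patterns=patterns)

    @classmethod
    def from_patterns(cls, entries: Iterable[tuple[str, str]]) -> "ExclusionList":
        return cls(patterns=list(entries))

    def match(self, name: str) -> Optional[str]:
        """Category of the first matching pattern, or None."""
        for pattern, category in self.patterns:
            if fnmatch.fnmatchcase(name, pattern):
                return category
        return None


def _merge_reason(existing: str, new: str) -> str:
    reasons = set(filter(None, existing.split(","))) | {new}
    return ",".join(sorted(reasons))


def exclusion_filter(scores: "ScoreTable", exclusions: ExclusionList) -> "ScoreTable":
    """Flag rows whose prey or bait matches an exclusion entry.

    Returns a new ScoreTable; matched rows get ``filtered=True`` with the
    matching category appended to the reason code, and ranks are
    recomputed over the surviving rows.
    """
    out = scores.copy()
    df = out.frame
    bait_names = df["bait_name"] if "bait_name" in df.columns else df["bait"]
    for idx in df.index:
        category = exclusions.match(df.at[idx, "prey"]) or exclusions.match(
            str(bait_names.at[idx])
        )
        if category is not None:
            df.at[idx, "filtered"] = True
            df.at[idx, "filter_reason"] = _merge_reason(df.at[idx, "filter_reason"], category)
    out.assign_ranks()
    return out
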