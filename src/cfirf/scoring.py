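"""Frequency-based (CFIR-f) classification and scoring, plus the original
+/-2 comparator.

The CFIR-f rules, applied per stakeholder group and theme:

1. A theme mentioned by fewer than the relevance threshold (default 50%,
   inclusive) of the group is excluded and scores 0.
2. A relevant theme is neutral (score 0) when a threshold-sized majority
   discussed it in neutral terms, or when enabler and barrier endorsers
   balance — exactly equal counts, or within a one-person margin in
   odd-sized groups where both valences occur.
3. Otherwise a threshold-sized barrier (enabler) majority classifies the
   theme as a barrier (enabler), scored minus (plus) the endorser count.
4. Group scores sum to a theme total; the sign of the total classifies
   the theme overall, and totals rank the themes.

The original CFIR comparator assigns each group -2/0/+2 (paper-
operationalised mode, reproducing published totals) or follows the
salience rubric literally (+/-1 for themes discussed only in passing,
"all themes included").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    CodedDataset,
    GroupThemeSummary,
    ScoringPolicy,
    summarise,
)

__all__ = [
    "Classification",
    "GroupScore",
    "ThemeResult",
    "ValidityReport",
    "RankedThemes",
    "IndeterminateSummaryError",
    "is_relevant",
    "classify_group_cfirf",
    "score_original_group",
    "score_study",
    "rank_themes",
    "concurrent_validity",
    "results_to_frame",
    "results_to_json",
    "ranked_to_markdown",
]

ORIGINAL_MODES = ("paper_operationalised", "rubric")


class IndeterminateSummaryError(ValueError):
    """A relevant cell matched no classification rule and policy says error."""


@dataclass(frozen=True)
class Classification:
    EXCLUDED = "excluded"
    BARRIER = "barrier"
    ENABLER = "enabler"
    NEUTRAL = "neutral"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class GroupScore:
    """Classification and scores for one (group, theme) cell.

    ``reasons`` records which rule fired, in evaluation order, so a report
    can explain every 0.
    """

    group_id: str
    theme_id: str
    classification: str
    cfirf_score: int
    original_score: int | None = None
    reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class ThemeResult:
    """Per-theme outcome: group scores, both totals, and the overall class."""

    theme_id: str
    label: str
    group_scores: tuple[GroupScore, ...]
    total_cfirf: int
    total_original: int
    overall_class: str
    mentioner_total: int

    def group_score(self, group_id: str) -> GroupScore:
        for gs in self.group_scores:
            if gs.group_id == group_id:
                return gs
        raise KeyError(group_id)


@dataclass(frozen=True)
class RankedThemes:
    """Theme results split into ordered report sections.

    Barriers are ordered most negative first, enablers most positive
    first; ties break on larger total mentioner count, then theme label.
    """

    barriers: tuple[ThemeResult, ...]
    neutral: tuple[ThemeResult, ...]
    enablers: tuple[ThemeResult, ...]


@dataclass(frozen=True)
class ValidityReport:
    """Concurrent-validity comparison of the two scorers' theme classes."""

    pairs: Mapping[str, tuple[str, str]]
    agreement_count: int
    n_themes: int
    tallies_cfirf: Mapping[str, int]
    tallies_original: Mapping[str, int]

    @property
    def agreement_fraction(self) -> float:
        return 1.0 if self.n_themes == 0 else self.agreement_count / self.n_themes


def is_relevant(summary: GroupThemeSummary, policy: ScoringPolicy | None = None) -> bool:
    """True when the cell's mention count meets the relevance threshold.

    Inclusive at the threshold: 3 of 6 passes the default 50% cutoff.
    """
    policy = policy or ScoringPolicy()
    return summary.mention_count >= policy.min_mentions(summary.group_size)


def classify_group_cfirf(
    summary: GroupThemeSummary, policy: ScoringPolicy | None = None
) -> GroupScore:
    """Apply the CFIR-f decision sequence to one cell; first match wins.

    Order matters: the neutrality criteria are tested before the
    barrier/enabler majorities, so a majority-mentioned theme with an
    equal enabler/barrier split is neutral even if one valence alone
    would clear the threshold.
    """
    policy = policy or ScoringPolicy()
    need = policy.min_mentions(summary.group_size)
    e, b, n = summary.enabler_count, summary.barrier_count, summary.neutral_count

    def make(classification: str, score: int, reason: str) -> GroupScore:
        return GroupScore(
            group_id=summary.group_id,
            theme_id=summary.theme_id,
            classification=classification,
            cfirf_score=score,
            reasons=(reason,),
        )

    if summary.mention_count < need:
        return make(Classification.EXCLUDED, 0, "below_threshold")
    if n >= need:
        return make(Classification.NEUTRAL, 0, "neutral_majority")
    if e == b:
        return make(Classification.NEUTRAL, 0, "balanced_valences")
    if summary.group_size % 2 == 1:
        both_present = min(e, b) >= 1 or not policy.neutrality_requires_both_valences
        if both_present and abs(e - b) <= policy.odd_group_neutral_margin:
            return make(Classification.NEUTRAL, 0, "odd_group_margin")
    if b >= need:
        return make(Classification.BARRIER, -b, "barrier_majority")
    if e >= need:
        return make(Classification.ENABLER, e, "enabler_majority")
    if policy.indeterminate_handling == "error":
        raise IndeterminateSummaryError(
            f"({summary.group_id}, {summary.theme_id}): relevant but no rule fires "
            f"(E={e}, B={b}, N={n}, size={summary.group_size})"
        )
    return make(Classification.INDETERMINATE, 0, "indeterminate")


def score_original_group(
    summary: GroupThemeSummary,
    cfirf_class: GroupScore | None = None,
    mode: str = "paper_operationalised",
    policy: ScoringPolicy | None = None,
) -> int:
    """Original-CFIR score (-2..+2) for one cell.

    ``paper_operationalised`` (default) maps the CFIR-f classification to
    -2 (barrier), +2 (enabler) or 0, reproducing the published totals in
    which sub-threshold cells score 0.

    ``rubric`` follows the original rubric literally: every theme is
    included, the strictly larger of the enabler/barrier counts sets the
    sign, magnitude 2 when at least two endorsers of that valence were
    substantive, else 1, and a tie (including no mentions) scores 0.
    """
    if mode not in ORIGINAL_MODES:
        raise ValueError(f"mode must be one of {ORIGINAL_MODES}, got {mode!r}")
    if mode == "paper_operationalised":
        if cfirf_class is None:
            cfirf_class = classify_group_cfirf(summary, policy)
        return {
            Classification.BARRIER: -2,
            Classification.ENABLER: 2,
        }.get(cfirf_class.classification, 0)

    e, b = summary.enabler_count, summary.barrier_count
    if e == b:
        return 0
    if e > b:
        substantive, sign = summary.enabler_substantive, 1
    else:
        substantive, sign = summary.barrier_substantive, -1
    if substantive is None:
        raise ValueError(
            "rubric mode needs salience tallies; build summaries with summarise() "
            "or set enabler_substantive/barrier_substantive (missing salience "
            "defaults to 'substantive')"
        )
    return sign * (2 if substantive >= 2 else 1)


def _overall_class(total_cfirf: int) -> str:
    if total_cfirf < 0:
        return Classification.BARRIER
    if total_cfirf > 0:
        return Classification.ENABLER
    return Classification.NEUTRAL


def score_study(
    dataset: CodedDataset,
    policy: ScoringPolicy | None = None,
    mode: str = "paper_operationalised",
) -> list[ThemeResult]:
    """Score every theme of a dataset under both systems.

    Returns one result per declared theme, in declaration order, with
    per-group scores, CFIR-f and original totals, and the overall class
    (the sign of the CFIR-f total).
    """
    policy = policy or ScoringPolicy()
    summaries = {(s.group_id, s.theme_id): s for s in summarise(dataset)}
    results: list[ThemeResult] = []
    for theme in dataset.themes:
        scores: list[GroupScore] = []
        mentioners = 0
        for group in dataset.groups:
            s = summaries[(group.group_id, theme.theme_id)]
            mentioners += s.mention_count
            gs = classify_group_cfirf(s, policy)
            original = score_original_group(s, gs, mode=mode, policy=policy)
            scores.append(
                GroupScore(
                    group_id=gs.group_id,
                    theme_id=gs.theme_id,
                    classification=gs.classification,
                    cfirf_score=gs.cfirf_score,
                    original_score=original,
                    reasons=gs.reasons,
                )
            )
        total_cfirf = sum(gs.cfirf_score for gs in scores)
        total_original = sum(gs.original_score or 0 for gs in scores)
        results.append(
            ThemeResult(
                theme_id=theme.theme_id,
                label=theme.label,
                group_scores=tuple(scores),
                total_cfirf=total_cfirf,
                total_original=total_original,
                overall_class=_overall_class(total_cfirf),
                mentioner_total=mentioners,
            )
        )
    return results


def rank_themes(results: Sequence[ThemeResult]) -> RankedThemes:
    """Split results into barrier/neutral/enabler sections, ranked by total."""
    barriers = [r for r in results if r.overall_class == Classification.BARRIER]
    neutral = [r for r in results if r.overall_class == Classification.NEUTRAL]
    enablers = [r for r in results if r.overall_class == Classification.ENABLER]
    barriers.sort(key=lambda r: (r.total_cfirf, -r.mentioner_total, r.label))
    enablers.sort(key=lambda r: (-r.total_cfirf, -r.mentioner_total, r.label))
    neutral.sort(key=lambda r: (-r.mentioner_total, r.label))
    return RankedThemes(tuple(barriers), tuple(neutral), tuple(enablers))


def concurrent_validity(
    results_cfirf: Sequence[ThemeResult],
    results_original: Sequence[ThemeResult] | None = None,
) -> ValidityReport:
    """Compare theme classes under the CFIR-f and original scorers.

    The CFIR-f class is the sign of the CFIR-f total; the original class
    is the sign of the original total.  Passing a single result list
    compares its two total columns.
    """
    if results_original is None:
        results_original = results_cfirf
    themes_f = {r.theme_id for r in results_cfirf}
    themes_o = {r.theme_id for r in results_original}
    if themes_f != themes_o:
        raise ValueError(
            "result lists cover different themes: "
            f"only-cfirf={sorted(themes_f - themes_o)}, "
            f"only-original={sorted(themes_o - themes_f)}"
        )
    original_by_theme = {r.theme_id: r for r in results_original}
    pairs: dict[str, tuple[str, str]] = {}
    for r in results_cfirf:
        o = original_by_theme[r.theme_id]
        pairs[r.theme_id] = (_overall_class(r.total_cfirf), _overall_class(o.total_original))
    agreement = sum(1 for a, b in pairs.values() if a == b)
    return ValidityReport(
        pairs=pairs,
        agreement_count=agreement,
        n_themes=len(pairs),
        tallies_cfirf=dict(Counter(a for a, _ in pairs.values())),
        tallies_original=dict(Counter(b for _, b in pairs.values())),
    )


# ---------------------------------------------------------------------------
# Export


def results_to_frame(results: Sequence[ThemeResult]) -> pd.DataFrame:
    """Wide table: one row per theme with per-group classes and both scores."""
    rows = []
    for r in results:
        row: dict[str, object] = {"theme_id": r.theme_id, "label": r.label}
        for gs in r.group_scores:
            row[f"{gs.group_id}_class"] = gs.classification
            row[f"{gs.group_id}_cfirf"] = gs.cfirf_score
            row[f"{gs.group_id}_original"] = gs.original_score
        row["total_cfirf"] = r.total_cfirf
        row["total_original"] = r.total_original
        row["overall_class"] = r.overall_class
        row["n_mentioners"] = r.mentioner_total
        rows.append(row)
    return pd.DataFrame(rows)


def results_to_json(results: Sequence[ThemeResult]) -> dict:
    ranked = rank_themes(results)
    def theme_obj(r: ThemeResult) -> dict:
        return {
            "theme_id": r.theme_id,
            "label": r.label,
            "total_cfirf": r.total_cfirf,
            "total_original": r.total_original,
            "overall_class": r.overall_class,
            "n_mentioners": r.mentioner_total,
            "groups": [
                {
                    "group_id": gs.group_id,
                    "classification": gs.classification,
                    "cfirf_score": gs.cfirf_score,
                    "original_score": gs.original_score,
                    "reasons": list(gs.reasons),
                }
                for gs in r.group_scores
            ],
        }

    return {
        "barriers": [theme_obj(r) for r in ranked.barriers],
        "neutral": [theme_obj(r) for r in ranked.neutral],
        "enablers": [theme_obj(r) for r in ranked.enablers],
    }


def ranked_to_markdown(results: Sequence[ThemeResult]) -> str:
    """Render the ranked report as a small Markdown document."""
    ranked = rank_themes(results)
    lines: list[str] = []
    for title, section in (
        ("Barriers", ranked.barriers),
        ("Neither enablers nor barriers", ranked.neutral),
        ("Enablers", ranked.enablers),
    ):
        lines.append(f"## {title}")
        lines.append("")
        if not section:
            lines.append("_none_")
        else:
            lines.append("| theme | CFIR-f total | original total | n |")
            lines.append("| --- | ---: | ---: | ---: |")
            for r in section:
                lines.append(
                    f"| {r.label} | {r.total_cfirf:+d} | {r.total_original:+d} "
                    f"| {r.mentioner_total} |"
                )
        lines.append("")
    return "\n".join(lines)
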