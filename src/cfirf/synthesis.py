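"""Fixtures and data synthesis.

Published frequency-scoring studies report per-(group, theme) outcomes —
a barrier or enabler endorser count, a neutral verdict, or exclusion as
below the relevance threshold — plus each theme's total mentioner count,
but not the underlying participant-level codes.  This module ships the
study fixture as such a constraint table and reconstructs a
participant-level dataset consistent with it, so the whole scoring
pipeline can be exercised end to end.

Reconstruction guarantees (for any feasible constraint set and seed):

* barrier/enabler cells reproduce their endorser counts exactly;
* neutral cells get an all-neutral mention block at or above the
  relevance threshold (the minimal split satisfying neutrality
  criterion 1);
* below-threshold cells stay strictly below the threshold;
* per-theme mention counts sum to the published total, extra mentioners
  being added neutral-first;
* re-scoring the reconstruction reproduces every cell status and score.

Barrier/enabler endorser counts are uniquely determined by the scores;
only the neutral and below-threshold cells are under-determined, and a
seeded stream picks among the admissible completions.

A separate generator draws fully random coded datasets (per-participant
mention Bernoulli and a valence mixture) for property testing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .model import (
    CodedDataset,
    EndorsementRecord,
    Group,
    ScoringPolicy,
    Theme,
    Valence,
    _bundled_data,
)

__all__ = [
    "CellStatus",
    "CellConstraint",
    "SummaryConstraint",
    "SynthesisConfig",
    "InfeasibleConstraintError",
    "table2_fixture",
    "bundled_mapping_path",
    "reconstruct_participants",
    "generate_synthetic",
]


class InfeasibleConstraintError(ValueError):
    """No participant-level dataset can satisfy the constraint table."""


class CellStatus(str, Enum):
    BELOW_THRESHOLD = "below_threshold"
    NEUTRAL = "neutral"
    BARRIER = "barrier"
    ENABLER = "enabler"


@dataclass(frozen=True)
class CellConstraint:
    """Published outcome of one (group, theme) cell.

    ``endorsers`` is the barrier/enabler endorser count (the magnitude of
    the published cell score); it is None for the other statuses.
    """

    status: CellStatus
    endorsers: int | None = None

    def __post_init__(self) -> None:
        scored = self.status in (CellStatus.BARRIER, CellStatus.ENABLER)
        if scored and (self.endorsers is None or self.endorsers <= 0):
            raise ValueError(f"{self.status.value} cell needs a positive endorser count")
        if not scored and self.endorsers is not None:
            raise ValueError(f"{self.status.value} cell must not carry an endorser count")


@dataclass(frozen=True)
class SummaryConstraint:
    """A full constraint table: cells per (theme, group) plus theme totals."""

    groups: tuple[Group, ...]
    themes: tuple[Theme, ...]
    totals: Mapping[str, int]  # theme_id -> total mentioners across groups
    cells: Mapping[tuple[str, str], CellConstraint]  # (theme_id, group_id)

    def cell(self, theme_id: str, group_id: str) -> CellConstraint:
        return self.cells[(theme_id, group_id)]

    def validate(self, policy: ScoringPolicy | None = None) -> None:
        """Check per-cell arithmetic and per-theme feasibility."""
        policy = policy or ScoringPolicy()
        for theme in self.themes:
            if theme.theme_id not in self.totals:
                raise InfeasibleConstraintError(f"no total for theme {theme.theme_id!r}")
            for group in self.groups:
                key = (theme.theme_id, group.group_id)
                if key not in self.cells:
                    raise InfeasibleConstraintError(f"no cell constraint for {key}")
                cell = self.cells[key]
                need = policy.min_mentions(group.size)
                if cell.status in (CellStatus.BARRIER, CellStatus.ENABLER):
                    if cell.endorsers > group.size:
                        raise InfeasibleConstraintError(
                            f"{key}: {cell.endorsers} endorsers exceed group size {group.size}"
                        )
                    if cell.endorsers < need:
                        raise InfeasibleConstraintError(
                            f"{key}: {cell.endorsers} endorsers below the relevance "
                            f"minimum {need} of {group.size}"
                        )
            lo, hi = self.theme_bounds(theme.theme_id, policy)
            n = self.totals[theme.theme_id]
            if not (lo <= n <= hi):
                raise InfeasibleConstraintError(
                    f"theme {theme.theme_id!r}: total mentioners {n} outside the "
                    f"feasible range [{lo}, {hi}] implied by the cell statuses"
                )

    def cell_bounds(
        self, theme_id: str, group_id: str, policy: ScoringPolicy | None = None
    ) -> tuple[int, int]:
        """Admissible mention-count range for one cell.

        Scored cells may carry extra *neutral* mentioners as long as the
        neutral count stays below the threshold (else neutrality
        criterion 1 would fire); neutral cells span threshold..size;
        below-threshold cells span 0..threshold-1.
        """
        policy = policy or ScoringPolicy()
        group = next(g for g in self.groups if g.group_id == group_id)
        need = policy.min_mentions(group.size)
        cell = self.cell(theme_id, group_id)
        if cell.status in (CellStatus.BARRIER, CellStatus.ENABLER):
            return cell.endorsers, min(group.size, cell.endorsers + need - 1)
        if cell.status is CellStatus.NEUTRAL:
            return need, group.size
        return 0, need - 1

    def theme_bounds(
        self, theme_id: str, policy: ScoringPolicy | None = None
    ) -> tuple[int, int]:
        lo = hi = 0
        for group in self.groups:
            a, b = self.cell_bounds(theme_id, group.group_id, policy)
            lo += a
            hi += b
        return lo, hi


# ---------------------------------------------------------------------------
# Bundled study fixture


def bundled_mapping_path():
    """Path-like handle on the bundled dual-rater construct-mapping table."""
    return _bundled_data("table3_mapping.csv")


def table2_fixture() -> SummaryConstraint:
    """The study's published summary table as a constraint set.

    Sixteen themes over four stakeholder groups (sizes 5, 7, 6, 6), each
    cell transcribed as below-threshold, neutral, or a barrier/enabler
    endorser count, plus each theme's total mentioner count.
    """
    groups: list[Group] = []
    with _bundled_data("groups.csv").open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            groups.append(Group(row["group_id"], row["label"], int(row["size"])))
    themes: list[Theme] = []
    totals: dict[str, int] = {}
    with _bundled_data("table2_themes.csv").open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            themes.append(Theme(row["theme_id"], row["label"]))
            totals[row["theme_id"]] = int(row["n_total"])
    cells: dict[tuple[str, str], CellConstraint] = {}
    with _bundled_data("table2_cells.csv").open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            endorsers = int(row["endorsers"]) if row["endorsers"].strip() else None
            cells[(row["theme_id"], row["group_id"])] = CellConstraint(
                CellStatus(row["status"]), endorsers
            )
    constraint = SummaryConstraint(
        groups=tuple(groups), themes=tuple(themes), totals=dict(totals), cells=cells
    )
    constraint.validate()
    return constraint


# ---------------------------------------------------------------------------
# Constraint-based reconstruction


def _allocate_extras(
    constraint: SummaryConstraint,
    theme_id: str,
    policy: ScoringPolicy,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Choose a mention count per group summing to the theme total.

    Start every cell at its minimum, then spread the remaining mentions
    neutral-first: neutral cells, then scored cells (whose extras are
    neutral mentioners), then below-threshold cells.  Seeded shuffling
    breaks the remaining slack.
    """
    priority = {
        CellStatus.NEUTRAL: 0,
        CellStatus.BARRIER: 1,
        CellStatus.ENABLER: 1,
        CellStatus.BELOW_THRESHOLD: 2,
    }
    bounds = {
        g.group_id: constraint.cell_bounds(theme_id, g.group_id, policy)
        for g in constraint.groups
    }
    mentions = {gid: lo for gid, (lo, _) in bounds.items()}
    deficit = constraint.totals[theme_id] - sum(mentions.values())
    if deficit < 0 or constraint.totals[theme_id] > sum(hi for _, hi in bounds.values()):
        lo, hi = constraint.theme_bounds(theme_id, policy)
        raise InfeasibleConstraintError(
            f"theme {theme_id!r}: total {constraint.totals[theme_id]} outside [{lo}, {hi}]"
        )
    for level in (0, 1, 2):
        gids = [
            g.group_id
            for g in constraint.groups
            if priority[constraint.cell(theme_id, g.group_id).status] == level
        ]
        order = list(rng.permutation(gids)) if gids else []
        while deficit > 0 and any(mentions[g] < bounds[g][1] for g in order):
            for gid in order:
                if deficit == 0:
                    break
                if mentions[gid] < bounds[gid][1]:
                    mentions[gid] += 1
                    deficit -= 1
        if deficit == 0:
            break
    return mentions


def reconstruct_participants(
    constraint: SummaryConstraint,
    seed: int,
    policy: ScoringPolicy | None = None,
) -> CodedDataset:
    """Build a participant-level dataset consistent with a constraint table.

    Deterministic for a fixed seed.  The result is a stand-in consistent
    with the published summary, not a recovery of the study's real codes:
    which participants mention which themes, and the composition of
    neutral and below-threshold cells, are free choices drawn from one
    seeded stream.
    """
    policy = policy or ScoringPolicy()
    constraint.validate(policy)
    rng = np.random.default_rng(seed)
    participants = {
        g.group_id: [f"{g.group_id}-p{j + 1:02d}" for j in range(g.size)]
        for g in constraint.groups
    }
    records: list[EndorsementRecord] = []
    for theme in constraint.themes:
        mentions = _allocate_extras(constraint, theme.theme_id, policy, rng)
        for group in constraint.groups:
            m = mentions[group.group_id]
            if m == 0:
                continue
            cell = constraint.cell(theme.theme_id, group.group_id)
            if cell.status is CellStatus.BARRIER:
                valences = [Valence.BARRIER] * cell.endorsers
            elif cell.status is CellStatus.ENABLER:
                valences = [Valence.ENABLER] * cell.endorsers
            else:
                valences = []
            valences += [Valence.NEUTRAL] * (m - len(valences))
            chosen = rng.choice(participants[group.group_id], size=m, replace=False)
            for pid, valence in zip(chosen, valences):
                records.append(
                    EndorsementRecord(str(pid), group.group_id, theme.theme_id, valence)
                )
    return CodedDataset(list(constraint.groups), list(constraint.themes), records)


# ---------------------------------------------------------------------------
# Random synthetic datasets


@dataclass(frozen=True)
class SynthesisConfig:
    """Parameters of the random coded-dataset generator.

    Defaults emulate the study design: four stakeholder groups of sizes
    5, 7, 6 and 6, sixteen themes, a mention probability giving roughly
    the observed mention density, and a valence mixture
    (enabler, barrier, neutral) leaning barrier-and-neutral as the study
    interviews did.
    """

    group_sizes: tuple[int, ...] = (5, 7, 6, 6)
    n_themes: int = 16
    mention_prob: float = 0.5
    valence_mix: tuple[float, float, float] = (0.25, 0.35, 0.40)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes or any(s <= 0 for s in self.group_sizes):
            raise ValueError("group_sizes must be positive integers")
        if self.n_themes < 0:
            raise ValueError("n_themes must be >= 0")
        if not (0.0 <= self.mention_prob <= 1.0):
            raise ValueError(f"mention_prob must be in [0, 1], got {self.mention_prob}")
        if len(self.valence_mix) != 3 or any(p < 0 for p in self.valence_mix):
            raise ValueError("valence_mix needs three non-negative probabilities")
        if abs(sum(self.valence_mix) - 1.0) > 1e-9:
            raise ValueError(f"valence_mix must sum to 1, got {sum(self.valence_mix)}")


def generate_synthetic(config: SynthesisConfig) -> CodedDataset:
    """Draw a random coded dataset; bit-stable for a fixed seed.

    Each participant mentions each theme independently with
    ``mention_prob`` and, when mentioning, draws a valence from
    ``valence_mix`` (enabler, barrier, neutral).
    """
    rng = np.random.default_rng(config.seed)
    groups = [
        Group(f"g{i + 1}", f"Group {i + 1}", size)
        for i, size in enumerate(config.group_sizes)
    ]
    themes = [Theme(f"t{i + 1}", f"Theme {i + 1}") for i in range(config.n_themes)]
    valence_values = (Valence.ENABLER, Valence.BARRIER, Valence.NEUTRAL)
    records: list[EndorsementRecord] = []
    for group in groups:
        for j in range(group.size):
            pid = f"{group.group_id}-p{j + 1:02d}"
            for theme in themes:
                if rng.random() < config.mention_prob:
                    valence = valence_values[
                        int(rng.choice(3, p=list(config.valence_mix)))
                    ]
                    records.append(
                        EndorsementRecord(pid, group.group_id, theme.theme_id, valence)
                    )
    return CodedDataset(groups, themes, records)
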