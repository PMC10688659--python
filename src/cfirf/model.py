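"""Core data model for frequency-based theme scoring.

Coded qualitative data arrives as long-format endorsement records: one row
per participant x theme, carrying the participant's stakeholder group and
the valence of their stance (enabler, barrier or neutral).  Group sizes are
declared separately because participants who never mentioned a theme still
count in the relevance denominator.

This module holds the domain types, their validation, delimited-text I/O,
the per-(group, theme) tally, and the bundled CFIR 2.0 construct taxonomy.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Valence",
    "Salience",
    "EndorsementRecord",
    "Group",
    "Theme",
    "ScoringPolicy",
    "CodedDataset",
    "GroupThemeSummary",
    "DatasetError",
    "TaxonomyError",
    "CFIRConstruct",
    "CFIRTaxonomy",
    "read_groups",
    "read_themes",
    "read_endorsements",
    "write_groups",
    "write_themes",
    "write_endorsements",
    "summarise",
    "summaries_to_frame",
    "load_taxonomy",
]


class DatasetError(ValueError):
    """Raised when coded endorsement data violates a structural invariant."""


class TaxonomyError(ValueError):
    """Raised when a construct taxonomy file is malformed."""


class Valence(str, Enum):
    """A participant's coded stance on a theme."""

    ENABLER = "enabler"
    BARRIER = "barrier"
    NEUTRAL = "neutral"

    @classmethod
    def parse(cls, raw: str) -> "Valence":
        try:
            return cls(str(raw).strip().lower())
        except ValueError:
            allowed = ", ".join(v.value for v in cls)
            raise DatasetError(
                f"unknown valence {raw!r}; expected one of: {allowed}"
            ) from None


class Salience(str, Enum):
    """Depth of discussion; only the original-CFIR rubric uses this.

    A theme touched on without explicit examples is ``in_passing``; one
    discussed with concrete examples is ``substantive``.  Missing salience
    defaults to substantive.
    """

    IN_PASSING = "in_passing"
    SUBSTANTIVE = "substantive"

    @classmethod
    def parse(cls, raw: str) -> "Salience":
        text = str(raw).strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls(text)
        except ValueError:
            allowed = ", ".join(s.value for s in cls)
            raise DatasetError(
                f"unknown salience {raw!r}; expected one of: {allowed}"
            ) from None


@dataclass(frozen=True)
class EndorsementRecord:
    """One participant's dominant stance on one theme."""

    participant_id: str
    group_id: str
    theme_id: str
    valence: Valence
    salience: Salience = Salience.SUBSTANTIVE


@dataclass(frozen=True)
class Group:
    """A stakeholder group with its declared total size.

    ``size`` is the number of interviewees in the group, including those
    who never mentioned a given theme; it is the denominator of the
    relevance filter.
    """

    group_id: str
    label: str
    size: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise DatasetError(
                f"group {self.group_id!r}: size must be positive, got {self.size}"
            )


@dataclass(frozen=True)
class Theme:
    theme_id: str
    label: str


@dataclass(frozen=True)
class ScoringPolicy:
    """Tunable rule parameters for classification.

    relevance_threshold
        Minimum fraction of the group that must mention a theme for it to
        be scored at all; the comparison is inclusive, so exactly 50% of
        an even-sized group (3 of 6) passes with the default 0.5.
    odd_group_neutral_margin
        For odd-sized groups, an enabler/barrier difference up to this
        margin counts as balanced (hence neutral), provided both valences
        are present when ``neutrality_requires_both_valences`` is set.
    indeterminate_handling
        What to do when a theme is relevant but no classification rule
        fires: score it 0 (``neutral_zero``) or raise (``error``).
    """

    relevance_threshold: float = 0.5
    odd_group_neutral_margin: int = 1
    neutrality_requires_both_valences: bool = True
    indeterminate_handling: str = "neutral_zero"

    def __post_init__(self) -> None:
        if not (0.0 < self.relevance_threshold <= 1.0):
            raise ValueError(
                f"relevance_threshold must be in (0, 1], got {self.relevance_threshold}"
            )
        if self.odd_group_neutral_margin < 0:
            raise ValueError("odd_group_neutral_margin must be >= 0")
        if self.indeterminate_handling not in ("neutral_zero", "error"):
            raise ValueError(
                "indeterminate_handling must be 'neutral_zero' or 'error', "
                f"got {self.indeterminate_handling!r}"
            )

    def min_mentions(self, group_size: int) -> int:
        """Smallest mention count meeting the relevance threshold."""
        if group_size <= 0:
            raise ValueError(f"group size must be positive, got {group_size}")
        import math

        return max(1, math.ceil(group_size * self.relevance_threshold - 1e-9))


@dataclass(frozen=True)
class GroupThemeSummary:
    """Per-(group, theme) endorsement tallies.

    ``enabler_substantive`` / ``barrier_substantive`` count endorsers of
    each valence whose salience was substantive; they stay ``None`` when
    the summary was built without salience information.
    """

    group_id: str
    theme_id: str
    group_size: int
    mention_count: int
    enabler_count: int
    barrier_count: int
    neutral_count: int
    enabler_substantive: int | None = None
    barrier_substantive: int | None = None

    def __post_init__(self) -> None:
        for name in ("mention_count", "enabler_count", "barrier_count", "neutral_count"):
            if getattr(self, name) < 0:
                raise DatasetError(f"{name} must be >= 0")
        if self.group_size <= 0:
            raise DatasetError("group_size must be positive")
        total = self.enabler_count + self.barrier_count + self.neutral_count
        if total != self.mention_count:
            raise DatasetError(
                f"({self.group_id}, {self.theme_id}): valence counts sum to {total} "
                f"but mention_count is {self.mention_count}"
            )
        if self.mention_count > self.group_size:
            raise DatasetError(
                f"({self.group_id}, {self.theme_id}): {self.mention_count} mentions "
                f"exceed group size {self.group_size}"
            )


@dataclass
class CodedDataset:
    """A validated collection of groups, themes and endorsement records."""

    groups: list[Group]
    themes: list[Theme]
    records: list[EndorsementRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        group_ids = [g.group_id for g in self.groups]
        if len(set(group_ids)) != len(group_ids):
            raise DatasetError("duplicate group_id in group declarations")
        theme_ids = [t.theme_id for t in self.themes]
        if len(set(theme_ids)) != len(theme_ids):
            raise DatasetError("duplicate theme_id in theme declarations")
        groups = {g.group_id: g for g in self.groups}
        themes = set(theme_ids)

        participant_group: dict[str, str] = {}
        seen: dict[tuple[str, str], EndorsementRecord] = {}
        per_cell_participants: dict[tuple[str, str], set[str]] = {}
        for i, rec in enumerate(self.records):
            where = f"record {i + 1}"
            if rec.group_id not in groups:
                raise DatasetError(f"{where}: undeclared group {rec.group_id!r}")
            if rec.theme_id not in themes:
                raise DatasetError(f"{where}: undeclared theme {rec.theme_id!r}")
            prev_group = participant_group.setdefault(rec.participant_id, rec.group_id)
            if prev_group != rec.group_id:
                raise DatasetError(
                    f"{where}: participant {rec.participant_id!r} appears in groups "
                    f"{prev_group!r} and {rec.group_id!r}"
                )
            key = (rec.participant_id, rec.theme_id)
            if key in seen:
                raise DatasetError(
                    f"{where}: duplicate endorsement for participant "
                    f"{rec.participant_id!r} on theme {rec.theme_id!r} "
                    f"(valences {seen[key].valence.value!r} and {rec.valence.value!r}); "
                    "resolve to one dominant valence upstream"
                )
            seen[key] = rec
            per_cell_participants.setdefault((rec.group_id, rec.theme_id), set()).add(
                rec.participant_id
            )

        # declared size must cover everyone observed in the group
        by_group: dict[str, set[str]] = {}
        for pid, gid in participant_group.items():
            by_group.setdefault(gid, set()).add(pid)
        for gid, pids in by_group.items():
            if len(pids) > groups[gid].size:
                raise DatasetError(
                    f"group {gid!r}: {len(pids)} distinct participants exceed "
                    f"declared size {groups[gid].size}"
                )

    def group(self, group_id: str) -> Group:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def theme(self, theme_id: str) -> Theme:
        for t in self.themes:
            if t.theme_id == theme_id:
                return t
        raise KeyError(theme_id)


# ---------------------------------------------------------------------------
# Tallying


def summarise(dataset: CodedDataset) -> list[GroupThemeSummary]:
    """Tally endorsements per (group, theme), including zero-count cells.

    A pure count over the records: permuting record order never changes
    any summary.  Substantive-salience tallies are always filled because
    salience defaults to substantive on every record.
    """
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for g in dataset.groups:
        for t in dataset.themes:
            counts[(g.group_id, t.theme_id)] = {
                "enabler": 0,
                "barrier": 0,
                "neutral": 0,
                "enabler_sub": 0,
                "barrier_sub": 0,
            }
    for rec in dataset.records:
        cell = counts[(rec.group_id, rec.theme_id)]
        cell[rec.valence.value] += 1
        if rec.salience is Salience.SUBSTANTIVE and rec.valence is not Valence.NEUTRAL:
            cell[f"{rec.valence.value}_sub"] += 1

    out: list[GroupThemeSummary] = []
    for g in dataset.groups:
        for t in dataset.themes:
            cell = counts[(g.group_id, t.theme_id)]
            out.append(
                GroupThemeSummary(
                    group_id=g.group_id,
                    theme_id=t.theme_id,
                    group_size=g.size,
                    mention_count=cell["enabler"] + cell["barrier"] + cell["neutral"],
                    enabler_count=cell["enabler"],
                    barrier_count=cell["barrier"],
                    neutral_count=cell["neutral"],
                    enabler_substantive=cell["enabler_sub"],
                    barrier_substantive=cell["barrier_sub"],
                )
            )
    return out


def summaries_to_frame(summaries: Iterable[GroupThemeSummary]) -> pd.DataFrame:
    rows = [
        {
            "group_id": s.group_id,
            "theme_id": s.theme_id,
            "group_size": s.group_size,
            "mention_count": s.mention_count,
            "enabler_count": s.enabler_count,
            "barrier_count": s.barrier_count,
            "neutral_count": s.neutral_count,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Delimited-text I/O

_REQUIRED_ENDORSEMENT_COLS = ("participant_id", "group_id", "theme_id", "valence")


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_groups(path: str | Path, *, delimiter: str = ",") -> list[Group]:
    """Read group declarations from CSV columns group_id, label, size."""
    df = _read_table(path, delimiter)
    for col in ("group_id", "label", "size"):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing column {col!r}")
    groups = []
    for i, row in df.iterrows():
        try:
            size = int(row["size"])
        except ValueError:
            raise DatasetError(
                f"{path} row {i + 2}: size {row['size']!r} is not an integer"
            ) from None
        groups.append(Group(row["group_id"].strip(), row["label"].strip(), size))
    return groups


def read_themes(path: str | Path, *, delimiter: str = ",") -> list[Theme]:
    """Read theme declarations from CSV columns theme_id, label."""
    df = _read_table(path, delimiter)
    for col in ("theme_id", "label"):
        if col not in df.columns:
            raise DatasetError(f"{path}: missing column {col!r}")
    return [Theme(row["theme_id"].strip(), row["label"].strip()) for _, row in df.iterrows()]


def read_endorsements(
    path: str | Path,
    groups: Sequence[Group],
    *,
    themes: Sequence[Theme] | None = None,
    delimiter: str = ",",
) -> CodedDataset:
    """Read long-format endorsement records and build a validated dataset.

    Columns: participant_id, group_id, theme_id, valence and optionally
    salience.  Valence and salience strings are case-insensitive.  When no
    theme table is supplied, themes are inferred from the records in order
    of first appearance with the id doubling as label.  Errors name the
    offending file row (header is row 1).
    """
    df = _read_table(path, delimiter)
    for col in _REQUIRED_ENDORSEMENT_COLS:
        if col not in df.columns:
            raise DatasetError(f"{path}: missing column {col!r}")
    has_salience = "salience" in df.columns

    records: list[EndorsementRecord] = []
    seen: dict[tuple[str, str], tuple[int, Valence]] = {}
    participant_group: dict[str, tuple[int, str]] = {}
    for i, row in df.iterrows():
        rownum = int(i) + 2
        try:
            valence = Valence.parse(row["valence"])
            salience = (
                Salience.parse(row["salience"])
                if has_salience and row["salience"].strip()
                else Salience.SUBSTANTIVE
            )
        except DatasetError as exc:
            raise DatasetError(f"{path} row {rownum}: {exc}") from None
        pid = row["participant_id"].strip()
        gid = row["group_id"].strip()
        tid = row["theme_id"].strip()
        if pid in participant_group and participant_group[pid][1] != gid:
            first_row, first_gid = participant_group[pid]
            raise DatasetError(
                f"{path} row {rownum}: participant {pid!r} declared in group {gid!r} "
                f"but row {first_row} put them in group {first_gid!r}"
            )
        participant_group.setdefault(pid, (rownum, gid))
        key = (pid, tid)
        if key in seen:
            first_row, first_val = seen[key]
            raise DatasetError(
                f"{path} row {rownum}: participant {pid!r} already endorsed theme "
                f"{tid!r} at row {first_row} (valences {first_val.value!r} and "
                f"{valence.value!r}); one dominant valence per participant per theme"
            )
        seen[key] = (rownum, valence)
        records.append(EndorsementRecord(pid, gid, tid, valence, salience))

    if themes is None:
        order: list[str] = []
        for rec in records:
            if rec.theme_id not in order:
                order.append(rec.theme_id)
        themes = [Theme(t, t) for t in order]
    try:
        return CodedDataset(list(groups), list(themes), records)
    except DatasetError as exc:
        raise DatasetError(f"{path}: {exc}") from None


def write_groups(groups: Sequence[Group], path: str | Path) -> None:
    pd.DataFrame(
        [{"group_id": g.group_id, "label": g.label, "size": g.size} for g in groups]
    ).to_csv(path, index=False)


def write_themes(themes: Sequence[Theme], path: str | Path) -> None:
    pd.DataFrame(
        [{"theme_id": t.theme_id, "label": t.label} for t in themes]
    ).to_csv(path, index=False)


def write_endorsements(dataset: CodedDataset, path: str | Path) -> None:
    """Write records back to the standard endorsement CSV."""
    pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group_id": r.group_id,
                "theme_id": r.theme_id,
                "valence": r.valence.value,
                "salience": r.salience.value,
            }
            for r in dataset.records
        ],
        columns=["participant_id", "group_id", "theme_id", "valence", "salience"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CFIR 2.0 construct taxonomy

_DOMAINS = (
    "innovation",
    "outer_setting",
    "inner_setting",
    "individuals",
    "implementation_process",
)


def _norm_code(code: str) -> str:
    return "".join(ch for ch in str(code) if ch.isalnum()).casefold()


def _norm_name(name: str) -> str:
    text = str(name).casefold().replace("&", " and ")
    text = re.sub(r"[^a-z0-9]+", " ", text)
    # tolerate the two common spellings
    text = text.replace("centeredness", "centredness")
    return " ".join(text.split())


@dataclass(frozen=True)
class CFIRConstruct:
    """One named element of the CFIR 2.0 taxonomy."""

    code: str
    name: str
    domain: str
    definition: str = ""

    def __post_init__(self) -> None:
        if self.domain not in _DOMAINS:
            raise TaxonomyError(
                f"construct {self.code!r}: unknown domain {self.domain!r}; "
                f"expected one of {', '.join(_DOMAINS)}"
            )


class CFIRTaxonomy:
    """A construct taxonomy with code and normalised-name lookup.

    The bundled CFIR 2.0 file has exactly 67 constructs in 5 domains;
    user-supplied taxonomies may be any size.
    """

    def __init__(self, constructs: Sequence[CFIRConstruct], version: str = "custom"):
        self.constructs = list(constructs)
        self.version = version
        self._by_code: dict[str, CFIRConstruct] = {}
        self._by_name: dict[str, list[CFIRConstruct]] = {}
        for c in self.constructs:
            key = _norm_code(c.code)
            if key in self._by_code:
                raise TaxonomyError(f"duplicate construct code {c.code!r}")
            self._by_code[key] = c
            self._by_name.setdefault(_norm_name(c.name), []).append(c)

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    @property
    def domains(self) -> list[str]:
        seen: list[str] = []
        for c in self.constructs:
            if c.domain not in seen:
                seen.append(c.domain)
        return seen

    def get_by_code(self, code: str) -> CFIRConstruct | None:
        return self._by_code.get(_norm_code(code))

    def find_by_name(self, name: str) -> list[CFIRConstruct]:
        return list(self._by_name.get(_norm_name(name), []))

    def lookup(self, key: str) -> CFIRConstruct:
        """Resolve a construct by code or by unique normalised name."""
        hit = self.get_by_code(key)
        if hit is not None:
            return hit
        candidates = self.find_by_name(key)
        if len(candidates) == 1:
            return candidates[0]
        if len(candidates) > 1:
            codes = ", ".join(c.code for c in candidates)
            raise KeyError(
                f"construct name {key!r} is ambiguous (codes {codes}); use a code"
            )
        raise KeyError(f"no construct with code or name {key!r}")

    def suggest(self, key: str, n: int = 3) -> list[str]:
        """Nearest codes/names for an unresolvable key (for error messages)."""
        import difflib

        pool = [c.code for c in self.constructs] + [c.name for c in self.constructs]
        return difflib.get_close_matches(str(key), pool, n=n, cutoff=0.4)


def _bundled_data(name: str):
    return resources.files("cfirf").joinpath("data").joinpath(name)


def load_taxonomy(path: str | Path | None = None) -> CFIRTaxonomy:
    """Load a construct taxonomy from YAML/JSON, or the bundled CFIR 2.0 list.

    The file is a mapping with a ``version`` label and a ``constructs``
    list of ``{code, name, domain, definition}`` entries (a bare list is
    also accepted).
    """
    if path is None:
        text = _bundled_data("cfir2_taxonomy.yaml").read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    payload = yaml.safe_load(text)
    if isinstance(payload, dict):
        version = str(payload.get("version", "custom"))
        entries = payload.get("constructs")
    else:
        version = "custom"
        entries = payload
    if not isinstance(entries, list):
        raise TaxonomyError("taxonomy file must contain a list of constructs")
    constructs = []
    for entry in entries:
        try:
            constructs.append(
                CFIRConstruct(
                    code=str(entry["code"]),
                    name=str(entry["name"]),
                    domain=str(entry["domain"]),
                    definition=str(entry.get("definition", "")),
                )
            )
        except KeyError as exc:
            raise TaxonomyError(f"construct entry missing field {exc}") from None
    tax = CFIRTaxonomy(constructs, version=version)
    if path is None and (len(tax) != 67 or len(tax.domains) != 5):
        raise TaxonomyError(
            f"bundled CFIR 2.0 taxonomy corrupt: {len(tax)} constructs, "
            f"{len(tax.domains)} domains"
        )
    return tax
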