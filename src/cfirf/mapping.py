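"""Theme-to-construct mapping, dual-rater consensus, and coverage.

Two researchers independently map each scored theme onto the construct
taxonomy; their assignment sets are reconciled (programmatically by set
intersection or union, or by loading a hand-adjudicated table), and the
consensus is summarised as a coverage report: how many taxonomy
constructs received at least one theme, and which did not.

Agreement between raters is measured per theme as Jaccard set overlap
|A ∩ B| / |A ∪ B| (1.0 when both sets are empty), pooled over themes for
the overall figure.  Assignments are sets, so a simple overlap is the
natural statistic rather than a chance-corrected kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import CFIRTaxonomy, DatasetError

__all__ = [
    "MappingRecord",
    "ConsensusMapping",
    "AgreementReport",
    "CoverageReport",
    "MappingError",
    "read_mapping_records",
    "build_consensus",
    "rater_agreement",
    "coverage",
    "coverage_to_frame",
]

CONSENSUS_STRATEGIES = ("intersection", "union", "manual_file")


class MappingError(ValueError):
    """Raised for unresolvable construct codes or malformed mapping tables."""


@dataclass(frozen=True)
class MappingRecord:
    """One rater's assignment of one construct to one theme."""

    theme_id: str
    rater_id: str
    construct_code: str


@dataclass(frozen=True)
class ConsensusMapping:
    """Consensus construct sets per theme, with the rater originals kept."""

    consensus: Mapping[str, frozenset[str]]
    by_rater: Mapping[str, Mapping[str, frozenset[str]]]
    strategy: str

    def all_codes(self) -> frozenset[str]:
        out: set[str] = set()
        for codes in self.consensus.values():
            out |= codes
        return frozenset(out)


@dataclass(frozen=True)
class AgreementReport:
    per_theme: Mapping[str, float]
    overall: float
    rater_ids: tuple[str, str]


@dataclass(frozen=True)
class CoverageReport:
    """Which taxonomy constructs the consensus mapping reaches.

    ``mapped_construct_count + len(unmapped)`` always equals the taxonomy
    size: the two lists partition the taxonomy exactly.
    """

    mapped_construct_count: int
    mapped_codes: frozenset[str]
    unmapped: tuple[tuple[str, str], ...]  # (code, name)
    per_domain: Mapping[str, tuple[int, int]]  # domain -> (mapped, total)
    taxonomy_size: int


def _resolve(key: str, taxonomy: CFIRTaxonomy, where: str) -> str:
    try:
        return taxonomy.lookup(key).code
    except KeyError:
        hints = taxonomy.suggest(key)
        hint = f"; did you mean: {', '.join(hints)}?" if hints else ""
        raise MappingError(f"{where}: unresolvable construct {key!r}{hint}") from None


def read_mapping_records(
    path: str | Path,
    taxonomy: CFIRTaxonomy,
    *,
    delimiter: str = ",",
) -> list[MappingRecord]:
    """Read a mapping CSV and resolve every construct against the taxonomy.

    Columns: theme_id, rater_id and construct_code and/or construct_name.
    The code is resolved first; a missing or unresolvable code falls back
    to the name.  Exact duplicate assignments collapse to one record.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("theme_id", "rater_id"):
        if col not in df.columns:
            raise MappingError(f"{path}: missing column {col!r}")
    if "construct_code" not in df.columns and "construct_name" not in df.columns:
        raise MappingError(f"{path}: need construct_code or construct_name column")

    records: list[MappingRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for i, row in df.iterrows():
        where = f"{path} row {int(i) + 2}"
        code_raw = row.get("construct_code", "").strip()
        name_raw = row.get("construct_name", "").strip()
        if code_raw and taxonomy.get_by_code(code_raw) is not None:
            code = taxonomy.get_by_code(code_raw).code
        elif name_raw:
            code = _resolve(name_raw, taxonomy, where)
        elif code_raw:
            code = _resolve(code_raw, taxonomy, where)
        else:
            raise MappingError(f"{where}: empty construct reference")
        key = (row["theme_id"].strip(), row["rater_id"].strip(), code)
        if key in seen:
            continue
        seen.add(key)
        records.append(MappingRecord(*key))
    return records


def _sets_by_rater(
    records: Iterable[MappingRecord],
) -> dict[str, dict[str, set[str]]]:
    out: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        out.setdefault(rec.rater_id, {}).setdefault(rec.theme_id, set()).add(
            rec.construct_code
        )
    return out


def build_consensus(
    records: Sequence[MappingRecord],
    strategy: str = "intersection",
    *,
    taxonomy: CFIRTaxonomy | None = None,
    manual_path: str | Path | None = None,
) -> ConsensusMapping:
    """Reconcile rater assignment sets into one consensus set per theme.

    ``intersection`` and ``union`` are programmatic stand-ins for the
    discussion step of a real consensus meeting; ``manual_file`` loads an
    adjudicated table (columns theme_id, construct_code/construct_name;
    requires ``taxonomy``) and keeps the rater originals alongside it.
    """
    if strategy not in CONSENSUS_STRATEGIES:
        raise ValueError(f"strategy must be one of {CONSENSUS_STRATEGIES}, got {strategy!r}")
    by_rater_sets = _sets_by_rater(records)
    themes: set[str] = set()
    for theme_map in by_rater_sets.values():
        themes |= set(theme_map)

    consensus: dict[str, frozenset[str]] = {}
    if strategy == "manual_file":
        if manual_path is None or taxonomy is None:
            raise ValueError("manual_file strategy needs manual_path and taxonomy")
        df = pd.read_csv(manual_path, dtype=str, keep_default_na=False)
        df.columns = [c.strip().lower() for c in df.columns]
        adjudicated: dict[str, set[str]] = {}
        for i, row in df.iterrows():
            where = f"{manual_path} row {int(i) + 2}"
            key = row.get("construct_code", "").strip() or row.get(
                "construct_name", ""
            ).strip()
            code = _resolve(key, taxonomy, where)
            adjudicated.setdefault(row["theme_id"].strip(), set()).add(code)
        themes |= set(adjudicated)
        consensus = {t: frozenset(adjudicated.get(t, set())) for t in themes}
    else:
        for theme in themes:
            sets = [
                frozenset(theme_map.get(theme, set()))
                for theme_map in by_rater_sets.values()
            ]
            if strategy == "intersection":
                agreed = frozenset.intersection(*sets) if sets else frozenset()
            else:
                agreed = frozenset().union(*sets)
            consensus[theme] = agreed

    frozen_raters = {
        rater: {t: frozenset(codes) for t, codes in theme_map.items()}
        for rater, theme_map in by_rater_sets.items()
    }
    return ConsensusMapping(consensus=consensus, by_rater=frozen_raters, strategy=strategy)


def rater_agreement(records: Sequence[MappingRecord]) -> AgreementReport:
    """Jaccard overlap of the two raters' construct sets, per theme and pooled.

    The pooled overall figure is sum of intersections over sum of unions
    across themes (1.0 when every union is empty).  Exactly two raters
    are required.
    """
    by_rater = _sets_by_rater(records)
    if len(by_rater) != 2:
        raise ValueError(
            f"rater_agreement needs exactly two raters, got {sorted(by_rater)}"
        )
    (ra, sets_a), (rb, sets_b) = sorted(by_rater.items())
    themes = sorted(set(sets_a) | set(sets_b))
    per_theme: dict[str, float] = {}
    inter_total = union_total = 0
    for theme in themes:
        a = sets_a.get(theme, set())
        b = sets_b.get(theme, set())
        inter, union = len(a & b), len(a | b)
        per_theme[theme] = 1.0 if union == 0 else inter / union
        inter_total += inter
        union_total += union
    overall = 1.0 if union_total == 0 else inter_total / union_total
    return AgreementReport(per_theme=per_theme, overall=overall, rater_ids=(ra, rb))


def coverage(consensus: ConsensusMapping, taxonomy: CFIRTaxonomy) -> CoverageReport:
    """Count taxonomy constructs reached by at least one theme.

    Idempotent under duplicated mapping rows and invariant to theme and
    rater order: only the set of distinct consensus codes matters.
    """
    mapped = consensus.all_codes()
    for code in sorted(mapped):
        if taxonomy.get_by_code(code) is None:
            raise MappingError(f"consensus code {code!r} not in taxonomy")
    unmapped = tuple(
        (c.code, c.name) for c in taxonomy if c.code not in mapped
    )
    per_domain: dict[str, list[int]] = {}
    for c in taxonomy:
        tally = per_domain.setdefault(c.domain, [0, 0])
        tally[1] += 1
        if c.code in mapped:
            tally[0] += 1
    return CoverageReport(
        mapped_construct_count=len(mapped),
        mapped_codes=mapped,
        unmapped=unmapped,
        per_domain={d: (m, t) for d, (m, t) in per_domain.items()},
        taxonomy_size=len(taxonomy),
    )


def coverage_to_frame(report: CoverageReport, taxonomy: CFIRTaxonomy) -> pd.DataFrame:
    """One row per taxonomy construct with its mapped flag."""
    return pd.DataFrame(
        [
            {
                "code": c.code,
                "name": c.name,
                "domain": c.domain,
                "mapped": c.code in report.mapped_codes,
            }
            for c in taxonomy
        ]
    )
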