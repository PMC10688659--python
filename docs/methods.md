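# Methods

## The model

`cfirf` operates on counts, not transcripts. The upstream qualitative
work — interviewing, thematic analysis, and coding each participant's
stance on each theme — is a human activity whose output this package
consumes as long-format endorsement records. Each record carries one
*dominant* valence per participant per theme (enabler, barrier or
neutral); a participant coded with conflicting valences for the same
theme is a validation error, not something the package resolves, because
reconciling within-participant mixed talk is a judgement that belongs to
the coder. Group sizes are declared rather than inferred from the
records: participants who never mentioned a theme still count in the
relevance denominator.

Classification is a fixed decision sequence per (group, theme) cell,
documented in `scoring.classify_group_cfirf`. Two orderings matter and
are deliberate:

* **Neutrality precedes the majority rules.** A cell with an equal
  enabler/barrier split is neutral even when one valence alone clears
  the 50% threshold; testing the majorities first would misclassify the
  equal-split case that motivates neutrality criterion 2.
* **The threshold is inclusive.** "Fewer than 50% … excluded" makes
  exactly 50% (3 of 6) included; the comparison is
  `mentions ≥ ⌈size × threshold⌉`.

Cells that are relevant but match no rule (e.g. E=0, B=2, N=1 in a group
of five: no neutral majority, unequal valences, no majority valence) are
*indeterminate*. They score 0 by default — the conservative reading of
"not strongly identified" — and the policy can escalate them to an error
for datasets where they should not occur.

The odd-group one-person margin (criterion 2) applies only when both
valences are present, reflecting its rationale of participants
discussing a theme "as both an enabler and barrier"; exact equality
(including 0 = 0) always qualifies. Both behaviours are policy switches.
Note the margin can override a clear 4-vs-3 majority in a group of
seven; the rules imply this and the package follows them. The
majority-neutral criterion denominates over the group size, not over
mentioners, consistent with every other rule; a sensitivity analysis can
rerun with a custom policy if the other reading is wanted.

The overall class of a theme is the sign of its CFIR-f total. No other
rule is needed: a mixed-sign profile nets out, and the published results
contain no theme where the two readings diverge.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `relevance_threshold` | 0.5 | fraction of group size a theme must reach to be scored; inclusive |
| `odd_group_neutral_margin` | 1 | max E−B difference treated as balanced in odd groups |
| `neutrality_requires_both_valences` | true | the margin applies only when min(E, B) ≥ 1 |
| `indeterminate_handling` | `neutral_zero` | score 0 or raise on unmatched relevant cells |

The original-CFIR comparator ships two modes because the classic rubric
says "all themes included" while published comparison tables show 0 for
sub-threshold groups. `paper_operationalised` (default) maps the CFIR-f
classification to −2/0/+2 and reproduces such tables;
`rubric` follows the classic wording literally, using salience
(in-passing vs substantive) for the ±1/±2 magnitude. Salience defaults
to substantive when absent, so the rubric mode degrades gracefully for
datasets coded without it.

Ranking orders barriers most-negative-first and enablers
most-positive-first; ties break on larger total mentioner count, then
label lexicographically. The tie-break is an invention of this package —
the reference study has no ties — chosen only to make reports
deterministic.

Rater agreement is Jaccard set overlap (|A∩B|/|A∪B| per theme, pooled
across themes, 1.0 when both sets are empty), not a chance-corrected
kappa: assignments are construct *sets* per theme and the statistic
mirrors how agreement percentages are quoted for such tables. With
identical rater sets, per-assignment and per-theme readings coincide at
1.0.

## Fixtures and reconstruction

The bundled fixture transcribes the study's published summary: 16 themes
× 4 groups (sizes 5, 7, 6, 6), each cell being below-threshold, neutral,
or a barrier/enabler endorser count, plus each theme's total mentioner
count. Published mapping tables contain a few typographical code slips
(a code whose letter belongs to another domain's construct, a
legacy construct name); the curated mapping fixture treats the construct
*name* as authoritative, resolves the code against the taxonomy, and
records a provenance note on every corrected row. The four
characteristic constructs of the Individuals domain (Need, Capability,
Opportunity, Motivation) are lettered 4J–4M as a continuation of the
role constructs, matching the table they were transcribed from.

Participant-level codes are not published, so `reconstruct_participants`
builds a dataset consistent with the summary by constraint satisfaction.
Barrier/enabler cells are fully determined (the score *is* the endorser
count); freedom exists only in neutral cells, below-threshold cells, and
the allocation of surplus mentioners needed to reach each theme's total.
The resolution policy is: neutral cells start at the minimal satisfying
split (all-neutral at exactly the threshold, i.e. neutrality criterion 1);
surplus mentions are distributed neutral-first — neutral cells up to the
group size, then scored cells (as neutral co-mentioners, capped strictly
below the threshold so criterion 1 cannot fire), then below-threshold
cells (capped strictly below the threshold). A single seeded generator
shuffles the remaining slack; no global random state is touched.
Feasibility is checked per theme against the interval arithmetic of
these caps and violations are reported with the violated bound. By
construction, re-scoring any reconstruction reproduces every cell status
and score — the round-trip property the test suite exercises across 100
seeds, half on the study fixture and half on randomly drawn feasible
constraint sets.

The reconstruction is explicitly a stand-in: it reproduces the summary
statistics, not the study's real codes. Several cells admit many
completions (e.g. a theme whose total exceeds its endorser counts can
place the surplus mentions in more than one group) and none is
privileged; every admissible completion scores identically, which is why
the acceptance numbers are seed-invariant.

## The synthetic generator

`generate_synthetic` draws fully random coded datasets: each participant
mentions each theme independently with `mention_prob` and, when
mentioning, draws a valence from the (enabler, barrier, neutral)
mixture. Defaults mirror the study design — groups of 5, 7, 6 and 6,
sixteen themes, mention probability 0.5 (the study's 184 mentions over
384 participant×theme pairs ≈ 0.48), and a mixture of (0.25, 0.35, 0.40)
reflecting the barrier-and-neutral tilt of the published tallies. The
generator emulates none of the structure of real interview data — no
within-participant correlation across themes, no group-level valence
consensus, no salience variation — so tests built on it demonstrate rule
correctness and pipeline robustness, not realism of any downstream
inference.

## Numerical and design notes

* All scoring is integer arithmetic; the only float is the threshold
  fraction, compared via `ceil(size × threshold)` with a 1e-9 guard
  against representation error at exact multiples.
* Valence and salience strings are case-insensitive on read and stored
  canonically; construct names normalise punctuation, `&`/`and`, and the
  -centredness/-centeredness spelling variants.
* File errors (unknown valence, conflicting duplicates, participants in
  two groups, tallies exceeding a declared group size, unresolvable
  construct codes) are raised with the offending row number; unresolvable
  constructs include nearest-match suggestions.
* The command-line layer is a thin wrapper: every command is
  deterministic given its flags and seed, and logs record the policy,
  mode, seed and package version.

## Problem sizes

Everything here is desk-scale: the study fixture is 24 participants × 16
themes, exhaustive rule verification enumerates all ≤8-person cells
(about 10⁴ combinations), and the round-trip suite covers 100 seeds. The
full test suite and the acceptance script each complete in seconds on a
single CPU.

## Limitations

* The package scores counts; it cannot detect coding problems upstream
  (e.g. a coder systematically splitting one theme into two).
* Indeterminate cells are a real gap in the rule set for small groups;
  they are surfaced in `reasons` rather than silently absorbed.
* The relevance cutoff is a single frequency criterion; alternative
  hybrid cutoffs (e.g. always retaining each group's most-cited theme)
  are not implemented.
* Consensus strategies (intersection/union) are programmatic stand-ins
  for a human adjudication meeting; `manual_file` is the faithful route
  when an adjudicated table exists.
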