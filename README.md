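# cfirf — frequency-based scoring of implementation themes

`cfirf` is a small toolkit for implementation-science evaluators who code
semi-structured interviews against the Consolidated Framework for
Implementation Research (CFIR). Given long-format coded data — one record
per participant × theme, with the participant's stakeholder group and the
valence of their stance — it classifies and ranks themes as enablers or
barriers using the frequency-based CFIR-f rules, emulates the classic
±2 CFIR scoring for concurrent-validity comparison, and maps themes onto
the 67-construct CFIR 2.0 taxonomy with dual-rater consensus and coverage
reporting.

## The scoring rules

For each stakeholder group *g* (size *n_g*) and theme *t*, let *E*, *B*
and *N* be the numbers of group participants coded as endorsing the theme
as an enabler, a barrier, or in neutral terms. The CFIR-f evaluates, in
order (first match wins):

1. **Relevance filter.** If fewer than 50% of the group mentioned the
   theme (*E + B + N < ⌈n_g/2⌉*, threshold inclusive), it is excluded for
   that group and scores 0.
2. **Neutrality.** The theme is neutral (score 0) if a threshold-sized
   majority discussed it neutrally (*N ≥ ⌈n_g/2⌉*), or if enabler and
   barrier endorsements balance: *E = B*, or *|E − B| ≤ 1* in an
   odd-sized group where both valences occur.
3. **Majority valence.** A barrier (enabler) majority *B ≥ ⌈n_g/2⌉*
   (*E ≥ ⌈n_g/2⌉*) classifies the theme as a barrier (enabler) for the
   group, scored **−B** (**+E**) — the score *is* the endorser count.
4. **Total.** Group scores sum to the theme total; its sign classifies
   the theme overall and the totals rank the themes for action.

The original-CFIR comparator assigns each group −2/0/+2 from the same
classification (the operationalisation that reproduces published totals),
or, in `rubric` mode, follows the classic rubric literally: all themes
included, ±1 for themes discussed only in passing, ±2 once two endorsers
of the dominant valence gave substantive examples.

## Worked example

The bundled study fixture is the published summary table of a process
evaluation of two family-based therapies (FFT-CW and MST-CAN) in NSW,
Australia: 16 themes over four expert groups of sizes 5, 7, 6 and 6.
Because the publication reports per-cell outcomes rather than raw codes,
`cfirf` reconstructs a consistent participant-level dataset by constraint
satisfaction and scores it end to end:

```bash
cfirf simulate --fixture table2 --seed 3 --out data/
cfirf score --endorsements data/endorsements.csv --groups data/groups.csv \
            --themes data/themes.csv --compare --out report/
```

```
6 barriers, 3 enablers, 7 neutral themes (16 total)
concurrent validity: 16/16 themes classified identically by both scorers
```

`report/ranked_themes.csv` lists the themes with both scoring columns;
the top barrier ("Technical, logistical and referral challenges") totals
−11 under the CFIR-f and −6 under the original scoring, and the top
enabler ("Nature and structure of FFT-CW program") totals +7 and +4 —
the frequency-based column spreads an ordinal ±2 scale into a ranked,
continuous one. Construct coverage:

```bash
cfirf fixtures --out fixtures/
cfirf coverage --mapping fixtures/table3_mapping.csv --out report/
```

```
65/67 constructs mapped; 2 unmapped
rater agreement: 1.00
```

The two unreached CFIR 2.0 constructs are Innovation Trialability and
Critical Incidents.

The same pipeline runs on your own data: any endorsement CSV
(`participant_id,group_id,theme_id,valence[,salience]`) plus a group
declaration CSV (`group_id,label,size`), and a mapping CSV
(`theme_id,rater_id,construct_code`) against the bundled or a custom
taxonomy. `cfirf simulate` without `--fixture` draws random coded
datasets for testing.

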