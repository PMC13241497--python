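# actidiary

Agreement analysis between wearable-accelerometer physical-activity
intensity and diary-based energy expenditure, on 15-minute epochs.

Tri-axial acceleration from body-worn sensors (ankle, wrist, lower back) is
converted to ENMO (Euclidean Norm Minus One: vector magnitude minus 1 g,
low-pass filtered, truncated at zero), averaged over 5-second epochs and
then over the 36 fifteen-minute slots of the 09:00–18:00 daytime window.
In parallel, activity-diary entries are mapped to MET values through a
Compendium-style lookup keyed on activity label and self-reported intensity
(mild/moderate/vigorous); overlapping entries yield three slot-level MET
series (low = min, average = duration-weighted mean, high = max).  After
day- and participant-level quality control, both arms are min-max
normalized (per sensor for ENMO, jointly across levels for MET), a single
multiplicative correction factor per sensor × MET level is fitted by
Nelder-Mead on the group-mean profiles under the model `MET = α × ENMO`,
and per-participant RMSE distributions quantify agreement, optionally
stratified by tremor severity (sum of the three MDS-UPDRS III tremor items,
≤ 1 vs > 1).

Because no real cohort ships with the package, a synthetic cohort generator
(`actidiary.synthetic`) produces the full input bundle — 5-second ENMO
epoch series or raw 100 Hz CSVs, diaries, a matching Compendium table and
participant metadata — from a latent activity schedule with known
ground-truth correction factors, so the entire pipeline is testable offline.

## Layout

| module | role |
|---|---|
| `actidiary.signal_enmo` | raw acceleration → ENMO → 5-s epochs → 15-min slots |
| `actidiary.diary_met` | diary parsing, Compendium MET lookup, slot MET levels |
| `actidiary.cohort_qc` | inclusion rules (window span, 9 h sensor time, ≥ 4 simultaneous slots, ≥ 3 days) and panel assembly |
| `actidiary.agreement` | min-max normalization, α fit (Nelder-Mead + closed-form oracle), subject RMSE, summaries, tremor split |
| `actidiary.synthetic` | synthetic cohort generator with ground truth |
| `actidiary.pipeline` / `actidiary.cli` | orchestration, reports, `actidiary` CLI |

## CLI

```bash
# write a synthetic bundle (CSV files + ground_truth.json)
actidiary simulate --out bundle/ --seed 7

# run the full analysis
cat > cfg.yaml <<EOF
input_dir: bundle
output_dir: results_run
EOF
actidiary run --config cfg.yaml
```

Subcommands `enmo | mets | qc | fit | report` run the pipeline up to the
named stage.  Exit codes: 0 ok, 2 config error, 3 data error, 4 empty
cohort.  Outputs include `enmo_slots.csv`, `met_slots.csv`,
`qc_report.csv`, `scaling_results.csv` (the nine fitted α values),
`subject_rmse.csv`, `summary_table1.csv` (median/min/max per sensor ×
level), `tremor_summary.csv`, `group_profiles.csv`, `run_summary.json`
and the resolved configuration.

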