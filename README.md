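# notesieve

Weakly supervised relevance filtering for clinical note corpora.

`notesieve` builds "silver standard" training labels from diagnosis-code and
temporal heuristics over an EHR encounter timeline, trains lightweight
classifiers on five text representations, calibrates the decision threshold
on a small gold-annotated split, and evaluates with confusion-matrix metrics
and bootstrap confidence intervals. A synthetic cohort generator makes the
entire pipeline runnable end to end without any real patient data.

## Components

| module | what it does |
| --- | --- |
| `notesieve.corpus_model` | EHR data model, JSONL note-corpus I/O, exact-match diagnosis-code sets (default: the 11 ICD-9-CM + 11 ICD-10-CM COPD codes) |
| `notesieve.silver_labeling` | silver pools (code-positive / never-coded negative / pre-diagnosis negative / excluded), balanced training subsets, gold validation/test split |
| `notesieve.representations` | bag of words, TF-IDF, paragraph-vector document embeddings (DM + DBOW with hierarchical softmax, pure numpy), gzip compression features and normalized compression distance, lexicon concept vectors with negation-aware assertion values |
| `notesieve.classification` | RF / gradient-boosted trees / kNN / NCD-kNN, grid search with stratified 5-fold CV selecting on positive-class F1 |
| `notesieve.evaluation` | confusion metrics, 0.0–1.0 threshold sweep and selection, percentile bootstrap CIs, code-heuristic baseline evaluation |
| `notesieve.synthetic_data` | deterministic synthetic cohorts with configurable coding noise and topic-mixture note text, plus gold-annotation sampling |
| `notesieve.pipeline` / `notesieve.cli` | one-config-one-report experiment orchestration and the `notesieve` CLI |

## CLI quick start

```bash
# 1. simulate a cohort (notes.jsonl, truth.jsonl, gold.csv)
notesieve simulate --out-dir cohort/ --seed 1 --gold-n 170

# 2. assign silver pools
notesieve label --corpus cohort/notes.jsonl --out cohort/pools.jsonl

# 3. full experiment from a config file
cat > config.json <<'EOF'
{"corpus_path": "cohort/notes.jsonl", "gold_path": "cohort/gold.csv",
 "representation": "emb", "family": "rf", "grid": "fast", "n_pos": 150}
EOF
notesieve run --config config.json --report report.json

# 4. compare several runs (same gold set)
notesieve compare --reports report_bow.json --reports report_emb.json
```

Stage-level subcommands (`subset`, `featurize`, `train`, `calibrate`,
`evaluate`) operate on the intermediate files, so each step can be run and
inspected standalone. Reports embed all seeds, input digests and library
versions; identical config + seeds reproduce a byte-identical report.

## Notes

- The corpus format is UTF-8 line-delimited JSON, one object per note with
  denormalized encounter fields (`note_id, patient_id, encounter_id, date,
  note_type, text, codes`).
- Code matching is exact set membership after uppercasing and dot removal —
  no prefix expansion. Custom code sets load from JSON.
- A toy 40-term respiratory lexicon and negation-trigger list ship with the
  package for the concept representation.
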