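# gtaccess

Identify access to germline genetic testing in unstructured clinical notes.

The pipeline mirrors a production quality-informatics workflow for breast
cancer care review:

1. **Snippet extraction** — case-insensitive keyword matching over
   whitespace-tokenized notes; each hit yields a context window of 100
   words on either side of the phrase; overlapping windows merge; all of a
   patient's snippets are consolidated chronologically into one cleaned
   document.
2. **Triage** — deterministic pre-classifier rules: zero snippets ⇒
   automatic negative; ≥ 20 snippets or > 4,000 words ⇒ automatic
   positive; everything else goes to the classifier.
3. **Classification** — a zero-shot answer-template prompt (four review
   categories: Yes / No / Not applicable / Not sure) rendered around the
   consolidated document and sent to a pluggable backend
   (`ClassifierBackend`). Responses are parsed by regular expression from
   the `ANSWER: <category>` scaffold and consolidated to a binary outcome
   (positive = access identified; No / Not applicable / Not sure ⇒
   negative). Deterministic mock backends (scripted replay and a
   phrase-rule heuristic) are first-class; a minimal OpenAI-compatible
   HTTP adapter is included for real model servers but never required.
4. **Evaluation** — confusion matrices; accuracy / precision / recall /
   F1 with explicit undefined markers; percentile-bootstrap confidence
   intervals (default 5,000 iterations); a development/testing split
   stratified by category and reviewer-disagreement flag; agreed-case
   subsets; per-reviewer accuracies; Pearson chi-square comparisons.
5. **Synthetic corpus** — a calibrated generator producing labeled
   cohorts with the real corpus's statistical shape (median 42 notes per
   patient, 4 snippets per patient, ~200-word snippets, ~800-word merged
   documents, 21.5% zero-snippet patients who are always binary-negative,
   13.5% high-burden patients who are always positive, 14.5%
   initial-reviewer disagreement with adjudicated consensus), so the full
   pipeline runs, tests, and demos without any protected data.

## CLI

All stages are subcommands of `gtaccess`; artifacts are plain text (JSONL
for note/snippet/document streams, CSV for tables, JSON for reports), and
every run writes a `manifest.json` with the effective configuration and
seeds so reruns are byte-identical.

```bash
# generate a 200-patient synthetic cohort
gtaccess simulate --n 200 --seed 1 --out runs/demo

# full pipeline over it (heuristic mock backend by default)
gtaccess run-all --corpus runs/demo/corpus.jsonl --labels runs/demo/labels.csv \
    --out runs/demo

# or stage by stage
gtaccess extract  --corpus runs/demo/corpus.jsonl --out runs/demo
gtaccess triage   --documents runs/demo/documents.jsonl --out runs/demo
gtaccess classify --documents runs/demo/documents.jsonl --triage runs/demo/triage.csv \
    --backend heuristic --out runs/demo
gtaccess evaluate --predictions runs/demo/predictions.csv --labels runs/demo/labels.csv \
    --out runs/demo
```

Backends: `heuristic` (phrase rules with an optional seeded error rate),
`scripted:<responses.json>` (deterministic replay keyed by prompt or
prompt SHA-256), `endpoint:<base_url>#<model>` (OpenAI-compatible chat
endpoint). The keyword lexicon (`--lexicon`) and prompt template
(`--template`, `{{document}}` placeholder) are editable text assets;
packaged defaults live in `src/gtaccess/assets/`. Generation settings
default to temperature 0.75 and top_p 0.9. A YAML config file
(`--config`) can pre-set any option; explicit flags win.

## Layout

```
src/gtaccess/
  corpus.py     synthetic cohort generator (labels, strata, reviews)
  snippets.py   tokenization, keyword hits, windows, consolidation, cleaning
  triage.py     pre-classifier routing rules
  classify.py   prompt templates, backends, response parsing, consolidation
  evaluate.py   metrics, bootstrap CIs, splits, reviewer stats, chi-square
  io.py         JSONL/CSV/JSON readers and writers
  cli.py        click CLI binding the stages
  assets/       default lexicon and prompt templates
tests/          pytest suite (unit, property, acceptance)
scripts/        acceptance.py
```
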