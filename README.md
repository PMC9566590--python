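# sensits

Rule-based integrated-testing-strategy (ITS) engine for skin sensitization.
It converts DPRA peptide-depletion values, h-CLAT outcomes and an in silico
prediction score into additive points (0–3 + 0–3 + 0–1), maps the total onto
a hazard call (total ≥ 2 → sensitizer) and a GHS potency subcategory
(6–7 → 1A, 2–5 → 1B, rest NC), and treats any missing or out-of-domain
component as inconclusive. It also provides:

- a **two-out-of-three consensus** hazard call over the three key-event
  assays (DPRA, KeratinoSens, h-CLAT);
- a **mixture rule**: a mixture is a sensitizer if any ingredient above
  0.1% w/w (strict) is a sensitizer, inconclusive if an above-threshold
  ingredient is inconclusive, otherwise a non-sensitizer;
- **evaluation metrics**: accuracy, sensitivity, specificity, balanced
  accuracy, coverage, and per-subcategory potency rates, with inconclusive
  predictions excluded from every metric except coverage;
- **deterministic synthetic fixtures**: label-first panels and mixtures for
  testing every scoring branch without external data.

The DPRA/h-CLAT point bin edges are not unique to this implementation —
they follow the OECD Guideline No. 497 tables and are fully user-overridable
through the YAML scoring configuration.

## CLI

```sh
sensits config --show-defaults                 # print scoring thresholds
sensits simulate --n 64 --seed 7 --out panel.csv \
    --mixtures 10 --mixtures-out mix.csv       # synthetic inputs
sensits score --panel panel.csv --out scores.csv
sensits twoofthree --panel panel.csv --out calls.csv
sensits mixture --mixtures mix.csv --panel panel.csv --out mixcalls.csv
sensits evaluate --panel panel.csv --out report.json --table report.txt
```

Panels are delimited text (`--sep` to override the comma) with columns
`id, smiles, dpra_cys, dpra_lys, dpra_coelution, hclat_outcome, hclat_mit,
insilico_score, insilico_in_domain, ref_hazard, ref_potency, dpra_call,
ks_call, hclat_call`; empty cells and `NA` both mean missing. Mixture
tables are long format: `mixture_id, ingredient_id, concentration_pct`.
Any entry of the scoring configuration can be overridden via
`--config my.yaml`.

## Layout

- `src/sensits/its_engine.py` — point scoring and hazard/potency calls
- `src/sensits/two_of_three.py` — consensus hazard call
- `src/sensits/mixtures.py` — concentration-threshold mixture rule
- `src/sensits/evaluation.py` — confusion counts, metrics, reports
- `src/sensits/fixtures.py` — deterministic synthetic panels/mixtures
- `src/sensits/io.py`, `src/sensits/cli.py` — tabular IO and the CLI
- `src/sensits/config.py` — all thresholds, YAML (de)serialization
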