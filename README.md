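# panmethyl

Selectivity profiling of pan-methyllysine antibodies and lysine-methylome
analytics, as a tested, reusable Python pipeline.

The package models a lysine-oriented peptide library (K-OPL: 114 sets of
9-mers around a fixed central methyl-lysine), processes microarray
fluorescence tables into replicate-averaged, normalized selectivity
profiles, summarizes antibody pan-ness as a 0–100 pan metric score, converts
profiles into position-specific scoring matrices (PSSMs) for proteome-wide
scanning, and runs the downstream methylome analytics: site calling from
PSM tables, enrichment-strategy overlap (upset-style), novelty accounting
against a reference PTM catalog, log2 frequency-ratio motif analysis, PTM
crosstalk proximity, enrichment-efficiency QC, and compartment-enrichment
statistics via the two-proportion Z-test. A synthetic-data module generates
every input with known ground truth, so the whole chain is testable offline.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (design constants,
closed forms, oracle equivalence, parameter recovery, round trips, bias
detection, Z-test oracle).

## CLI

Everything is exposed through the `panmethyl` command:

```bash
# library manifest (114 sets for one methyl state)
panmethyl kopl-design --state me2 --out manifest.tsv

# array processing -> selectivity profile -> pan score -> PSSM -> proteome scan
panmethyl simulate array --seed 1 --state me2 --out scan.tsv
panmethyl array-profile --scan scan.tsv --manifest manifest.tsv --out profile.tsv
panmethyl pan-score --profile profile.tsv --state me2
panmethyl pssm-build --profile profile.tsv --state me2 --out pssm.tsv
panmethyl simulate proteome --seed 2 --out proteome.fasta
panmethyl pssm-scan --pssm pssm.tsv --fasta proteome.fasta --out ranked.tsv

# methylome analytics
panmethyl simulate methylome --seed 3 --fasta proteome.fasta \
    --out-sites truth_sites.tsv --out-reference reference.tsv
panmethyl simulate psms --seed 3 --fasta proteome.fasta --out psms.tsv
panmethyl sites-call --psms psms.tsv --fasta proteome.fasta --out sites.tsv
panmethyl sites-overlap --sites sites.tsv --out overlap.tsv
panmethyl sites-novelty --sites sites.tsv --reference reference.tsv --out novelty.tsv
panmethyl motif --sites sites.tsv --fasta proteome.fasta --out motif.tsv
panmethyl crosstalk --sites sites.tsv --reference reference.tsv --window 9 --out prox.tsv
panmethyl qc --psms psms.tsv --out qc.tsv
panmethyl localization --compartments comp.tsv --methylome sites.tsv \
    --proteome all_accessions.txt --out localization.tsv
```

All table formats are plain TSV; see module docstrings in `src/panmethyl/`
for column contracts.

## Layout

| module | role |
| --- | --- |
| `kopl_design` | combinatorial model of the 114-set library, set membership |
| `array_processing` | replicate averaging, global / per-column normalization, profile building |
| `selectivity_metrics` | pan metric, PSSM construction, 7-mer scoring, proteome ranking |
| `methylome_catalog` | localization filtering, site calling, overlap, novelty, merge, per-protein stats |
| `motif_analysis` | frequency tables and log2(dataset/background) motif matrices |
| `crosstalk` | PTM proximity profiles and methyl/phospho peptide co-occurrence |
| `enrichment_qc` | per-run methyl-PSM percentages and dominant-state checks |
| `localization_stats` | compartment assignment and two-proportion Z-tests |
| `synthetic_data` | seeded generators for proteomes, array scans, site catalogs, PSM tables |
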