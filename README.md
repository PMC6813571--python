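# ubcphen

Rule-based derivation of urinary-bladder-cancer (UBC) prognostic phenotypes
from coded hospital-episode records, plus a candidate-SNP replication
analysis over the derived outcomes — packaged with a synthetic-data
generator so the whole pipeline runs and is testable without any
access-controlled data.

## What it does

1. **Cohort selection** (`ubcphen.cohort`) — eligibility from cancer-registry
   diagnosis codes (ICD-9/ICD-10 bladder sites), ICD-O histology and a
   precomputed ancestry flag; earliest matching diagnosis becomes the index
   date.
2. **Phenotyping** (`ubcphen.phenotyping`) — a temporal rule engine over
   OPCS4 procedure codes: bladder-tumour resections, gaps in intravesical
   chemotherapy sequences, and examinations followed by interventions define
   tumour events; events are merged when closer than the independence
   window; recurrence counts exclude the primary-treatment block;
   progression requires a radical intervention (cystectomy/radiotherapy)
   within the follow-up window of a post-baseline event; early radical
   intervention marks a muscle-invasive baseline tumour (MIBC vs NMIBC).
3. **Outcomes** (`ubcphen.outcomes`) — overall and UBC-specific death from
   death-registry causes; continuous and dichotomised age at diagnosis.
4. **Statistics** (`ubcphen.assoc`) — self-implemented allele-dosage
   logistic (IRLS) and linear regressions with sex adjustment, Wald
   intervals, an approximate Bayes factor with a Normal prior on the
   log-odds effect, imputation INFO scores, allele frequencies from
   (fractional) genotype-count triples, dosage LD r², and per-outcome-family
   Bonferroni thresholds.
5. **Replication runs** (`ubcphen.pipeline`) — per catalog entry the
   analysis is restricted to the originally-reported subgroup (UBC/NMIBC/
   MIBC), annotated with nominal and Bonferroni significance and direction
   consistency (with allele harmonisation and palindromic-variant flagging),
   plus a descriptive cohort table.
6. **Synthetic data** (`ubcphen.simulate`) — cohorts with configurable
   event rates whose episode streams are written through the inverse of the
   phenotyping rules (ground truth is recovered exactly), and genotypes
   drawn under an additive per-allele odds-ratio model with optional
   imputation noise.

## CLI

```sh
# synthetic cohort with one effect variant
ubcphen simulate --out sim/ --seed 5 --n-patients 1534 \
    --variant "rs1:A:G:0.3:1.4:recurrence"

# derive phenotypes for eligible patients
ubcphen phenotype --registry sim/diagnoses.csv --episodes sim/episodes.csv \
    --deaths sim/deaths.csv --samples sim/samples.csv --out phenotypes.csv

# replicate a SNP catalog (VCF with DS/GP, or wide dosage CSV)
ubcphen associate --registry sim/diagnoses.csv --episodes sim/episodes.csv \
    --deaths sim/deaths.csv --samples sim/samples.csv \
    --genotypes sim/genotypes.vcf --catalog catalog.csv \
    --out report.csv --descriptive-out descriptive.csv

# descriptive table only, or everything at once
ubcphen report --phenotypes phenotypes.csv --samples sim/samples.csv --out desc.csv
ubcphen all --out run/ --seed 3
```

Windows, code lists, eligibility rules and statistical constants can be
overridden from a YAML config (`--config`), e.g.:

```yaml
windows:
  ivc_gap_days: 120
  followup_window_days: 183
  independence_days: 91
assoc:
  abf_prior_sd: 0.2
eligibility:
  require_white_british: true
```

## Catalog format

CSV with columns `rsid, allele_ref, allele_eff, outcome_label, subgroup,
original_direction, original_estimate`. Outcome labels: `recurrence`,
`progression`, `overall_survival`, `ubc_specific_survival`,
`age_continuous`, `age_cutoff_{50,55,60,65,70}`; subgroups `UBC`, `NMIBC`,
`MIBC`. Bonferroni denominators are taken from the loaded catalog's
per-family entry counts.

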