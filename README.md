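# eegcomplex

Multiscale-entropy (MSE) complexity analysis of multichannel EEG with
penalized logistic regression, leave-one-subject-out cross-validation,
selection-frequency scalp maps, and canonical correlation against
neuropsychiatric symptom scores. A seeded synthetic cohort generator makes
the whole pipeline runnable and testable without any clinical data.

## What it does

1. **synth** — generates a cohort of EEG-like recordings (19-channel 10-20
   montage, 256 Hz) as standardized white/pink-noise mixtures. A per-subject
   latent severity grades the pink weight on a subset of "effect" channels
   (T5, T6, O1, O2 by default) and drives a 12-symptom score table, planting
   a recoverable group contrast, an entropy-curve crossover, and an
   MSE↔symptom correlation.
2. **extract** — per channel: linear detrend, then sample entropy
   (m=2, r=0.15×SD, Chebyshev distance, strict `< r`, self-matches excluded)
   of coarse-grained series at scale factors 1–20, giving 19×20 = 380 named
   features (`<channel>_s<scale>`) per session.
3. **classify** — native L1/elastic-net logistic regression (IRLS +
   coordinate descent, KKT-certified; `alpha=0.7` default for enet),
   leave-one-subject-out outer CV with subject-grouped nested CV for the
   penalty weight, session-level pooled metrics (sensitivity, specificity,
   accuracy, Mann-Whitney AUC).
4. **biomap** — per-feature selection frequencies across LOSO folds,
   aggregated per channel over five scale bins (1–4, 5–8, 9–12, 13–16,
   17–20) by the max-within-bin rule, exported with 10-20 scalp coordinates.
5. **cca** — pseudo-inverse-whitened canonical correlation between
   subject-averaged MSE features and the 12 symptom scores, with structure
   coefficients and pair ranking.

## CLI

```sh
eegcomplex synth    --out out/cohort --subjects-per-group 5 --seed 1
eegcomplex extract  --in out/cohort/manifest.csv --out out/features.csv
eegcomplex classify --features out/features.csv --contrast HC:AD3 \
                    --method lasso --out out/classify
eegcomplex biomap   --cv-result out/classify/selection_frequency.csv --out out/map.csv
eegcomplex cca      --features out/features.csv --npi out/cohort/npi.csv --out out/cca
eegcomplex run-all  --out out --subjects-per-group 5 --seed 1
```

All subcommands accept `--config <yaml>` (flat keys, see
`eegcomplex.config.AnalysisConfig`) and write a `run_metadata.json` echoing
the configuration, seed, and library versions. An optional minimal EDF
reader (`eegcomplex.edf.read_edf`) imports plain 16-bit EDF exports.

## Layout

```
src/eegcomplex/
  synth.py     synthetic cohorts (signals + symptom scores)
  mse.py       coarse-graining, sample entropy, feature extraction
  reglearn.py  penalized logistic regression (native solver)
  evalcv.py    LOSO orchestration and metrics
  biomap.py    selection-frequency scalp maps
  cca.py       canonical correlation + structure coefficients
  dataio.py    CSV readers/writers; edf.py: minimal EDF reader
  config.py    flat YAML analysis configuration
  cli.py       click CLI (synth/extract/classify/biomap/cca/run-all)
```
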