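# nightcough

Nocturnal cough detection and sleep-stage cough-rate analysis from
non-contact audio recordings.

The pipeline mirrors a classic whole-night cough-monitoring system:

1. **Pre-processing** — DC removal and polyphase down-sampling to 16 kHz.
2. **Event detection** — per-frame energies (20 ms frames, 50% overlap)
   are histogrammed in dB over the whole recording; three
   recording-adaptive thresholds (`th1` trigger, `th2` onset, `th3`
   offset) are derived from the histogram, and events outside the
   0.15–1.1 s cough-duration band are dropped.
3. **Feature extraction** — each event is split into an explosive first
   part, a turbulent second part and an optional voiced third part
   (detected when the 50–255 Hz autocorrelation voicing score exceeds
   0.45), and a 34-dimensional feature vector is extracted: energy-peak
   index, 12 MFCCs per part, two voicing scores, LPC cross-frame
   variance, part-1/part-2 energy-peak ratio, mean ZCR, kurtosis,
   skewness, amplitude entropy and spectral centroid.
4. **Classification** — either three per-class diagonal Gaussian
   mixtures scored by `log(S_cough / max(S_snore, S_noise))` (default
   orders 1/1/16, default operating threshold 1.17), or a small fully
   connected network (two hidden layers of 100 ReLU units, dropout 0.5,
   softmax; 13,502 parameters at 31 inputs) scored by
   `log(S_cough / S_non_cough)` (default threshold −2.22).
5. **Evaluation** — confusion-matrix metrics incl. Cohen's kappa,
   ROC/PR curves and AUCs, threshold selection, subject-disjoint 5-fold
   cross-validation, and sequential forward feature selection with the
   criterion `J = (sensitivity + PPV) / 2`.
6. **Sleep analysis** — detected coughs are aligned to a 30 s-epoch
   hypnogram; per-stage cough rates (coughs/hour), Wilcoxon rank-sum
   tests (exact for small samples), Pearson/Spearman/partial
   correlations and post-cough stage-transition tables.

Because clinical night recordings cannot be redistributed, the package
ships a first-class synthetic-night generator (`nightcough.synth`) that
produces annotated waveforms with the acoustic structure the detector
assumes — three-phase coughs (voiced:unvoiced 2:3), semi-periodic
snores, transient noises, a pink-noise background and a Markov-chain
hypnogram — so the entire pipeline is testable end to end.

## CLI

```bash
nightcough synth --seed 7 --duration 600 --out night1/
nightcough detect night1/night.wav --out events.csv
nightcough features night1/night.wav events.csv --out features.csv
nightcough train-gmm features_labeled.csv --out gmm.json
nightcough train-dnn features_labeled.csv --out dnn.json
nightcough score gmm.json features.csv --kind gmm --out scores.csv
nightcough evaluate scores.csv labels.csv --threshold 1.17 --out report.json
nightcough analyze events.csv night1/hypnogram.tsv --out rates.csv
nightcough run-all --seed 7 --out pipeline_out/   # full synthetic workflow
```

`run-all` generates a multi-subject synthetic corpus, detects and
featurizes events, trains both classifiers on subject-disjoint splits,
evaluates them, and writes stage-normalized cough-rate tables plus a
reproducibility manifest (config hash + seeds); reruns with the same
config are bit-identical.

## Layout

```
src/nightcough/
  synth.py        synthetic nights, events, hypnograms
  preprocess.py   WAV loading, DC removal, resampling
  detect.py       frame energy, adaptive thresholds, event extraction
  features.py     part segmentation + 34-feature extractor
  select.py       sequential forward selection (criterion J)
  gmm.py          diagonal-covariance EM mixtures + LLR scoring
  dnn.py          numpy MLP (Adam, dropout, class weights) + LLR scoring
  evaluate.py     metrics, curves, thresholds, k-fold CV
  sleep.py        hypnogram alignment, rates, statistics
  pipeline.py     orchestration and config
  cli.py          click CLI (one verb per stage)
```
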