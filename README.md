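# depnet — depression-subtype EEG network connectivity

`depnet` is an analysis package for a question in EEG network psychiatry:
do different *symptom subtypes* of depression — depressed mood, anhedonia,
cognitive depression, somatic depression — carry different resting-state
connectivity signatures in the alpha (8–12.9 Hz) and beta (13–18 Hz)
bands?  It implements the full analysis chain used to ask that question,
together with a synthetic-data generator with known ground truth, so every
stage is testable and the statistical behaviour of the design itself can
be characterised.

The chain, and where each step lives:

1. **Subtype scoring** (`depnet.sds`) — Zung Self-Rating Depression Scale
   (20 items, 1–4, ten reverse-keyed; total 20–80).  Each subtype is the
   mean of its items; participants are split depressed / non-depressed
   *per subtype* at the cohort-mean cutoff (ties depressed).
2. **Synthetic cohort and EEG** (`depnet.simulate`, `depnet.headmodel`) —
   correlated subtype severities from a one-general-factor latent model;
   24-channel, 1 kHz, 3-minute eyes-closed EEG forward-modelled through an
   analytic three-shell spherical head, with narrowband alpha/beta sources,
   1/f background, blink / pop / muscle artifacts, and *lagged* coupling
   planted on designated ROI pairs with a group-dependent strength.
3. **Preprocessing** (`depnet.preprocess`) — zero-phase 1–30 Hz filtering
   with 50 Hz notch + band-stop, back-to-back 4-s epochs, ±50 µV rejection
   after whole-epoch baseline correction, exclusion of participants with
   < 75% clean epochs, FFT band power.
4. **Source inverse** (`depnet.inverse`) — eLORETA-style weighted
   minimum-norm operator with the zero-localisation-error property
   (verified exactly on the test grid), and time series for 18 ROIs of the
   default-mode, executive-control and salience networks (MNI centres,
   10 mm radius).
5. **Connectivity** (`depnet.connectivity`) — lagged linear connectivity
   per band, `LLC = Im(S_xy)² / (S_xx S_yy − Re(S_xy)²) ∈ [0, 1]`, from
   epoch-averaged cross-spectra; insensitive to instantaneous (volume
   conduction) mixing by construction.
6. **Group comparison** (`depnet.compare`) — per-edge pooled-variance t
   and Cohen's d (depressed − non-depressed), flagging at |d| ≥ 0.2,
   cross-subtype *exclusivity* filtering, count tables, signed network
   matrices, and max-|t| permutation-corrected p values.
7. **Orchestration** (`depnet.pipeline`) — seeded, manifest-tracked,
   checksum-gated end-to-end runs configured in YAML or code.

The numbered scripts under `analysis/` are thin narrative drivers over the
package, writing their tables under `results/`.

## Worked example

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_score_sds.py
python analysis/03_run_eeg_pipeline.py --seed 1   # full 100-participant EEG run, a few minutes
python analysis/04_compare_groups.py
python analysis/05_null_calibration.py
```

`01` and `02` print (seed 1):

```
SDS total: mean 34.65, sd 10.94, range 20-72
inter-subtype correlations: 0.61 - 0.71      (all inside the 0.55-0.90 band)
scored 100 participants; Cronbach's alpha = 0.943
clinical cutoff 40: 32 above, 68 below; F(1,98) = 200.438, partial eta^2 = 0.672
subtype-mean cutoffs: {'mood': 1.733, 'anhedonia': 1.7, 'cognitive': 1.74, 'somatic': 1.74}
```

i.e. the generator reproduces the descriptive shape of a community cohort:
a mildly symptomatic majority, a third of participants above the clinical
cutoff, high internal consistency, and strongly correlated subtype scores.

`03` plants six alpha-band lagged-coupling edges whose strength is raised
by 50% for the mood-depressed group, then runs the whole chain.  `04`
summarises (seed 1):

```
  subtype  band  D_gt_ND  D_lt_ND   best_p
     mood alpha        8        1 0.000400     <- planted contrast drives the corrected p
anhedonia alpha        7        2 0.006399
...
recovered by the d >= 0.2 screen: 6/6; surviving exclusivity: 0/6
```

All six planted edges are recovered by the effect-size screen with the
correct direction (d between +0.29 and +1.11), and the mood-alpha cell has
by far the best family-wise corrected p.  None of them survives the
cross-subtype exclusivity filter: because the four subtype scores
correlate at r ≈ 0.6–0.85, the other subtypes' splits see the same
contrast at about half size and flag the same edges, and the filter
removes every edge flagged under two or more subtypes.  That asymmetry —
the screen finds planted structure reliably, the exclusivity partition has
a hard statistical ceiling — is a property of the design itself, and is
quantified in `docs/methods.md` (§8).

`05` calibrates the screen under the null (no group difference,
n = 50/50): each edge is flagged with probability ≈ 0.32 (Monte-Carlo
expectation 0.316, observed 0.321), i.e. ~49 of 153 edges per cell by
chance alone, while the max-statistic permutation correction keeps the
family-wise error at ≈ 5%.

## Layout

```
src/depnet/          the library (all computation)
analysis/            numbered narrative drivers writing results/
tests/               pytest suite incl. the acceptance battery
scripts/acceptance.py
docs/methods.md      models, defaults, numerics, statistical behaviour, limitations
```
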