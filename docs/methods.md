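# Methods

`pafnet` detects atrial fibrillation (AF) in long-term ("dynamic") ECG
recordings and localizes where each AF episode starts and ends.  It treats
AF and atrial flutter as one positive class and everything else —
predominantly normal sinus rhythm (NSR) — as negative.  This note records
the models, the parameter choices, the numerical decisions, and what the
synthetic data can and cannot establish.

## Signal model and preprocessing

Input records are WFDB-style (header + 16-bit samples + annotations); all
processing happens at 200 Hz, and records stored at other rates (128–360 Hz)
are resampled on read with a polyphase filter, with annotation indices
rescaled by the same ratio.  The 600-point network window assumes roughly
200 samples per cardiac cycle, which only holds at this rate.

Denoising is a fixed, parameter-light chain:

1. **Baseline removal** — the baseline estimate is a cascade of two median
   filters (0.2 s, then 0.6 s windows, rounded to odd sample counts) and is
   subtracted from the signal.  Medians reject the narrow QRS complexes, so
   R-wave amplitude survives; drift below ~1 Hz is almost entirely removed.
2. **Impulse rejection** — samples deviating from a 5-point rolling median
   by more than k = 8 robust standard deviations (1.4826·MAD of the whole
   signal) are replaced by that rolling median.  The threshold is far
   outside the ECG dynamic range, so clean records pass through bit-identical.
3. **Low-pass** — order-4 Butterworth, −3 dB at 40 Hz, applied
   forward–backward.  Zero phase matters: a causal filter would shift R
   peaks and corrupt episode boundaries defined on them.

**R-peak detection** is Pan–Tompkins: 5–15 Hz band-pass, five-point
derivative, squaring, 150 ms moving-window integration, adaptive dual
thresholds with search-back when no beat appears within 1.66× the running
R-R average, and a 200 ms refractory period.  The integration peak does not
sit on the R wave, so each detection is snapped to the QRS-band maximum
within ±100 ms and then refined to the signal maximum within ±40 ms.

**R-peak correction** handles spurious detections (typically T waves or
noise spikes): for every R-R interval shorter than 0.5 s, the member of the
pair whose amplitude is below α = 0.6 of the smaller of its two
neighbouring peaks is deleted, repeating until stable.  α has no published
value; 0.6 cleanly separates T waves (≈0.2–0.4 of R height) from genuine
low-amplitude beats on the synthetic morphology, and is configurable.  The
0.5 s rule is deliberately a *trigger*, not a veto: genuine short AF
intervals between comparable-amplitude beats are never deleted.

## Sample construction

Records are cut at R peaks into overlapping 3-beat samples: sample *i*
spans peaks *i*..*i+3* and is linearly time-scaled to exactly 600 points
(endpoints preserved; amplitudes untouched — no per-sample normalization,
though a z-scoring flag exists for experiments).  With N peaks every
channel yields N−3 samples, stepping one cycle at a time, so interior beats
are covered by three samples each.  A sample is AF if *any* of its three
beats is AF.  Episode onsets/offsets are defined on R peaks: the onset is
the beat nearest before AF begins, the offset the last beat after it ends,
stored as inclusive beat-index pairs.

## Classifier

A 1-D residual network feeds one Transformer encoder layer:

- Stem: conv(1→32, kernel 16) → batch-norm → ReLU.
- Eight residual blocks, each conv → BN → ReLU → dropout → conv → BN with
  an element-wise sum and ReLU.  Kernel 16 throughout; stride 1 in
  odd-numbered blocks and 2 in even-numbered ones (temporal length
  600→300→150→75→38 with ceil division); filters 32, doubling to 64 at
  block 5.  The shortcut is parameter-free: max-pool with pool = stride,
  channel widening by zero-padding.  A 1×1 projection would work too but
  adds parameters and breaks the reference parameter total.
- A learned positional table (50 × 64, zero-initialized, sliced to the
  38-step sequence) is added, then one encoder layer: 8-head scaled
  dot-product self-attention (d_k = d_v = 8) with residual + layer-norm,
  and a position-wise feed-forward 64→32→64 with residual + layer-norm
  (post-norm ordering).
- Head: global average pooling over time → dense 64→32 → ReLU → dropout →
  dense 32→1 → sigmoid.

Two places where sources conflict were resolved toward the parameter
accounting, which is self-consistent: the positional encoding is a
*learned* table (a sinusoidal one has zero parameters, but the layer table
assigns it 50·64 = 3 200 trainable parameters, and the total/trainable gap
of 1 600 is exactly the batch-norm running statistics, 2 per channel over
800 channels); and the feed-forward hidden width is 32, the unique value
consistent with the printed encoder total of 21 088 = 4·(64·64+64) MHA
projections + (64·32+32 + 32·64+64) FFN + 2·128 layer-norms.  The audit in
`model.audit_parameters` recomputes all of this from the built network:
653 505 total, 651 905 trainable.

The engine is a small numpy layer library with hand-written backward
passes, verified end-to-end against central finite differences in float64.
Dropout defaults to 0.2 (no published value).  Batch-norm uses ε = 1e-3
and running-statistics momentum 0.9 — deliberately faster than the common
0.99 so that inference statistics are usable after the short training runs
this package targets.

## Training protocol

Records are split 80/10/10 *by recording* (no sample of one record in two
splits), seed-deterministic.  Persistent-AF records (all samples AF) are
augmented with Gaussian-noise copies of their samples; σ defaults to 5% of
the corpus' median per-sample peak amplitude.  Loss is binary
cross-entropy (computed from logits for stability); the optimizer is
RAdam (lr 1e-3, β = 0.9/0.999) with the variance-rectification fallback to
a plain momentum update while the rectification term ρ_t ≤ 4.  Batch size
128.  Early stopping watches *validation accuracy* (sample-level, threshold
0.5): training stops after 10 epochs without improvement and the
best-validation weights are restored.

## Post-processing

Each beat is covered by up to three samples; its label is the majority
vote, ties resolving toward AF, and uncovered edge beats inherit the
nearest covered beat's label.  Maximal AF runs become episodes after
closing gaps shorter than `min_len` non-AF beats and dropping runs shorter
than `min_len` beats ("isolated labels"); `min_len` defaults to 2, a choice
this package makes since no count is published, and the symmetric gap/run
treatment is deliberate.  The whole-record class follows the AF-sample
fraction: < 0.1 normal, > 0.9 persistent AF, otherwise paroxysmal — the
boundaries themselves fall in the paroxysmal class (strict inequalities).
Normal records report no episodes; persistent AF reports the single
full-span episode.

Two-channel merging is a per-sample logical AND; when the channels disagree
on more than half the samples, the channel whose mean confidence
|p − 0.5| is higher dominates outright.  Both the 50% threshold and the
confidence measure are this package's quantification of an otherwise
qualitative rule.

## Evaluation

TP/FP/TN/FN with AF positive feed accuracy, sensitivity, specificity,
precision, F1, FPR and Matthews correlation.  Zero-denominator metrics are
reported as explicit `None`, never 0, so aggregates cannot silently absorb
them.  Boundary detection counts an onset (offset) as found when an
unmatched predicted onset (offset) lies within ±3 beats, matched greedily
nearest-first under a one-to-one constraint — the multiplicity rule is this
package's choice.  Episode-level tables are beat-weighted (duration view);
a per-episode detection rate is available separately through the boundary
matcher, and reports label which view they use.

## Noise stress harness

White, EMG-like and motion-artifact surrogates are generated (unit power,
seeded): i.i.d. Gaussian; Gaussian band-passed 20 Hz–90% of Nyquist; and a
low-pass-filtered random walk gated by 1–4 s burst envelopes with < 5 Hz
energy.  Mixing scales the noise so the mean-square power ratio equals the
requested SNR exactly (after mean removal, per record).  Noise is added to
the *raw* signal before preprocessing — the harder and more realistic
protocol.  Baseline wander is excluded from the catalogue because the
median cascade removes it (asserted in tests: > 90% of sub-1 Hz power
gone).  Surrogates stand in for recorded ambulatory noise so the harness
needs no downloads; an external noise series can be passed to
`scale_and_mix` with identical semantics.

## Synthetic data: what it shows and what it does not

The generator builds each beat from five Gaussian bumps (P, Q, R, S, T)
with latencies stretched by the local cycle length; R-R intervals are
lognormal with CV 0.05 for NSR and 0.25 for AF (clipped to 0.3–3 s); AF
segments drop the P bump and superimpose a phase-noisy sinusoid at 6 Hz
(amplitude 0.1 mV against a 1 mV R wave) — exactly the three features that
define AF on an ECG.  Heart rate defaults to 75 bpm; corpora draw it
uniformly from 60–95 bpm per record.  Channels share rhythm and beat times
but are independent morphological realizations.  The default corpus mixes
normal/persistent/paroxysmal records 51/33/16, the approximate composition
of public dynamic-ECG AF corpora.

These records make the two classes nearly separable, which is the point:
they give exact ground truth for beats and episodes, so segmentation,
voting, episode extraction and the learning machinery can be verified
end-to-end.  They do *not* contain ectopy (PACs/PVCs, bigeminy), paced
rhythms, lead dropout, or the morphological diversity of real patients —
passing tests here demonstrates correctness of the pipeline, not clinical
performance.  Scale choices for the in-repo checks: the learning sanity
check trains on 200 single-channel records of ~100 beats (≈19 400 samples)
for one epoch per seed, three seeds — enough for the separable corpus to
exceed 0.95 validation accuracy while keeping the suite fast on one CPU.

## Known limitations

- The WFDB reader/writer covers format 16 with one annotation file; enough
  for this pipeline and for round-tripping its own records, not a general
  PhysioNet client.
- Weight determinism across platforms is best-effort (BLAS reduction order);
  data-pipeline determinism is exact and asserted.
- The challenge-specific two-step penalty score and ROC/AUC plotting are out
  of scope; a threshold sweep can be run through `predict_labels`.
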