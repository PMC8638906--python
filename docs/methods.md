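# Methods

This note records the model, the constants, and the design choices made
where the published description of CAP A-phase detection leaves the
implementation open. It is the companion to the code, not a results report:
every number quoted as behaviour is computed by the test suite or by
`scripts/acceptance.py`.

## Detection model

The detector treats a CAP A phase as a transient whose amplitude stands out
from the local background in at least one of two frequency bands:

* slow band 0.3–4.5 Hz (synchronised, high-voltage component),
* fast band 7–25 Hz with the sigma band removed (desynchronised component;
  sleep spindles at 11–15 Hz would otherwise be detected as activations).

Within NREM sleep each band-filtered derivation is scanned in 90-s context
epochs advanced by 30 s. Each epoch decides its central 30 s; a second is
marked when its variability exceeds 1.6× the epoch variability *and* the
analytic-signal envelope exceeds 1.5× the epoch RMS at one or more samples.
Both references are taken from the same 90-s epoch (`rms_mode="per_epoch"`);
the variant using a single RMS over the whole NREM record
(`rms_mode="whole_nrem"`) is retained because the per-epoch reference is
the decisive difference between the two published variants of this
algorithm family. Because every threshold is relative, detection is exactly
invariant under global amplitude rescaling (property-tested).

Marked seconds become events by merging runs separated by ≤ 1 s and then
discarding events shorter than 2 s; slow- and fast-band events are unioned
and re-cleaned with the same rule.

### Choices the published description leaves open

* **Variability statistic.** Undefined in the source description. We use
  the within-second sample standard deviation of the band-filtered trace,
  and the epoch variability is the mean of the per-second SDs over the
  epoch. It is the simplest statistic consistent with "variability" and is
  isolated in `second_variability` so alternatives can be swapped.
* **Envelope.** Magnitude of the analytic signal (Hilbert transform) of the
  band-filtered trace; the threshold test is "any sample in the second".
* **Epoch boundaries.** Only the central-30-s rule is published. The first
  and last 30 s of each NREM segment are decided by the segment's first and
  last epoch; segments shorter than 90 s serve as their own context. Epochs
  never span NREM segment boundaries, and filtering is applied per segment
  so concatenation joins cannot ring.
* **Cleanup order.** "Remove 1-s events, combine events 1 s apart" does not
  fix an order; we merge first, then remove, which preserves genuine A
  phases fragmented by a single quiet second. A corollary is that two
  isolated marked seconds 2 s apart survive as one 3-s event; this is the
  main source of short background false positives.
* **Events longer than 60 s** are kept in the event list but violate the
  phase rules, so they act as sequence breakers downstream.

### Filters

4th-order Butterworth band-passes and a 2nd-order Butterworth band-stop
over 11–15 Hz, all applied forward–backward (`sosfiltfilt`), so events keep
their timing (zero phase; property-tested at lag 0 ± 1 sample). The
measured amplitude responses of the fast chain are 0.87 at 10 Hz, 0.98 at
20 Hz and ≈ −93 dB at 13 Hz relative to 10 Hz, comfortably inside the
package's contract (10/20 Hz within ±20% of unity, 13 Hz ≥ 10 dB down).

## Multi-trace fusion

*Global Analysis* is the per-second union of the per-derivation event
lists, re-cleaned with the same merge/minimum-duration rules. Since union
coverage contains every local list's coverage and merging only grows
events, the global TP count dominates every local one under any-overlap
matching — sensitivity ordering is a theorem, not an empirical finding, and
is asserted as a property test.

*Global Analysis — Common Events* retains a global event iff ≥ 1 of its
seconds is covered by ≥ 2 derivations' cleaned events simultaneously
(`min_support`, `min_overlap_s` configurable). "Simultaneously" is read
strictly as per-second co-detection, not mere co-occurrence inside the same
merged global event; the weaker reading would retain events merged across a
1-s gap without any true co-detection. By construction this discards every
*artifact-only* event — an event supported by exactly one derivation. It
cannot promise to discard every injected artifact on arbitrary data: a
chance background detection on a second derivation overlapping the artifact
gives it support 2 (observed at roughly one event per hour on synthetic
backgrounds), so the rejection guarantee, and its test, are stated for
artifact-only events.

## CAP sequences and parameters

A phases lasting 2–60 s and lying wholly in NREM chain into runs when each
inter-A gap (the B phase) is 2–60 s of uninterrupted NREM; runs of ≥ 2 As
form sequences. The closing B after the last A — whose extent the scoring
rules leave open — runs to the earliest of the next event's onset, the NREM
segment end, or 60 s, and is counted even when a stage transition cuts it
below 2 s. Isolated A phases contribute to the A-event count and mean
duration but not to CAP time. CAP time per class (NREM, LS = S1–S2,
SWS = S3–S4) is the sequence-span time in that class; CAP rate divides by
the class's sleep time, so NREM CAP time = LS + SWS CAP time exactly.

Sleep quality: onset is the first epoch of any sleep stage; TST counts all
sleep epochs; WASO counts wake epochs between onset and the end of the last
sleep epoch; %-Sleep is TST over that span.

Event matching for evaluation is any-overlap ≥ 1 s on the second grid,
counted on the reference side (one long detection may validate several
reference events; FPs are counted per detected event). The criterion is
exposed as `min_overlap_s`.

## Synthetic data: what it emulates, what it does not

The generator produces the structure the detector assumes:

* **Background**: 1/f-shaped noise low-passed at 30 Hz, with a spectral
  knee at 1 Hz (flat below). The knee matters: without it the infraslow
  power diverges, background variance grows with record length, and the
  slow-band per-second SD has so few effective degrees of freedom that the
  variability test fires on background alone. Derivations share half their
  variance (pairwise correlation 0.5) via a shared + private noise mix.
  Background RMS 25 µV.
* **A phases**: band-limited noise bursts (slow, fast, or both, with
  default mix 0.4/0.3/0.3) injected into *all* derivations simultaneously,
  scaled so the in-band RMS during the burst is `burst_amplitude_ratio`
  times the background's in-band RMS (default 4/3 — A phases run about one
  third above background). Cosine ramps of ≤ 0.5 s; the burst is
  renormalised after tapering so the pooled measured ratio stays within 10%
  of the target (asserted).
* **CAP structure**: A durations drawn uniformly on 4–15 s and in-sequence
  B gaps on 5–40 s. These sampling ranges sit inside the 2–60 s rule bound
  (which is enforced) but are deliberately narrower: scored A phases
  average around ten seconds, and uniform sampling over the full 2–60 s
  range would make half-minute activations dominate each 90-s context
  epoch, which no real recording does. Sequences of 2–6 cycles are placed
  into NREM segments, separated by 65–180 s gaps (> 60 s, so sequences
  stay distinct), until the target NREM CAP rate (default 30%, a typical
  adult value) is reached; an unreachable target raises an error.
* **Artifacts**: 3–8-s bursts at 3× background injected into exactly one
  derivation each (default 0.2/NREM-minute), placed ≥ 5 s away from any A
  phase.

Not emulated: realistic full-night architecture, A-subtype (A1/A2/A3)
morphology, non-Gaussian transients (K-complexes, eye movements, ECG
bleed), or scorer variability. Passing the recovery tests therefore shows
the pipeline implements its rules correctly under its own signal model, not
that it matches an expert on clinical data — real A phases sit much closer
to background (ratio ≈ 4/3) and real backgrounds are less stationary, so
performance on clinical recordings should be expected to be substantially
lower than the synthetic figures.

## Problem sizes and determinism

The end-to-end study fixture used by the tests and the acceptance script is
60 min at 128 Hz with 6 derivations and bursts at ratio 2.0 — large enough
for ~24 A phases and ~10 artifacts, small enough that the whole suite runs
in seconds. All randomness flows from a single `numpy` generator seed;
fixtures are bit-reproducible per seed (asserted). EDF output is 16-bit
with per-channel physical scaling, so write→read round trips are exact to
quantisation (~0.003 µV for ±150 µV signals).

## Known limitations

* The variability statistic and envelope estimator are plausible choices,
  not reverse-engineered ones; absolute agreement with the original
  implementation's event lists is not guaranteed.
* Sequence assembly is greedy left-to-right (matching the rule text); no
  global optimisation over alternative cycle groupings is attempted.
* The PhysioNet scoring-file reader in `scripts/physionet_harness.py` is
  best-effort and untested; the native tab-delimited format is the tested
  contract.
* `fs < 64 Hz` recordings are rejected rather than analysed with a reduced
  fast band.
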