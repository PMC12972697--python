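# Methods

## Sleep scoring

A fly's minute is *immobile* iff its beam-cross count is exactly 0; a sleep
episode is a maximal run of immobile minutes with length ≥ the bout
threshold (default 5 min). Sub-threshold runs contribute nothing. Episodes
truncated by the edges of the analysis window are scored from the observed
minutes only.

The analysis day is the 1440 minutes starting at lights-on (ZT0) of a
configurable day index (default day 3 of a 3-day recording, leaving two
days of entrainment). Day is ZT [0, 720), night ZT [720, 1440). An episode
spanning the ZT720 boundary is split there: its minutes are apportioned to
each phase and the clipped segment counts as one bout in each phase it
overlaps. This choice keeps the identity *phase bout length × phase bout
count = phase sleep minutes* exact within each phase; assigning the whole
bout to one phase would break it. The same rule applies at ZT1440 if an
episode runs into the window edge (it is simply truncated).

Waking activity for a phase is (sum of counts in the phase) / (phase
minutes − phase sleep minutes). When a fly sleeps an entire phase the
denominator is 0 and the parameter is **undefined** (NaN), not 0 or
infinity; such flies are dropped from that parameter's statistics only, and
the reported group sizes count the values actually tested.

A dead-or-escaped-fly guard (`flag_inactive_fly`: zero counts over the
final 6 h) is computed and reported for every fly but excludes nobody by
default; exclusion is a config switch and every exclusion is logged.

Known scoring-level artifact, reproduced faithfully: latent sleep spells
shorter than the threshold are scored as *waking* minutes with zero counts,
so genotypes with fragmented sleep dilute their measured waking activity
slightly. The synthetic fragmentation mutant shows this as a small but
detectable waking-activity difference alongside its large bout-length
effect.

## Group statistics

* **Pairwise test.** Two-sided Wilcoxon rank-sum (Mann–Whitney). The
  p-value is exact — full enumeration of the rank-sum null — whenever the
  pooled sample is ≤ 20 and tie-free; otherwise the tie- and
  continuity-corrected normal approximation is used (scipy's
  `mannwhitneyu`). The Z used for effect sizes is always taken from the
  tie-corrected normal approximation of U *without* the continuity shift,
  so identical samples give Z = 0 exactly and r is defined even when p is
  exact.
* **Effect size.** r = |Z|/√(n1+n2). Rank-based, hence invariant under
  strictly monotone transforms of the data and unaffected by the
  multiplicity correction.
* **Families.** With exactly two genotypes the raw pairwise p is reported
  unadjusted and no screen is run. With three or more, a tie-corrected
  Kruskal–Wallis test is computed over all groups and the pairwise p-values
  are Benjamini–Hochberg adjusted as one family per parameter (not across
  parameters). Significance is adjusted p < 0.05.
* **Magnitude labels.** Blank when adjusted p ≥ 0.05; otherwise small
  (r < 0.3), moderate (0.3 ≤ r < 0.5), large (r ≥ 0.5), applied to the
  unrounded r. Published tables that print r to two decimals can therefore
  show an 0.50 under either label; the validation data treats exactly-
  on-boundary printed values as consistent with either adjacent label.

## ERG quantification

Per sweep, with stimulus onset *t₀* and offset *t₁* (nominally t₁ − t₀ =
1 s):

* baseline = mean voltage over [t₀ − 0.3 s, t₀);
* receptor potential = mean over [t₀ + 0.3 s, t₁) − baseline;
* on-transient = signed extremum over [t₀, t₀ + 0.15 s) relative to the
  plateau level (not baseline), so a transient-free trace scores 0;
* off-transient = signed extremum over [t₁, t₁ + 0.3 s) relative to the
  mean of [t₁ − 0.1 s, t₁).

The window lengths are package choices (all configurable via
`ComponentWindows`): 0.15 s isolates the fast synaptic transient from the
sustained response, 0.3 s of plateau settling keeps decayed transient
residue below ~10⁻⁴ of its amplitude for decay constants ≤ 50 ms, and the
0.3 s off-search window assumes the sustained potential decays over seconds
so that the off-transient is measured against an essentially flat pre-offset
level. Sign convention: depolarising receptor potential negative at the
corneal electrode; transients keep the sign of their deflection.

Repeats (nominally 3) are averaged per (fly, intensity); group comparisons
pool the averaged values across the four intensities, so each genotype
enters with n = flies × 4, and then the ordinary statistics layer applies.
Per-intensity means ± SD are retained in the intensity–response summary, so
pooling loses nothing.

## Synthetic data generator

**Locomotion.** A two-state Markov chain at 1-min resolution: wake→sleep
probability `p_sleep_onset(zt)` and sleep→wake probability
`p_wake_onset(zt)`, step functions over ZT. Waking minutes emit
Poisson(`wake_rate`) beam crosses; sleeping minutes emit 0. The default
template has four blocks — morning (ZT0–3: onset 0.02, offset 0.10),
siesta (ZT3–9: 0.10, 0.03), evening (ZT9–12: 0.02, 0.10), night (ZT12–24:
0.15, 0.01) — chosen so a control fly scores ~330 day-sleep minutes, inside
the 300–400 min band typical of virgin males, with a consolidated night.
Default `wake_rate` is 4 beam crosses per waking minute, at the active end
of the realistic 2–5 range; a high rate keeps zero-count waking minutes
rare (P ≈ 0.018), so the immobility rule tracks the latent state and the
closed-form oracle below stays sharp. Mutants are expressed as
multiplicative scalings of these rates (`FlyModelParams.scaled`).

**Closed-form oracle.** For constant rates, sleep-state runs are
Geometric(`p_off`) and the stationary sleep probability is
π = p_on/(p_on+p_off); discarding runs shorter than m minutes leaves the
scored fraction

    π · E[L·1(L ≥ m)] / E[L] = π · q^(m−1) · (m·p_off + q),  q = 1 − p_off.

This is exact for the latent state. The scored series additionally absorbs
the occasional chance zero-count waking minute adjacent to a sleep run — a
positive bias of order P(0-count)·(runs per day), ≈ 1 minute/day at the
default rate, well inside the sampling error at n = 30 flies.

**ERG.** Baseline + sustained plateau (per-intensity amplitude, persisting
through the short post-offset window as the real potential decays over
seconds) + exponential on/off transient spikes (τ = 30 ms) + Gaussian
noise. Programmed amplitudes are recorded as ground truth; noiseless sweeps
round-trip through the extractor to < 10⁻⁵ mV (the residue of the decayed
transient inside the plateau window).

**What the generator does not emulate.** Homeostatic rebound, light-pulse
arousal, inter-fly rate heterogeneity within a genotype, electrode drift
and mains interference in ERGs, and DAM hardware artefacts (stuck beams,
double counts). Passing tests therefore demonstrate correctness of the
scoring/statistics chain and sensitivity to programmed effects of the
stated sizes — not that real recordings of any particular genotype would
reproduce any particular table.

## Problem sizes and numerics

Validation uses 1,000 random series for scan-oracle agreement, every
tie-free assignment pattern with pooled n ≤ 12 for the exact-test check
(8,166 patterns against enumerated nulls), 2,000 null replicates for the
Kruskal–Wallis type-I rate, 100 seeded replicates at n = 30 vs 30 for
fragmentation detection and 40 for the locomotor-confound dissociation,
and 30 flies through the file-based pipeline for closed-form recovery —
sizes at which the checks are decisive while the whole suite stays fast.
Ties in rank statistics are handled by the standard corrections; BH
adjustment is statsmodels' `fdr_bh`; all simulations run off
`numpy.random.default_rng` with explicit seeds, and generated monitor files
round-trip byte-identically through the parser/writer pair.

## Known limitations

* Only the single-beam DAM dialect is parsed (no multi-beam or
  environment-sensor channels); rows with error status inside the analysis
  window are treated as gaps, never imputed as zeros, since fabricated
  zeros would fabricate sleep.
* Single analysis day; no multi-day averaging or circadian period
  estimation.
* The exact-test cutoff (pooled n ≤ 20, tie-free) mirrors common practice;
  beyond it the normal approximation's p can differ from the exact tail in
  the extreme range, though r is unaffected.
* Intensity–response curves are summarised as mean ± SD only; no
  Naka–Rushton or similar fits.
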