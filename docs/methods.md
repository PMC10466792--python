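# Methods

## The measurement model

`hemibalance` analyses interhemispheric imbalance after stroke from three
modalities collected at baseline (T1) and one month later (T2):

* **fNIRS.** A 26-channel bilateral sensorimotor montage (14 sources, 8
  detectors) records continuous-wave intensities at 730 and 850 nm, 11 Hz,
  during a block-design grasping task: a 30 s leading rest, then three 25 s
  task blocks separated by 30 s rests. Per-ROI task activation is the
  task-minus-baseline change in oxyhaemoglobin concentration, dHBO (uM), for
  the primary motor cortex (M1), supplementary motor area (SMA) and premotor
  cortex (PMC) on the affected (AH) and unaffected (UH) hemispheres.
* **TMS.** Resting motor thresholds (RMT, %MSO) of both hemispheres. A
  hemisphere with no elicitable motor evoked potential carries the
  conventional ceiling RMT = 110 %MSO, which feeds all downstream formulas
  exactly like a measured threshold.
* **Clinic.** Upper-extremity Fugl-Meyer scores (FMA-UE, max 66) with
  distal (FMA-d) and proximal (FMA-p) sub-scores, Barthel Index, and
  demographics.

Laterality indices summarise each modality's asymmetry:

    LI(RMT)  = (RMT_AH - RMT_UH) / (RMT_AH + RMT_UH)
    LI(dHBO) = (dHBO_AH - dHBO_UH) / (|dHBO_AH| + |dHBO_UH|)

LI(RMT) > 0 means excitability lateralised to the unaffected hemisphere.
LI(dHBO) is bounded in [-1, 1]; the absolute values keep the denominator
positive when the two activation changes have opposite signs, and the
exactly-both-zero case is treated as undefined (an error) rather than zero,
since no dominance statement is possible there. LI(dHBO) is computed for M1,
SMA, PMC and the combined region, defined as the unweighted mean of the three
ROI-level activations per hemisphere (equal ROI weighting, insensitive to
unequal channel counts; channel pooling is a config alternative).

The equivalent threshold ratio R = RMT_AH / RMT_UH and its one-month change
d(R) = R2 - R1 stratify patients: d(R) > 0 assigns the unaffected-dominant
group, d(R) < 0 the affected-dominant group. d(R) exactly 0 has no defined
group; such subjects are excluded from subgroup analyses with a warning.

## fNIRS signal chain

1. **Optical density.** dOD = -log10(I / I_ref) per channel and wavelength,
   with I_ref the whole-recording channel mean (deterministic and
   mark-independent).
2. **Artifact correction.** First-difference jumps exceeding
   max(5 x robust SD of the channel's jumps, 0.005 OD) flag a 1 s window;
   flagged spans are bridged by linear interpolation. The absolute floor
   protects smooth task transients on very clean channels, where the robust
   SD collapses. A channel with more than 50% flagged samples is dropped from
   ROI averaging with a warning.
3. **Band-pass 0.01-0.1 Hz.** Zero-phase (forward-backward) 3rd-order
   Butterworth, suppressing drift, cardiac (~1.1 Hz) and respiratory
   (~0.25 Hz) oscillations. Each trace is demeaned and cosine-tapered over
   10 s at both ends before filtering: the 0.01 Hz corner rings for tens of
   seconds, and on a ~3 min recording the edge transients would otherwise
   leak into the task epochs (measured: a large off-band tone contaminates
   the block measure ~30x less with the taper; the first epoch starts 25 s
   into the recording, outside the tapered region). Zero-phase attenuation
   at 11 Hz sampling: ~0.01 dB at 0.05 Hz, ~52 dB at 0.25 Hz, >100 dB at
   1.1 Hz.
4. **Modified Beer-Lambert inversion.** Per channel the 2x2 system
   dOD(lambda) = (eps_HbO dC_HbO + eps_HbR dC_HbR) * d * DPF is solved for
   the two concentration changes. Defaults: source-detector separation
   30 mm, DPF 6.0 at both wavelengths, molar extinction (cm^-1 M^-1)
   730 nm: 390 / 1102.2 and 850 nm: 1058 / 691.32 (HbO2 / HbR). All are
   configurable; correctness tests use a forward-then-invert oracle and are
   therefore table-independent. Only HbO is analysed; HbR is retained on the
   series object.
5. **Block averaging and dHBO.** The three epochs spanning [-5 s, +25 s]
   around each task onset are averaged pointwise; dHBO is the task-window
   mean minus the 5 s pre-onset baseline mean. The 5 s baseline is the
   default (configurable); block averaging precedes baseline subtraction.
6. **ROI extraction.** Good-channel means per ROI and hemisphere, relabelled
   AH/UH from the subject's lesion side.

### The shape factor

Because the haemodynamic response rises over several seconds, the
task-window mean of the block response is below the plateau: numerically
integrating the HRF-convolved boxcar under this paradigm gives 0.84 x
plateau unfiltered and 0.85 through the band-pass
(`expected_delta_hbo_factor`). Recovery tests compare pipeline output
against this integrated expectation (agreement within ~3% on noise-free
recordings; the residual is interpolation and numerical effects), not
against the raw plateau. Laterality indices are ratios of same-shaped
quantities, so the factor cancels and does not bias any LI.

## Statistical battery

Test selection is gated on Shapiro-Wilk normality (alpha = 0.05) of every
variable involved: paired t / Pearson only if all pass, otherwise Wilcoxon
signed-rank / Spearman. A zero-variance sample forces the nonparametric arm
with a warning. All p-values are two-sided at alpha = 0.05 and uncorrected
by default, with a Benjamini-Hochberg switch (off by default) cross-checked
against statsmodels.

The declared battery is fixed at 105 cells: 6 clinical scores (FMA-UE/d/p at
T1, T2) x 10 laterality metrics (LI-RMT, LI-M1, LI-SMA, LI-PMC, LI-combined
at T1, T2) plus the 45 pairings among the laterality metrics. Cells with
fewer than three complete pairs or zero variance are reported as
not-computable rather than dropped, keeping the cardinality stable.
Correlation strengths are labelled on |r| with closed-lower-bound intervals:
negligible [0, 0.21), weak [0.21, 0.36), moderate [0.36, 0.68), strong
[0.68, 0.91), very strong [0.91, 1]; a boundary value such as |r| = 0.36 is
labelled by the interval it opens (moderate).

The combined-metric mean split computes s = LI-SMA(T1) + LI-RMT(T1), takes
the cohort mean of s, and compares outcome scores between the strictly-below
(g1) and strictly-above (g2) groups with Mann-Whitney U, reported as
medians with quartiles and the tie-corrected normal-approximation Z. A
subject exactly at the mean is excluded with a warning. The same correlation
battery runs separately inside the d(R) > 0 and d(R) < 0 strata (skipped
below n = 3).

## Synthetic studies

The generator emits complete studies with known ground truth. Per subject it
draws a severity, per-hemisphere RMTs (UH ~ N(50, 6) %MSO clipped to
35-70), an AH asymmetry increasing with severity, and no-MEP ceilings for
the most severe 20/31 at T1 and 19/31 at T2 (one subject regains an MEP).
True fNIRS laterality values are uniform on [-0.8, 0.8] per ROI and
timepoint and are converted to per-hemisphere plateau amplitudes around ROI
bases of 0.6/0.5/0.4 uM (M1/SMA/PMC), so every true LI satisfies its
defining formula exactly. Raw recordings apply the canonical double-gamma
HRF (peak 6 s, undershoot 16 s, ratio 1:6) convolved with the task boxcar,
dHbR = -dHbO/3, the Beer-Lambert forward model, and additive OD noise
(cardiac 1.1 Hz at 0.008, respiratory 0.25 Hz at 0.006, Mayer 0.09 Hz at
0.002, linear drift ~0.01 over the recording, white SD 0.003, Poisson
motion spikes of ~0.05 OD), before conversion to detector intensities. Raw
single-channel SNR is below one; block averaging restores recovery.

Outcome scores follow FMA-UE(T2) = FMA-UE(T1) + gain, with
gain ~ N(6, 4) - 55 * LI-RMT(T1) - 18 * LI-SMA(T1), plus
+32 * LI-PMC(T2) inside the d(R) > 0 stratum only, clipped to [0, 66];
the distal sub-score is a fixed 0.35 fraction. The couplings were calibrated
once, at design time, so the implied marginal Spearman correlations at
n = 31 sit at the moderate magnitudes the method is meant to operate at
(about -0.35, -0.34 and +0.56 for the three planted effects) and then
frozen. The optional `sma_rmt_rho` parameter couples LI-SMA(T1) to the
baseline RMT asymmetry through a Gaussian copula; its realistic value is
unknown and it defaults to 0.

What the generator does not emulate: anatomically realistic photon
transport, spatially correlated physiological noise, channel-specific
coupling gains, HbR dynamics beyond the fixed -1/3 ratio, missing data, or
learning/placebo effects on scores. Passing tests therefore demonstrate the
pipeline's internal consistency and its power to recover plantings of the
configured size at n = 31 — not clinical validity on real recordings.

## Problem sizes and numerical choices

End-to-end validation uses 20 effect studies plus 20 null studies of 31
subjects with full raw recordings (about 190 s at 11 Hz, 26 channels, two
wavelengths each), chosen to bound Monte-Carlo error on a sign-recovery rate
at roughly +-8% while keeping a complete run in the low minutes on one core.
Score-level simulations (which bypass raw signals via the ground-truth
activations) use 100-200 runs. Degenerate inputs fail loudly: non-positive
intensities, missing ROIs after channel exclusion, mark counts other than
three, a singular extinction matrix, and the all-zero LI denominator all
raise typed errors. Random draws flow through `numpy.random.default_rng`
with small derived integer seeds, so every artefact is reproducible from a
single seed.

## Known limitations

* The two-file recording container is deliberately plain-text and
  desk-scale; it is not an exchange format and no converter is provided.
* The Wilcoxon signed-rank arm uses the `wilcox` zero-handling rule; SPSS
  uses Pratt's in some versions, so borderline paired p-values can differ
  slightly from other software.
* The Mann-Whitney Z omits the continuity correction; with n around 15 per
  group the difference is in the third decimal.
* With 20 of 31 subjects at the RMT ceiling, LI-RMT(T1) is bimodal and its
  effective variance is small; correlations against it lean heavily on the
  11 sub-ceiling subjects, which is faithful to the measurement but limits
  attainable effect sizes.
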