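# Methods

## Color model

Pixel values are treated as the signal: frames are 8-bit RGB, divided by
255 and passed directly through the linear-sRGB/D65 matrix

    [X]   [0.4124 0.3576 0.1805] [R]
    [Y] = [0.2126 0.7152 0.0722] [G]
    [Z]   [0.0193 0.1192 0.9505] [B]

without sRGB gamma decoding (`rgb_to_xyz(..., gamma_decode=True)` enables it
for sensitivity analysis). The CIELAB white point is taken as the matrix row
sums, (0.9505, 1, 1.089), so an equal-RGB gray has X/Xn = Y/Yn = Z/Zn and
lies on the achromatic axis; in floating point the residue of that identity
is below 1e-12. The piecewise function f uses the standard CIE threshold
(24/116)³ ≈ 0.008856 with linear branch (841/108)x + 16/116. Hue is the
four-quadrant arctangent of (b\*, a\*) in degrees on [0, 360); requesting
the hue of an exactly achromatic color is an error (scalar) or NaN (array),
because no single branch value is defensible there.

## Signals and the ratio metric

A chamber signal is the arithmetic mean over the pixels whose centers lie
within the ROI circle (a mean of ~450 pixels at the default radius, which
suppresses pixel noise by ~20×). CIELAB channels are computed from the
ROI-mean RGB color, not per pixel: the conversion is nonlinear but locally
smooth, and the chamber is near-uniform, so the difference is negligible
while the cost drops by the pixel count.

The reference ("initial") value of the difference and ratio transforms is
the mean of the first `n_ref = 3` frames at/after the reference time.
Averaging protects the denominator from single-frame strobe jitter; the
cost is that the ratio at the reference frame itself is only ≈ 1, not
exactly 1 (use `n_ref = 1` when exactness matters, e.g. in noise-free
validation). Hue difference and ratio are computed on the wrapped angular
difference in (−180°, 180°], since naive subtraction is discontinuous at
the 0°/360° branch cut.

## Artifact correction

A sample is flagged when its relative change from the **last accepted**
sample exceeds 5% per second, scaled by the elapsed time since that sample.
Comparing against the last accepted value (rather than the immediate
predecessor) makes multi-frame flash excursions entirely flaggable: the
second frame of a two-frame flash differs little from the first, but a lot
from the last good sample. Flagged samples are replaced by linear
interpolation between the nearest unflagged neighbours (default) or by
holding the previous accepted value (`mode="hold"`); interpolation is the
default because it preserves trace length and timestamps, which the R²(t)
computation needs. Runs of flagged samples at either end clamp to the
nearest unflagged value.

The correction is idempotent on realistic traces (isolated excursions on a
slowly varying baseline) and is tested as such; a contrived trace whose
accepted samples sit exactly on the change bound over long gaps can be
re-flagged on a second pass, because the interpolated chord concentrates
the same relative change onto shorter steps.

## Smoothing and read-out

The 30-s moving average is trailing (causal): the value at t averages the
samples in (t − 30 s, t]. A trailing window permits a live readout during
the assay, at the price of a lag bias of roughly (window/2)·(trace slope);
with the default kinetics this bias is well below the strobe noise it
removes. The window mean is computed anchored at the current sample, so a
locally constant trace passes through bit-exactly. Values at arbitrary
times are linearly interpolated; extrapolation beyond the trace is refused.

## Calibration, R²(t), LOD

The calibration model is OLS of signal on log10(concentration) over the
nonzero standards (the blank's log is undefined; it enters only through the
LOD). R² is 1 − SS_res/SS_tot, computed explicitly so that a zero-variance
(degenerate) fit is reported as undefined rather than as 1. A 4PL fit was
considered and rejected as the default: with five standards over four
decades and a single quality statistic, the two extra parameters are not
identifiable enough to be worth it.

The earliest reliable time is the first grid time from which R² stays at or
above the threshold **for the rest of the grid** (a sustained crossing);
early single-point crossings on a fluctuating trajectory are not treated as
reliable.

LOD follows the blank ± 3·SD convention: the blank mean shifted by k·SD in
the direction of increasing concentration (down for a falling signal such
as the red ratio) is inverted through the fitted line. With only two blank
chambers the SD estimate is crude; the estimator refuses fewer than two
replicates and a flat curve.

The metric-concordance screen identifies the discordant replicate chip as
the one farthest from the median reference OD, computes the candidate
metric's CV over the remaining (concordant) chips, and checks that the
metric singles out the same discordant chip. The chip check is
direction-agnostic because decreasing-color metrics (red ratio) legitimately
anti-correlate with OD.

## Synthetic assay generator

The generator emulates the imaging, not the chemistry. Per chamber, the
noise-free red-channel ratio follows

    ratio(t; c) = 1 − A(c)·(1 − e^(−k t)),   A(c) = A_max · c/(c + c50),

blue stays constant and green drops at half the red rate. Defaults, chosen
once for realism:

| parameter | default | rationale |
|---|---|---|
| k (rate) | 0.002 /s | development time constant ~8 min: color still rising at 100 s, near its endpoint on the conventional 15-min scale |
| A_max | 0.6 | strong blue at saturating antigen leaves ~40% of the initial red |
| c50 | 30 ng/mL | near the geometric center of the 1–1000 ng/mL standards, so A(c) is approximately linear in log10(c) over all four decades (noise-free endpoint R² ≈ 0.97) — the regime in which a log-linear calibration is the right model |
| illumination | 1.00 … 0.75 across chambers | lateral strobe: brightness falls with distance |
| jitter | lognormal, σ = 1% | flash-to-flash strobe variation |
| flashes | p = 0.02/frame, +20% | occasional large excursions, the artifact the 5%/s rule targets |
| pixel noise | σ = 0.004 (≈1 LSB) | sensor noise |
| frames | 1/s for 600 s | readout grid |

The disk carries two blank chambers and the 1/10/100/1000 ng/mL standards.
The ground truth exposes the analytic traces, the jitter/flash draws, and
the generator's log-linear slope (the OLS slope of the noise-free endpoint
signal vs log10(c)) used as the recovery target.

What the generator does **not** model — and what passing tests therefore do
not show about real data: per-chamber (non-global) illumination
fluctuations, motion blur and strobe-timing error, meniscus and bubble
optics, chemical lag or depletion kinetics deviating from a single
exponential, and JPEG compression artifacts (PNG fixtures are lossless;
a JPEG mode exists and is verified to move ROI means by < 2/255). Because
the strobe jitter is global, it cancels across chambers and the simulated
R²(t) is high almost from the start; on real instruments chamber-local
noise delays the reliable read time, which is why the sustained-crossing
rule and the read-time/slope distinction matter in practice.

## Problem sizes

The default test-and-acceptance experiments use 601-frame assays
(60×360 px, 6 chambers) and 20 seeds for the stochastic suites — the
smallest sizes at which the sampling error of the reported medians is
clearly below the acceptance margins.

## Known limitations

* The ratio metric cancels only *static, multiplicative* illumination;
  additive stray light or time-varying gradients would not cancel.
* The hue ratio divides a branch-adjusted angle by the reference angle;
  hue is best consumed as raw or difference.
* The LOD carries no uncertainty interval.
* Chamber ROIs come from a geometry config; there is no auto-detection.
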