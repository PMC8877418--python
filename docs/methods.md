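# Methods

## Measurement model

A cantilever-based EHT platform reports tissue force through post bending.
Two PDMS posts (length L = 3 mm, circular cross-section of radius R) carry a
tissue attached at height *a* above the base; the post tops are stained with
carbon black so they appear as two dark discs in brightfield video. During a
twitch the tissue shortens, both posts bend inward, and the inter-marker
distance shrinks by δ(t). For a slender elastic beam with a point load at
height *a*, Euler–Bernoulli theory gives the tip deflection
δ = F a²(3L − a) / (6EI) with I = πR⁴/4, hence

    F = 3πER⁴ δ / (2a²(3L − a)).

Assumptions: small deflections (linear elasticity, no Timoshenko shear or
large-deflection correction), a rigid marker disc that translates with the
post tip, and a load that acts at a single height. δ is the *total* change of
the inter-marker distance, fed into the equation as printed; users who prefer
the per-post convention can set `per_post_deflection: true` in the config,
which halves δ. The measured marker displacement is used directly as the
tip deflection without a height correction for a < L.

All internal mechanics arithmetic is SI; reporting units are µm, µN and µN/s,
chosen to match the magnitudes typical of EHT work. The default geometry
ships with L = 3 mm and deliberately labelled placeholders E = 2.0 MPa,
R = 0.25 mm, a = 1.5 mm — plausible for Sylgard 184 cured at 1:10 and posts
of this size, but absolute forces are only meaningful after the user
calibrates E, R and a for their platform. Every output table records the
geometry it was computed with.

## Marker detection and tracking

Detection is a global Otsu threshold on the inverted frame, connected
components, and two filters: area within [min_area, max_area] px² (default
20 px² to a quarter of the frame) and circularity 4πA/P² ≥ 0.5. Sub-pixel
localization uses the intensity-weighted centroid of the inverted image
within each blob; the anti-aliased disc edge makes this accurate to well
under a tenth of a pixel on synthetic discs (the suite enforces < 0.25 px
noiseless and < 0.5 px at 5% sensor noise).

Tracking keeps the two blobs nearest the previous frame's pair (first frame:
the two largest blobs, area ties broken by leftmost x; candidate assignment
minimizes the summed left/right distance). Frames with fewer than two
surviving detections are bridged by linear interpolation of the centroid
coordinates and flagged, up to `max_gap` consecutive frames (default 5, i.e.
50 ms at 100 fps — shorter than any twitch phase at 1 Hz); longer gaps abort
with the frame range named, since silently extrapolating through a long
dropout would fabricate kinetics.

The relaxed ("baseline") inter-marker distance is the maximum distance over
the recording rather than the first-frame distance, because a recording may
start mid-twitch; it can be overridden in the config when the resting
distance is known. With this convention δ ≥ 0 by construction; negative
forces can still appear when a user supplies a smaller baseline, and they are
reported rather than clipped because they flag baseline mis-estimation.

## Twitch segmentation and features

Paced recordings are segmented into one window per pacing period. Peaks are
found with a prominence gate (`prominence_frac` × global amplitude, default
0.2, floored at 4× a robust noise estimate from first differences); within a
period the largest peak wins, which discards ectopic secondary peaks. Window
boundaries sit at the *center* of the near-minimum plateau between
successive peaks, not at the raw argmin: with sensor noise the argmin can
land immediately before the next upstroke, which would contaminate the
baseline estimate of the following beat. Windows whose boundary samples sit
more than 30% of the global amplitude above the global minimum are treated
as incomplete first/last beats and discarded. Without a pacing frequency the
same procedure runs with the period estimated as the median peak spacing.

Per beat: baseline = mean of the leading 10% of the window; amplitude =
peak − baseline; upstroke onset = last baseline crossing before the peak;
t10/t90 of contraction = time from onset to the first crossing of
baseline + 0.1/0.9 × amplitude; t10/t90 of relaxation = time from the peak
to the first crossing of baseline + 0.9/0.1 × amplitude (i.e. 10%/90% of
relaxation completed). All crossings are linearly interpolated between
samples, making the timings sub-frame accurate. Velocities are the extrema
of the Savitzky–Golay-smoothed derivative (window 11 samples, order 3 at
100 fps; both configurable) over the upstroke and decay — the smoothing
suppresses pixel-quantization noise without materially biasing peak dF/dt
(< 0.1% on a 0.4-s raised cosine at 100 fps). Velocities are reported in
µN/s; the µm/s marker-speed equivalent is the same number divided by the
beam constant and is available by running the kinetics on the deflection
trace directly. Garbage windows (no amplitude, no baseline crossing, no
completed relaxation) are excluded from the recording summary rather than
poisoning it. Summaries use the sample (n−1) standard deviation, reported as
exactly 0 for a single beat or identical values.

## Dose–response

Negative inotropy is summarized by a descending Hill fit
r(c) = 1/(1 + (c/IC50)^h) with top fixed at 1 and bottom at 0: responses are
normalized to the same tissue's 0-concentration amplitude (so the top is 1
by construction) and a saturating L-type calcium-channel block abolishes
contraction (bottom 0). Fixing both asymptotes stabilizes fits on the short
5–7 point series these experiments produce; `free_bottom` enables a floating
lower asymptote. The optimizer is bounded least squares over
(log10 IC50, h), multi-started from 16 log-spaced IC50 seeds spanning the
tested non-zero concentration range with h seeded at 1; the best of all
starts is returned with a convergence flag and residual RMS. The
0-concentration anchor is excluded from the fit domain (log 0 undefined).
Degenerate inputs — fewer than four distinct non-zero concentrations, flat
or overall non-decreasing responses — return a flagged failure instead of
raising, so batch runs continue. Per-tissue normalization always precedes
cross-tissue averaging; the two orders genuinely differ and the pooled order
would weight strong tissues more.

Positive inotropy (gain of force/velocity) is the plain difference of
treated and baseline mean amplitude/velocities of the same tissue; a tissue
identifier mismatch is an error because unpaired gains are meaningless.

## Morphometry

Tissue area: Otsu threshold (dark tissue on light background, polarity
configurable), largest connected component, hole filling, pixel count ×
(pixel size/1000)². A hand-traced binary mask can be supplied instead to
reproduce manual tracing. Early compaction is the day-5 area over the 11 mm²
seeding footprint; late compaction is the day-11/15/20 area over the same
tissue's day-5 area. Success of tissue formation is a visual judgment and is
taken as annotated input; the success rate is reported both exact and
rounded to the nearest integer percent, matching how such tables are
reported. Seeding dose is concentration × volume with 3-significant-figure
half-up rounding alongside the raw count.

## Synthetic data: what it emulates and what it does not

The generators emulate the study's acquisition conditions: 10-s recordings
at 100 fps, 1 Hz field pacing, two dark ~1 mm marker discs on a light
background, and dose series on a descending Hill curve. Twitch trains are
raised cosines (or an asymmetric two-phase variant with separate rise/decay
raised cosines, `rise_fraction` controlling the split) with duty 0.4 of the
period and a 0.3-period rest phase before each upstroke. Videos are rendered
with 4× supersampled anti-aliasing so the programmed sub-pixel centroids are
exact ground truth; noise models are additive Gaussian sensor noise and slow
sinusoidal illumination drift, the two dominant brightfield artifacts. Every
generator is a pure function of its seed.

What the synthetic data does *not* contain — and therefore what passing
tests do not demonstrate about real recordings: post bending curvature in
the image (markers translate rigidly), tissue debris or out-of-focus blur,
contrast drift that reverses marker/background polarity, beat-to-beat
variability and arrhythmia, and baseline wander from stage drift. Tracking
accuracy on real data should be validated against a few hand-measured
frames.

## Numerical and design choices

- Default synthetic study conditions: 10-s, 100-fps, 1-Hz-paced recordings;
  twitch duty 0.4; 2 µm/px calibration; sensor noise up to 5% of the dynamic
  range; dose tables with six log-spaced concentrations and σ = 0.03
  response noise. Recovery benchmarks run 20 tracking videos and 9 × 100
  seeded Hill replicates — large enough for stable medians on one CPU.
- Intensities are normalized to [0, 1] on load (integer bit depth removed at
  the boundary); grayscale conversion is an unweighted channel mean since
  the markers are near-black on a light background.
- Acquisition metadata (frame rate, pixel size) is always explicit user
  input; container tags are not trusted.
- Crossing times use linear interpolation; tie-break for equal-area blob
  seeding is leftmost x; coordinates are (x right, y down) with pixel
  centers at integer positions.
- The force conversion is exact arithmetic on the closed form; the suite
  pins it to an independently coded Euler–Bernoulli oracle at < 1e-12
  relative error over randomized geometries.

## Known limitations

- Absolute force accuracy is bounded by the user's calibration of E, R and
  a; the package validates the formula, not the constants.
- AVI input requires an ffmpeg-capable imageio plugin at run time; TIFF is
  the first-class path.
- One marker pair per recording; multi-tissue fields are handled by running
  per ROI.
- The Hill fit assumes a monotone descending response; agonist (ascending)
  curves are out of scope beyond sign diagnostics.
- Segmentation assumes a rest phase between twitches; fused tetanic
  responses at high pacing rates will be rejected as incomplete beats.
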