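# Methods

This note documents the models, defaults and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Physical conventions

Pixel indices are 0-based; centroids are continuous physical coordinates
in nm at pixel centers; voxel bins are half-open intervals
`[k*v, (k+1)*v)`. Default calibration: 84 x 84 nm lateral pixels, 500 nm
optical slices, 19.2 um mapping voxels. All randomness flows from one
master seed, split per stage by hashing `"<seed>:<stage>"` (SHA-256,
truncated to 31 bits), so stages are independently reproducible and a
rerun with the same config and seed is byte-identical. Provenance headers
therefore omit timestamps unless explicitly requested.

## Synthetic data

`synth_image` renders isotropic 2D Gaussian spots (sigma 123 nm, the
scale of a diffraction-limited spot at ~290 nm FWHM resolution) with
lognormal peak amplitudes (log-sd 0.4) on a constant background of 100
counts, then applies Poisson shot noise and Gaussian read noise (sd 2).
SNR is defined as median peak amplitude over background noise sd
`sqrt(background + read_noise^2)`; the default scene is SNR 5 at ~0.5
puncta/um^2, a deliberately hard low-SNR regime. Colocalized pairs are
constructed by displacing a channel-2 spot from a channel-1 spot by a
fixed radius (default 100 nm) at a uniform angle, which makes the 500 nm
pairing rule exactly scorable against the emitted truth table.

What the generator does *not* emulate: anisotropic/defocused PSFs, optical
sectioning and z-blur, tissue autofluorescence structure, uneven
illumination, and spatially correlated background. Passing detection
benchmarks here demonstrates the machinery is correct and robust to
shot-noise-limited low SNR, not that the trained classifier transfers to
real tissue; on real data the classifier is meant to be retrained from
the provided annotation-table path.

`synth_param_table` plants a Gaussian mixture per type with component
counts 11/7/19 (mirroring the catalog structure), identity within-component
covariance, Dirichlet(5) component weights, and component means placed by
rejection sampling with a minimum pairwise distance of `separation` sd
(default 6). Six is chosen as a clearly separated regime in 6 dimensions
(cluster radius ~sqrt(6) sd); at the minimum distance some index-based
cluster-count decisions become genuinely ambiguous (see Limitations).

`synth_spike_trains` provides homogeneous Poisson trains and a bursty mode
(Poisson burst onsets, regular intra-burst pulses) as stand-ins for
recorded cortical spike trains.

## Detection

The nonlocal-derivative feature at scale `s` and orientation `theta` is
the patch-averaged oriented second difference
`2*B(x) - B(x + d) - B(x - d)`, with `B` a box mean of half-width
`max(1, round(s/2))` (replicate borders) and `d = round(s*(sin, cos))`.
Banks: PSD95 4 scales (2, 4, 6, 8 px) x 8 orientations + a
center-contrast feature = 33 features; SAP102 13 scales (1..13 px) x 8
+ 1 = 105. The exact grids behind those two dimensionalities are not
published; these are conforming choices that reproduce the printed counts
with a simple, auditable operator. Features are differences, hence
invariant to additive background; candidates come from a quantile
threshold (default 0.5 of nonzero pixels — intentionally permissive) and
local maxima with 3 px minimum separation, refined by 3x3 center of mass.
The classifier is a 100-member bagged decision-tree ensemble; training
labels come from synthetic ground truth (candidates within 3 px of a true
centroid). Stacks are max-projected before detection.

## Measurement and colocalization

Each punctum is segmented inside its watershed zone at 10% of the zone's
maximum intensity, making size/shape measures independent of absolute
brightness. Skewness and kurtosis are the standardized 3rd and 4th
(excess) moments of within-mask intensities; circularity is `4*pi*A/P^2`
with a Crofton perimeter estimate; aspect ratio is the axis ratio of the
baseline-subtracted intensity-weighted second-moment ellipse. Single-pixel
masks yield null shape metrics but the punctum is retained.

Colocalization matches cross-channel puncta with lateral (xy) centroid
distance strictly below the threshold (default 500 nm, the scale of one
postsynaptic density; 600 nm and 300 nm presets exist for presynaptic
juxtaposition and striatal-compartment analyses). Matching is greedy by
ascending distance with ties broken by row order, so each punctum joins at
most one pair; this equals an exhaustive matcher on all tested inputs.
Distance is 2D because section geometry makes the criterion lateral-scale;
a randomized control (toroidal translation of one channel) estimates
chance-level pairing.

## Subtype catalog (weighted ensemble clustering)

Within each type, parameters are z-scored and clustered by 8 base methods
(k-means, mini-batch k-means, diagonal-covariance Gaussian mixture, ward/
average/complete hierarchical, spectral on a cached rbf-Laplacian
embedding, BIRCH) over cluster counts 1..30 (the full-scale analysis used
1..300; the range is a config field). Each labeling is scored by 11
validity indices — silhouette, Calinski–Harabasz, inverted Davies–Bouldin,
Dunn, inverted Xie–Beni, gap statistic (uniform reference, 3 draws),
inverted WSS/BSS, PBM, inverted C-index, point-biserial, and a bootstrap
1-NN stability ARI — min-max normalized across the pool; indices undefined
at k = 1 take the pool minimum, so only the gap statistic can argue for a
single cluster. A labeling's weight is its mean normalized index. The
cluster count is taken from the highest-validity results (max weight per
k), and the final partition cuts the weighted co-association matrix with
average linkage at that count.

The quadratic consensus runs on a seeded subsample (default 1000 rows);
remaining rows join the nearest consensus centroid in z-space. Global
subtype indices are blocked type 1, then 2, then 3, ordered by descending
population within a type.

## Maps and networks

Voxel maps bin puncta by centroid on the 19.2 um grid; diversity is
`-sum p_i log2 p_i / log2 37` of the per-voxel subtype composition (1 =
all 37 subtypes equally dense, 0 = a single subtype); the dominant-subtype
map is the argmax with ties to the lowest index. Region signatures report
density per 100 um^2 and aggregated parameters (median for map products,
mean for similarity inputs — both appear in the source material, so both
are supported and recorded in provenance). Similarity is a Gaussian kernel
on Euclidean distances between z-scored signatures with bandwidth set to
the median pairwise distance (the original bandwidth is unpublished; the
median heuristic is the standard self-tuning choice); the subtype variant
is the Pearson correlation of 37-subtype density vectors rescaled
`(r+1)/2` to keep the similarity in [0, 1] (raw r is also emitted).
Dendrograms are UPGMA on `1 - similarity`.

Networks binarize the similarity at the top 5% of off-diagonal entries
(ties broken by region order). Small-worldness uses degree-preserving
rewired nulls (20 by default, 10 attempted swaps per edge); path length is
averaged over reachable pairs with the disconnected fraction reported;
modularity is greedy agglomerative maximization (checked against
exhaustive partition search on small graphs in the tests).

## Genotype comparison

Cohen's d uses the pooled standard deviation
`s = sqrt(((n1-1)s1^2 + (n2-1)s2^2)/(n1+n2-2))`. The Bayesian model gives
each region x genotype cell a t-likelihood whose scale sigma_j depends on
region only; sigma_j ~ Gamma(mode omega, sd sigma_sigma) with omega and
sigma_sigma themselves gamma-distributed, modes set to the median of cell
sds and spreads to the sd of cell sds. Cell means get a vague normal prior
(data mean, 5x data sd); normality nu - 1 is exponential with mean 29.
The model is parameterized directly in cell means (the original two-factor
baseline+deflection form reduces to this for the pairwise contrast that is
the only quantity used downstream). The sampler is adaptive
Metropolis-within-Gibbs, 4 chains vectorized in numpy, default 5000
iterations after 1000 warmup, with split-chain R-hat < 1.1 as the
convergence flag (non-convergence is flagged, not fatal). The pseudo
p-value is `1 - c*`, with `c*` the largest credibility whose shortest
(HDI) interval of the genotype mean difference excludes the ROPE
±sigma_j/3 (posterior-median sigma_j); BH correction runs across regions.
Simulation tests show nominal-or-better type-I behavior and full power at
2-sd shifts with n = 50 per cell.

## Short-term plasticity model

Per spike, depression and facilitation multipliers accumulate over all
preceding spikes in the pattern (no truncation — patterns are short):

    A_td = max(1 - sum_i A_d exp(-dt_i/tau_d), 0)
    A_tf = min(1 + sum_i [A_f exp(-dt_i/tau_f) + A_s exp(-dt_i/tau_s)], 3.3)

The depression combination is written as one minus the summed history
(clipped at zero): the alternative reading "sum of (1 - A_di)" grows
without bound in the spike count and contradicts the stated positivity
clip, so it is rejected; both forms coincide for a single preceding spike.
Amplitudes are normalized to the first response. The EPSP kernel is
bi-exponential with tau1 = 3.0 ms, tau2 = 0.4 ms (analytic peak at
0.930 ms); the kernel's peak constant cancels under map normalization.

Bundled parameter sets (amplitudes a.u., taus ms):

| set | A_d0 | tau_d0 | A_f0 | tau_f0 | A_s0 | tau_s0 |
|---|---|---|---|---|---|---|
| control | 0.25 | 130 | 4.9 | 13 | 0.458 | 60 |
| psd95   | 0.022 | 140 | 7.3 | 13 | 0.458 | 60 |
| psd93   | 0.1 | 440 | 4.4 | 13 | 0.458 | 60 |

Stimulation patterns: theta-burst (4-pulse bursts, IPI 25 ms, IBI 125 ms),
theta (IPI 200 ms), gamma (IPI 25 ms), gamma doublets (IPI 13 ms, IBI
300 ms), and a fixed mixed pattern (25, 50, 120, 145, 205, 270, 310 ms).
The interburst interval is read as the gap from a burst's last pulse to
the next burst's first pulse, making theta-burst onsets 5 Hz, consistent
with the 10-bursts-at-5-Hz protocol the control parameters were fitted to;
an onset-to-onset mode is available.

Spatial fields scale `A_d, tau_d` by tangential/radial PSD95 size factors
and `A_f, tau_f` by the SAP102 factors (slow facilitation is spatially
constant), interpolating normalized profiles with cubic B-splines onto a
101-synapse tangential axis or an 11 x 11 grid. Factors are floored at
0.05 to keep scaled time constants positive (the floor is a package
choice). Fitting is Nelder–Mead least squares on log-parameters
(positivity by construction) with seeded jittered restarts, because
cap/floor saturation creates flat objective regions that can stall a
single simplex run; knockout-style refits free only `A_d0, tau_d0, A_f0`.

## Problem sizes

Defaults are desk-scale so the whole suite runs in minutes on one core:
192 px benchmark images (~130 puncta/channel), 20,000-row mixtures with a
1000-row consensus subsample, k up to 30, 20 network nulls, 4 x 5000 MCMC
iterations (tests use shorter chains via the exposed config). The original
study operated on ~1e9 puncta and ~800 regions; nothing in the interfaces
precludes larger inputs, but the consensus subsample and k-range should be
raised accordingly.

## Known limitations

- Cluster-count selection can be off by one when two planted components
  sit near the minimum separation; the consensus partition remains
  accurate (ARI > 0.95) even then.
- Detection operates on max projections; no 3D PSF model or per-slice
  detection.
- The NLD feature operator and the scale/orientation grids are conforming
  reconstructions of an under-specified prior operator, chosen to match
  the printed feature counts.
- The Bayesian sampler is a random-walk scheme; for very small cells or
  heavy imbalance, longer chains may be needed (R-hat is reported).
- The exact ROPE p-value construction is the natural reading of a
  paraphrased definition (largest HDI mass excluding the ROPE).
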