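# Methods

## Measurement model

A spectral cytometer records each event across all detectors (48 on the
four-laser instrument modelled here: violet 405 nm, blue 488 nm,
yellow-green 561 nm, red 640 nm). The detector readout of a cell is modelled
as a linear mixture

    y = M a + c·s_AF + ε,

where the columns of `M` are the unit-norm reference spectral signatures of
the panel's fluorophores, `a` the per-fluorophore abundances, `s_AF` the
cellular autofluorescence spectrum with per-cell magnitude `c`, and `ε`
detector noise. Unmixing solves the unconstrained ordinary-least-squares
problem per event via `numpy.linalg.lstsq`; negative abundances are
retained, not clipped — they carry the noise information that downstream
gates and QC statistics rely on. Autofluorescence is handled by appending
`s_AF` as one extra endmember, so its abundance is estimated jointly and
removed from the marker estimates; `s_AF` itself is the per-detector
**median** of an unlabeled control (median rather than mean, because real
controls contain debris and doublet outliers). Adding a true endmember can
only enlarge the least-squares span, so the fitted residual never increases
— a property the test suite asserts.

Rank deficiency of `M` (e.g. two identical signatures) is detected before
solving and reported with the most collinear pair, since a silent
pseudoinverse solution would distribute signal arbitrarily between the
colliding dyes.

### Similarity index

Panel compatibility is screened with the cosine similarity of unit-norm
emission profiles: 0 for spectrally disjoint dyes, 1 for identical spectra.
The vendor metric of the same name is not publicly defined; cosine
reproduces its stated endpoints and is symmetric and bounded, which is all
the 0.98 compatibility rule requires. Pairs above the threshold (default
0.98) are reported as design violations. No whole-panel "complexity"
metric is provided: the vendor formula is proprietary, and we prefer to
ship no number over an incomparable one. (The condition number of `M` is
one line of numpy for users who want a conditioning diagnostic.)

### Compensation

Residual post-unmix spillover is corrected with a percent-coefficient
matrix `C` (diagonal 100): `compensated = values · inv(C/100)`. Coefficients
are interpreted as percent of the *unmixed source channel* leaking into the
target — the convention under which a correction such as "−2.79 from one
conjugate into another" is a single off-diagonal entry. An identity matrix
is the identity map.

## Gating

Gating operates on arcsinh-transformed unmixed intensities,
`z = asinh(x / cofactor)` with cofactor 6000 by default (a common choice for
spectral data that keeps negatives near zero while compressing the bright
decades). Gate trees are declarative YAML: threshold terms
(`+`, `-`, `hi`, `lo`, `int`, `all`), 2-D scatter rectangles/polygons
(evaluated in raw scatter units), and boolean connectives. Intervals are
half-open with ties assigned to the positive side, so an event exactly on a
cutoff is positive and sibling quadrants partition their parent *exactly* —
an invariant the engine asserts on every run.

Default cutoffs are shipped per panel in raw units and transformed at load
time: positive at 500, high at 10 000, intermediate band [200, 2000). Real
instruments need per-marker, per-sample adjustment; the QC module's
`split_peaks` (deepest histogram valley between the two largest modes)
provides a data-driven estimator, and per-marker overrides are a config
entry. Basophil CD45^int uses the same static intermediate band as every
other `int` term rather than a sample-derived percentile rule — one
convention across the DSL, no dependence on a lymphocyte-mode fit.

Pre-gating applies, in order: singlets (FSC-A/FSC-H ratio within ±15% of
the modal ratio — a doublet carries roughly doubled area at singlet
height), a low-scatter exclusion standing in for red-blood-cell/debris
removal (none of the panels carries an RBC marker, so scatter is the only
available handle; the exact published gate geometry is figure-only),
viability-dye-negative, and CD45⁺.

Events can satisfy several canonical gates (negative-selection gates such
as the T/B panel's NK definition overlap specific deeper gates). Canonical
assignment therefore takes the **deepest** canonical node containing the
event, with ties broken by configuration order; the shipped panels list
more specific populations (Tregs, Th subsets, MDSC gates) before their
broader siblings. This convention is the package's own — published
workflows resolve the same ambiguity by the order in which an analyst draws
gates.

## Synthetic data

The simulator emulates the full measurement chain so that
simulate → unmix → pre-gate → gate is a closed loop with known truth.

**Population templates.** Marker expression levels per population are drawn
lognormal on the raw scale:

| level | median | sigma |
|-------|--------|-------|
| neg   | 50     | 0.5   |
| int   | 800    | 0.5   |
| pos   | 5 000  | 0.4   |
| hi    | 20 000 | 0.4   |

Templates are derived mechanically from the gating trees
(`templates_from_gating`): the conjunction of threshold terms along a
canonical population's root path, unconstrained markers negative, plus a
panel-level baseline (CD45 positive on every cellular template — the CD45⁺
pre-gate is not part of the tree) and per-population overrides where the
mechanical inversion is biologically wrong in a way that matters for gate
disambiguation (B cells carry HLA-DR; Tregs and Th subsets generate with a
CD197⁺ memory phenotype so they do not collapse into the effector CD27/CD28
quadrants). A canonical node fully covered by deeper canonical gates (e.g.
"Effector CD8", partitioned by its four CD27/CD28 children) is not
generable as a distinct identity and is skipped in favour of its children.
Default per-population frequencies ship in the panel YAMLs; they are broad
physiological values describing one plausible donor, chosen once, and both
PBMC panels describe the *same* donor (≈70% lymphocytes, ≈10% NK) so the
cross-panel consistency ratios are meaningful.

**Spectra.** `make_signature_set` builds smooth Gaussian-bump emission
profiles with a small secondary cross-laser bump, shrinking widths until
the requested maximum pairwise similarity holds; target 0 yields
single-detector (orthonormal) spectra. The shipped libraries use a maximum
pairwise similarity of ≈0.47 (normal-equation condition numbers 11–36).
This is deliberately better-separated than the 0.98 design bound: a 1-D
bump model at 0.98 similarity is near-singular in a way real 48-detector
spectra — which differ in fine structure across many detectors — are not,
and it would model a failed panel rather than a validated one. The
libraries are synthetic stand-ins (`*_signatures_synthetic.csv`); no
published reference spectra exist in machine-readable form.

**Noise and artifacts.** Detector noise is Gaussian with
SD = 5 + 0.02·signal (a floor plus a shot-noise-like term). Doublets sum
two singlets' detector and scatter-area signals while keeping the taller
height; dead cells take up the viability dye (hi level); RBC-like debris is
low-scatter with near-zero marker signal. Scatter populations are Gaussian:
lymphocyte FSC-A 50 000 ± 5 000, monocyte 90 000 ± 7 000, debris
12 000 ± 4 000 (arbitrary instrument units, separated enough that scatter
gates are not the accuracy bottleneck). Batch effects are per-channel
multiplicative gains and additive offsets applied to marker abundances
before mixing; a donor-unique population can be injected into one batch.

**What the simulator does not emulate** — and therefore what passing tests
do *not* establish about real data: spillover-spreading error (noise
correlations after unmixing), biological marker correlation beyond the
template logic (every marker is conditionally independent given the
population), instrument drift within a run, batch-varying spectra, and
continuous expression gradients between populations. Gating recovery of
≥99% on simulated defaults demonstrates the engine and the
template/threshold logic are mutually consistent at realistic separations;
it does not promise 99% accuracy on instrument data, where gate placement
dominates.

All randomness flows from a single integer seed; outputs are
bit-reproducible.

## Integration and batch assessment

Channels are scaled per channel by plain min-max to [−1, 1]
(`x → −1 + 2(x−min)/(max−min)`): the range is exactly [−1, 1] centered on
0. (Median-centering before a single affine map cannot put *both* extremes
at ±1 on skewed fluorescence data, so the range-based reading is the one
implemented; constant channels map to zero with a warning.) PCA keeps 20
components by default, computed with a full SVD and a deterministic sign
convention (largest-magnitude loading positive).

**LISI.** For each cell, a Gaussian kernel over its k nearest neighbors
(k = 3 × perplexity, perplexity 30, self excluded) has its bandwidth tuned
by bisection so the kernel entropy equals log(perplexity); kernel mass per
batch gives probabilities p_b and LISI = 1/Σp_b², clipped to [1, B]. When
all neighbor distances are equal the kernel is uniform by construction.
LISI is computed in 2-D UMAP space by default (with a PC-space option; the
two differ and the methods of record compute it on UMAP coordinates). The
high-LISI thresholds ship only for the two published cases — >2 for three
batches, >1.667 for two; any other batch count requires an explicit
threshold rather than an invented general rule. Correction is recommended
iff the high-LISI fraction is below 20%.

**Reference corrector.** In PC space, iterate: soft k-means assignment
(k = 20 clusters, unit temperature), per-cluster per-batch centroid offsets,
subtraction of assignment-weighted offsets; stop when the mean-LISI gain
drops below 0.01 or after 10 iterations, and never accept an iteration that
decreases mean LISI. The first pass uses a single cluster (global per-batch
centering): when batches are fully segregated, k-means clusters are
batch-pure and per-cluster offsets vanish, so the global pass is what
brings batches into contact before cluster-resolved passes refine
per-cell-type offsets. This corrector is contract-tested (mean LISI
non-decreasing; shift-only batch centroids collapse below 10% of their
pre-correction distance; event counts and truth labels untouched), not
output-matched to any published integration. An `external` backend hook
delegates to harmonypy when installed.

UMAP is a pluggable external backend (umap-learn) with a fixed seed;
determinism holds per that library's random_state contract. Corrected
coordinates can be appended to the event matrix as derived parameters and
written back to FCS.

## File formats

FCS is written as version 3.1, list mode, 32-bit float little-endian —
the output convention of modern spectral instruments; FCS 3.0 and 3.1 are
read. `$PnN` carries the detector/fluorophore token and `$PnS` the marker
token, so gating configs refer to markers and stay instrument-agnostic.
Channel kinds round-trip through nonstandard `CSKINDn` keywords and are
inferred from names for foreign files. CSV export is comma-separated,
UTF-8, full float precision, one row per event.

## Numerical and degenerate-case conventions

- Events exactly on a cutoff are positive (half-open intervals).
- Percent-of-parent of an empty parent is defined as 0.
- A zero-event population is excluded from heatmap matrices with a warning;
  a single-population or constant-column scaled matrix is defined as 1.
- Heatmap clustering is average-linkage Euclidean on the scaled matrix with
  populations lexicographically pre-sorted, making tie-breaks deterministic.
- `compute_lisi` reduces k with a warning when k ≥ n.
- The stain index uses the plain SD as defined; all other QC spread
  estimates use 1.4826 × MAD (heavy-tailed cytometry noise).

## Known limitations

- Weighted/Poisson least-squares unmixing variants are out of scope; OLS
  treats all detectors as equally noisy, which understates bright-channel
  error.
- The reference batch corrector removes location shifts per cluster; it
  does not correct batch-specific scale or shape differences (the clipping
  of negative-offset channels in the simulator produces exactly such
  distortions, and residual LISI deficits after correction are expected
  there).
- Gate cutoffs are global per panel by default; real analyses adjust them
  per sample and marker.
- The shipped panel marker lists reconstruct published gating tables; the
  full reagent catalogues (clones, exact conjugates) are not modelled.
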