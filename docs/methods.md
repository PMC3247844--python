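# Methods

## The assay

The package quantifies viability of unicellular cyanobacteria from
two-channel fluorescence micrographs taken in a calibrated counting
chamber. The biological signal is binary: chlorophyll a in viable cells
autofluoresces red; dead cells lose chlorophyll and show a residual,
unspecific green autofluorescence at the same excitation wavelength. A
cell is therefore expected to be bright in exactly one of the two
channels, and the green channel alone carries the class information.

Pipeline per field (deterministic; identical bytes in, identical results
out):

1. split the RGB image into red and green channels;
2. threshold each channel automatically with the Kapur–Sahoo–Wong
   maximum-entropy criterion;
3. OR-combine the two foreground masks;
4. register connected components ("particles") and measure pixel area,
   physical area (pixels × µm/px²), centroid, and the mean of each RAW
   channel over the component;
5. discard particles with area < 35 µm² (artifact filter);
6. class each surviving particle: non-viable iff mean green intensity
   > 50 (strict), else viable.

Counts are pooled over all fields of a run and converted to
concentration with the chamber constants (below).

## Maximum-entropy thresholding

For a 256-bin histogram with probabilities `p_i` and `P_t = Σ_{i≤t} p_i`,
the threshold maximises

    H_b(t) + H_f(t),
    H_b(t) = −Σ_{i≤t} (p_i/P_t) ln(p_i/P_t),
    H_f(t) = −Σ_{i>t} (p_i/(1−P_t)) ln(p_i/(1−P_t)),

with empty bins contributing zero (the limit x ln x → 0). Numerical
choices, each of which can change the returned level by a bin or two and
is therefore fixed and documented:

- natural logarithm (the argmax is base-invariant; ln makes the oracle
  reproducible to the last ulp);
- candidates that leave either class empty are skipped rather than scored
  −∞;
- ties break to the smallest t;
- a histogram with fewer than two occupied bins raises a
  degenerate-histogram error rather than guessing. In the full pipeline a
  degenerate channel is legitimate — a fully viable culture has an empty
  green channel — so that channel simply contributes no foreground, and
  only a field with both channels degenerate logs a warning and counts
  nothing.

The production path uses cumulative sums (O(levels)); an exhaustive
O(levels²) oracle recomputes both entropies literally at every candidate
and must agree exactly — this equivalence is asserted over randomised
histograms in the test suite and the acceptance script. One behaviour
worth knowing: for two well-separated modes of unequal width the
criterion can legitimately place the threshold inside the wider mode
(it balances class entropies, it does not seek the valley); only clean
bimodal histograms pin it to the gap.

## Parameters and defaults

| parameter | default | unit | meaning |
|---|---|---|---|
| `min_area_um2` | 35.0 | µm² | artifact filter; strict (`< 35` dropped, `= 35` kept) |
| `green_cutoff` | 50.0 | 8-bit intensity | class boundary on mean green; strict (`> 50` non-viable) |
| `imaged_volume_ul` | 0.084 | µl | TOTAL chamber volume covered by all fields of one run |
| `dilution_factor` | 2.0 | — | undoes the 1:2 glycerol mixing (final conc = ½ original) |
| `connectivity` | 8 | — | particle connectivity (4 available) |
| `include_edge_particles` | true | — | border-touching particles counted |

`concentration = n_total / imaged_volume_ul × 1000 × dilution_factor`,
so 2100 pooled cells over 0.084 µl at dilution 2 give exactly
5.0 × 10⁷ cells/ml.

The green cutoff of 50 is an empirical constant of the original imaging
setup; it is exposed in the configuration precisely because no claim of
transferability across microscopes, filter sets or exposure settings is
made. "Mixed 1:2 with glycerol" is read as final concentration = one half
of the original (factor 2.0); if the protocol is read as 1 part culture +
2 parts glycerol, set `dilution_factor = 3.0`.

All analysis is performed on 8-bit intensities because both fixed
intensity constants (50, and the max-entropy histogram) presuppose the
[0, 255] range; 16-bit input is linearly rescaled by its per-image
maximum at ingest and the factor logged. Spatial calibration is an
explicit required parameter, never read silently from image metadata.

Design choices where the convention was genuinely open: edge-touching
particles are included by default (chamber fields are imaged away from
the grid, and no border-exclusion rule is part of the assay), mean
intensities are measured on raw channels (a cutoff of 50 is meaningless
on a binary mask), no hole filling or watershed splitting is performed,
and classification uses only the green mean — the red mean is recorded
per particle for auditing but plays no part in the rule.

## Colony counting and chlorophyll

The plate counter reuses the same segmentation: channel selection (red,
green, or ITU-R 601 luminance), maximum-entropy threshold, 8-connected
components, and a minimum colony area in pixels (a required parameter —
colony size depends entirely on plate imaging geometry). A uniform plate
image yields zero colonies with a warning, not an error: a fully
non-viable sample legitimately forms no colonies. Plating viability is
`100 × n_sample / n_control` against an all-viable control; plated cell
numbers and plate areas cancel in this normalisation and are not
modelled.

Chlorophyll concentration from a methanol extract:
`µg/ml = Abs650 × 13.9 / sample_volume_ml`, volume 2 ml by default and
explicit so the formula transfers to other extraction volumes. No
OD₇₅₀-to-concentration conversion is provided: turbidity at 750 nm is
confounded by pigmentation loss in dying cultures, which is exactly the
failure mode this assay avoids.

## Synthetic scenes: what they emulate, and what they do not

The generator (`cyanovia.synthetic`) renders what the pipeline actually
consumes: a dark background (level 8), disk-shaped cells bright in
exactly one channel (per-cell brightness drawn from N(180, 15) red /
N(120, 15) green, the other channel at 20, i.e. safely below the cutoff),
pixelwise Gaussian read noise (σ = 3), and optional sub-filter "specks" —
dim noise blobs (area 10 µm², per-speck brightness N(60, 10), a single
random channel) emulating the background-noise artifacts the 35 µm²
filter exists to remove. The default cell radius is 4.0 µm (footprint
≈ 50 µm²): deliberately larger than the ~1 µm physical radius of a
unicellular cyanobacterium, because a 35 µm² minimum footprint only makes
sense for optically blurred fluorescent footprints, and the generator
models what the camera sees, not the cell wall.

Placement is rejection sampling with a minimum centre separation of 2.5
cell radii between cells and a 6 px guard gap between the edges of all
objects, so segmentation can never merge two objects; a scene that cannot
be placed within the retry budget raises an error rather than silently
overlapping. Each scene consumes three independent RNG streams spawned
from one mandatory seed — cell placement, speck placement, pixel noise —
so adding specks to a scene changes neither the cells nor the noise
field, which is what makes the artifact-immunity check exact.

The mixture series reproduces the validation design of the assay: runs at
true viable fractions 0/0.25/0.5/0.75/1.0 (200 cells per run, 4 fields of
512 × 512 px at 0.5 µm/px), against which the estimated fraction is
regressed; the tests require slope within [0.95, 1.05] and R² ≥ 0.99.

Not emulated: point-spread blur by default (an optional Gaussian blur
exists for robustness testing), uneven illumination, touching or dividing
cells, out-of-focus planes, channel bleed-through, and contaminating
organisms. Passing tests therefore demonstrate that the *algorithmic*
chain — thresholding, particle registration, filtering, classification,
arithmetic — is correct and self-consistent, not that the fixed cutoffs
(50, 35 µm²) are right for any particular microscope. Those must be
validated against plating on real imagery, as the assay's original
validation did.

## Manifests and determinism

Every CLI analysis writes a JSON manifest: run id, input paths with
SHA-256 digests, full configuration, per-field thresholds, and package
version. The manifest intentionally contains no wall-clock timestamp —
the input digests identify the run, and omitting the timestamp makes
repeated runs on identical inputs byte-identical across all outputs,
which the test suite asserts.

## Problem sizes

The test suite and acceptance script use 512 × 512 px fields, 100–200
cells per run, 100 randomised histograms for the oracle check, and
600 × 600 px plates with 45–60 colonies; the full suite runs in well
under a minute. These sizes were chosen because every property asserted
(exact recovery, immunity, linearity) is already decidable at this scale;
nothing in the implementation is specific to them.
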