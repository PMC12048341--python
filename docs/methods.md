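# Methods

## The problem

A dissolvable microneedle patch deposits an N × N array of near-infrared
fluorescent microdoses in the dermis; each needle position is one binary bit
(dye present = ON). Reading the record back from a fluorescence photo, weeks
to months later, faces two failure modes: *temporal* — individual bits fade,
photobleach or are cleared, so the observed pattern is a corrupted copy of
the fabricated one — and *spatial* — the photo sees the pattern at an
unknown small rotation, scale, offset, blur and exposure. The package
addresses the first with a Reed–Muller error-correcting layer and the second
with a fully automatic rectification/recognition chain plus corner
orientation markers.

## Encoding model

**Code.** RM(r, m) over GF(2): codeword positions are the 2^m points of
GF(2)^m (binary counting order; variable *x<sub>i</sub>* is bit *i* of the
point index), generator rows are evaluations of the degree-≤ r monomials,
ordered degree-ascending and lexicographically within a degree. This fixed
ordering — nowhere canonical in the literature — makes information bits,
generator rows and decoder output mutually consistent and round-trip safe.
Derived quantities: n = 2^m, k = Σ_{i≤r} C(m, i), d = 2^(m−r),
t = ⌊(d−1)/2⌋ = 2^(m−r−1) − 1 for r < m.

**Decoding** is Reed's majority-logic algorithm. For a monomial with
variable set S at the current (highest remaining) degree, each assignment of
the variables outside S yields one vote: the XOR of the received word over
the 2^|S| points of that coset. The coefficient is the majority of the
2^(m−|S|) votes; decided contributions are XOR-ed out of the word and the
next degree level is processed. Even splits resolve to 0 and increment a tie
counter. The decoder never refuses: beyond the guaranteed radius it returns
its best effort with `low_confidence=True` (set on any tie or when the
residual distance exceeds t), because the system-level success criterion is
exact payload match, which requires an answer. `n_corrected` is the Hamming
distance between the received word and the re-encoded decision.

**Grid layout.** The usable string-bit budget of an N × N array is
2^⌊log2(N²)⌋ (64, 128, 256 for N = 10, 12, 17). Marker layouts: 10×10 —
four 3×3 corners, top-left/top-right/bottom-left ON, bottom-right OFF (36
cells); 12×12 — four 2×2 corners, same assignment (16); 17×17 — three 3×3
ON corners plus a 3-row × 2-column OFF block at the bottom-right corner (33).
The 17×17 and 12×12 geometries are declared conventions chosen to preserve
the three-ON/one-distinct-corner asymmetry while matching the published cell
counts; the original layouts are not public. Generic N ≥ 6 uses the largest
corner side s with 4s² ≤ N² − 2^⌊log2(N²)⌋; surplus data cells are fixed
OFF. Codeword bits fill the non-reserved cells top-left → bottom-right in
raster order.

**Mask.** A fixed Bernoulli(1/2) pattern on the data cells
(deterministically redrawn from its seed until the ON fraction lies in
[0.4, 0.6]), XOR-ed onto the encoded grid. It balances ON/OFF counts
(structured RM codewords can be badly skewed) and acts as a shared-secret
obfuscation layer; it is not cryptography. Marker cells are excluded from
the mask so orientation stays readable before decryption — the source
system leaves this unspecified, and masking markers would couple two stages
that are cleanly separable.

## Synthetic imaging model

ON cells render as isotropic Gaussian spots (σ = pitch/6 by default, the
simplest point-spread model consistent with round dermal deposits) at
centres mapped by rotation (uniform in ±5°), scale jitter (±5 %),
translation jitter (±4 px) about the image centre; per-spot peak brightness
is uniform in [0.55, 0.95]. Background is a constant level (0.08) plus
Gaussian pixel noise (σ = 0.012), followed by optional defocus blur
(σ ≤ 1.2 px), motion blur (≤ 3 px line kernel), and multiplicative
gain/exposure (each ±10 %), clipped to [0, 1]. Image side defaults to
256 px with pitch ≈ 0.69·side/(N−1) so the grid plus pose jitter always
fits. Noise magnitudes and blur ranges are declared defaults spanning a
plausible acquisition envelope, not reconstructions of any particular
camera.

**Temporal degradation** is whole-bit dropout: each ON bit survives
independently with the tier's retention probability (1.00, 0.75, 0.50,
0.25, mixed into datasets at 5/15/60/20 %), with an optional per-surviving-
spot intensity attenuation factor. Bit-level dropout (rather than thinning
pixels within spots) matches how retention is scored — detectable bits out
of transferred bits. OFF bits never turn ON; spurious signal enters only
through the imaging noise model.

Every sample draws from one child generator whose seed is recorded, so any
dataset is bit-identically reproducible from its manifest.

**What the simulator does not emulate:** physically based light transport,
skin autofluorescence spectra and heterogeneous backgrounds, sensor-specific
noise, patch deformation by skin stretch/growth, and overlapping patches.
Passing tests therefore demonstrate the algorithmic chain's correctness and
noise robustness within the declared variation space, not performance on
real skin photographs.

## Decoding chain (classical, parameter-free per image)

1. **Binarize:** pixel ON iff value > local mean (window = 2·pitch + 1 px,
   so one spot plus surround) + offset (0.02 of dynamic range); connected
   components smaller than 12 px removed. A positive offset maps constant
   images to all-OFF.
2. **Rectify:** minimum-area rotated rectangle over all foreground pixels
   (rotating-calipers via `shapely`); the image is rotated about the
   rectangle centre by the rectangle angle folded into (−45°, 45°], cropped
   to a square 1.35× the rectangle's long side (centre preserved), and
   resized to 12·N px. The residual 90° ambiguity is deliberately left to
   the marker-based orientation step — markers, not image moments, define
   orientation.
3. **Read:** spot centroids anchor the lattice — the extreme centroids per
   axis are the centres of the first/last rows and columns (the always-ON
   corner markers guarantee such spots exist); each cell is scored by mean
   intensity over its central 50 % (margin against pitch misregistration)
   and labelled by an exact 1-D two-means split of the N² scores, ties and
   degenerate distributions going OFF. No per-image thresholds anywhere.
4. **Orient / unmask / correct:** the rotation minimising marker mismatches
   wins (a tie raises an ambiguity error); the mask XOR is removed; data
   cells are read in raster order and majority-logic decoded; an optional
   codebook maps the payload integer to a label.

**Retention analytics** count connected spots after stage 1 per timepoint
image and report `detected / transferred × 100 %`; **intensity analytics**
take each ON bit's maximum pixel value inside a half-pitch box, and
comparisons across different gain/exposure settings are refused unless
explicitly overridden, since the values are only commensurable at fixed
acquisition settings.

## Learned stages

The original system also trains a U-Net-style binarizer and a convolutional
grid recognizer on 650,000 synthetic images. These are optional by design
here and not included: the classical chain above meets every system-level
bar on synthetic data by itself (100 % clean-decode success with zero
corrected bits across the variation space), and the package declares no
deep-learning dependency. The simulator nevertheless produces exactly the
paired (image, binary mask / bit array) data with 90/10 train/validation
splits and impulse-noise augmentation such stages would train on.

## Numerical and design choices

- Majority-vote ties → 0, counted, surfaced; deterministic decoding.
- Rotations are counter-clockwise; coordinates are (row, col) from the
  top-left; these conventions fix raster order and `np.rot90` semantics.
- Two-means cell labelling is computed exactly (sorted scan over all splits,
  minimising within-class variance), not by iterative k-means.
- Degenerate inputs: empty foreground → `NoPatchError`; collinear foreground
  → `NoPatchError`; all-identical cell scores → all-OFF with a warning;
  fully symmetric markers → `OrientationAmbiguityError`.
- Problem sizes in the test and acceptance suites (100–120 rendered decodes
  per configuration, 1,000 flip-and-decode trials, 10,000-draw tier checks,
  exhaustive decode-oracle enumeration for m ≤ 4) were chosen as the
  smallest sizes at which the binomial/multinomial tolerances quoted in the
  tests are meaningful.

## Known limitations

- The per-bit loss simulation (~1.6 %) is a desk-scale analog of
  longitudinal in-animal behaviour; animal retention statistics,
  wall-clock processing speeds and the full-scale network training are out
  of scope and not claimed.
- The decoder assumes one complete patch per image; multi-patch scenes and
  partial occlusion are unsupported.
- The mask is obfuscation with a shared secret, not encryption with
  security guarantees.
- Grid reading assumes at least one detectable spot in each extreme row and
  column; at retention ≤ 0.25 this (and the marker budget) routinely fails,
  which is reported as decode failure rather than guessed around.
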