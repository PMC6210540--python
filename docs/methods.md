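# Methods

## The code family

All coders in this package map positive integers to prefix-free bit strings.
The BL code's prefix is the reversal of the M-th *binary cluster* (patterns
starting `10` with no other `10`); reversal places the only occurrence of
`01` at the prefix end, so a decoder can delimit the prefix by scanning for
`01` and never needs codeword boundaries transmitted out of band. The suffix
is a fixed-width binary number of `M + S − 1` bits. For each code-num `M`
the covered value range at parameter `S` is

    2^S (2^(M−1) − 1) + 1  ≤  Z  ≤  2^S (2^M − 1),

which contains exactly `2^(M+S−1)` integers — precisely what the suffix
width can enumerate; the implementation's exhaustive range-partition test
checks this, and it is the reason the scale factor in the encoder's affine
map must be `2^S` (the exponent is easy to misread as a product in flattened
typesetting; only the exponential reading closes the count for every
`S ≥ 1`, and both readings coincide at the default `S = 1`).

`S` (integer ≥ 1, default 1) trades prefix reuse against suffix width:
larger `S` packs `2^(S−1)`-fold more values under each prefix at the cost of
`S − 1` extra suffix bits per codeword. All published worked examples use
`S = 1`, which is the package default everywhere.

### Numerical choices

* The code-num is found by integer comparison (`M` = bit length of
  `ceil(Z / 2^S)`), never by floating-point `log2`/`ceil`, which would be
  vulnerable to rounding ties at exact powers of two (e.g. `Z = 2` or
  `Z = 2(2^M − 1)` boundaries). A brute-force search oracle covers this in
  tests.
* The group index is computed as the smallest `K` with `M ≤ K(K+1)/2`
  using `math.isqrt` plus a correction step. This equals the closed-form
  "strict floor of `(1 + √(1+8M))/2`" — strict meaning an integer argument
  yields the value minus one — which is verified exhaustively for
  `M ≤ 10^6`. Python integers make the coder exact for arbitrarily large
  `Z`; the vectorized array path is limited to `Z < 2^62` and falls back to
  the scalar path beyond that.
* One published table row (the 7-bit entry for `Z = 15`) is inconsistent
  with the code's own construction, whose prefix `0001` and 4-bit suffix
  `0000` give the 8-bit codeword `00010000`; the formulas govern and the
  known-answer table carries the corrected entry.

### Reference coders

Exponential Golomb is the order-0 code of `Z − 1` (so `Z = 1 → "1"`),
matching the indexing of the comparison tables; with that shift it is
bit-identical to Elias gamma. Fibonacci coding uses the Zeckendorf
representation over `F(2)=1, F(3)=2, …` with a terminating `1` — the only
convention consistent with the published 30-bit length for 1,000,000, which
was confirmed against a greedy Zeckendorf oracle before the golden tests
were frozen. Every reference coder has a decoder so unique decodability is
tested by roundtrip on concatenated streams, not assumed.

## Frame codec

Samples are flattened row-major (depth-first, matching per-scanline
acquisition), zigzag-mapped (`0→1, v>0→2v, v<0→1−2v`; magnitude-ordered so
zero-mean signals get short codes), and concatenated without separators.
The `.blc` container header (25 bytes: magic, version, coder id, `S`,
mapping id, bit depth, rows, cols, payload bit count) exists only to make a
self-describing *file*; the payload itself carries no per-symbol overhead,
and compression ratios are computed on payload bits alone (the CLI also
logs the with-header figure). Byte packing is MSB-first and the final byte
is zero-padded; the decoder stops after `rows × cols` symbols and treats
leftover non-padding bits as a format error, so padding can never be
misparsed as a codeword.

## Synthetic frame generator

The generator emulates the *amplitude statistics* of pulse-echo ultrasound,
which is all a sample-wise entropy coder responds to:

* **Speckle** — per column, white Gaussian scatterers convolved with a
  Gaussian-windowed sinusoid (center frequency 8 MHz, sampling rate 40 MHz,
  fractional bandwidth 0.6, unit-norm kernel so the configured
  `speckle_amplitude` is the output RMS in ADC units). The envelope of this
  band-limited Gaussian process is Rayleigh distributed; a
  Kolmogorov–Smirnov test against a fitted Rayleigh at n = 10^5 stays below
  distance 0.02 (observed ≈ 0.003–0.007).
* **Structure** — point targets add scaled pulse echoes; cyst regions scale
  local scatterer strength by an echogenicity in [0, 1].
* **Beamforming stand-in** — sums of 8 adjacent channel columns; incoherent
  speckle grows by ≈ √8 ≈ 2.8×, reproducing the larger dynamic range of
  beamformed data without modeling delay geometry, which the codec never
  sees.
* **I/Q** — mixing with cos/−sin at the center frequency, a 65-tap
  linear-phase FIR low-pass cut at half the decimated Nyquist, row
  decimation (default 4), and re-quantization. No post-mixing gain of 2 is
  applied, as in a hardware demodulator/decimator, so each of I and Q
  carries about half the RF amplitude — which is why baseband data compress
  better than beamformed RF, and why I and Q (same amplitude, π/2 phase
  offset) compress equally.

Frames are quantized to the configured ADC depth (default 12 bits) with
clipping; the clip fraction is reported on the frame and stays below 0.1 %
at default amplitudes.

### Default study conditions

Benchmark scenes are 2048 × 128 pre-beamformed frames at 12 bits. Speckle
RMS is 15 ADC units for the phantom-like scenes (`point-targets` with six
900-unit reflectors; `cysts` with three near-anechoic inclusions) and
32–35 for the two tissue-like scenes, which add low-contrast inclusions
(echogenicity 0.7–0.8) and a few modest reflectors. These amplitudes were
chosen once so that tissue-like baseband I/Q frames compress with the BL
code at roughly 20–30 % — the regime reported for in vivo baseband data on
12-bit systems — and were then frozen. What passing tests show is therefore
the *orderings* (BL > exponential Golomb on baseband data; phantom > tissue;
pre-beamformed > beamformed; I ≈ Q) and a broad 15–45 % sanity band, not a
reproduction of ratios on any acquired data set: real frames differ in
depth-dependent attenuation and gain, scatterer density, electronic noise,
and true delay-and-sum correlation structure, none of which are modeled.
Absolute ratios also depend on the signed-to-positive mapping (zigzag here),
which published evaluations generally leave unstated.

## Known limitations

* The per-symbol decoder is scalar Python; encoding has a vectorized numpy
  path but decoding a 2048 × 128 frame takes on the order of a second.
* `S` is global per stream; no adaptive or per-datum parameter selection.
* The generator does not model attenuation/TGC, scan conversion, or
  physically derived channel correlations; "beamformed" frames are a
  statistical stand-in.
* Tests exercise frames up to 2048 × 128 and values up to 10^30; these
  sizes keep the default suite under a minute while covering every code
  path and boundary family.
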