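"""Synthetic ultrasound-like frame generator.

Emulates the amplitude statistics of pulse-echo ultrasound data so the codec
can be exercised end-to-end with no acquired data: fully developed speckle
(white Gaussian scatterers convolved with a band-limited pulse, whose
envelope is Rayleigh distributed), optional strong point reflectors, and
anechoic or low-contrast cyst regions.  A "beamformed" stage is emulated by
summation of adjacent channel columns — the codec consumes amplitude
statistics, not image geometry, so no delay-and-sum geometry is modeled —
and baseband I/Q is produced by quadrature demodulation of the beamformed
frame.  Everything is a pure function of configuration plus seed.

The default amplitudes are chosen so that tissue-like baseband I/Q frames
compress with the BL code at roughly 20–30%, the regime reported for in vivo
baseband data on 12-bit systems, with phantom-like frames (sparser, weaker
speckle) compressing better than tissue-like ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .codec import SampleFrame

__all__ = [
    "PhantomConfig",
    "generate_rf_frame",
    "quadrature_demodulate",
    "make_benchmark_suite",
    "DATASETS",
]

#: synthetic stand-ins for the four benchmark scenes: two phantom-like
#: (point targets, cysts) and two tissue-like (denser, stronger speckle)
DATASETS = ("point-targets", "cysts", "nerve-like", "thyroid-like")


@dataclass
class PhantomConfig:
    """Configuration of one synthetic RF frame.

    ``speckle_amplitude`` is the RMS of the fully developed speckle signal in
    ADC units.  ``point_targets`` are (row, col, amplitude) scatterers whose
    echo is the transmit pulse scaled by ``amplitude`` (ADC units peak).
    ``cyst_regions`` are (center_row, center_col, radius, echogenicity)
    circles that scale the local scatterer strength; echogenicity 0 is
    anechoic, 1 leaves the speckle untouched.
    """

    rows: int = 2048
    cols: int = 128
    center_frequency: float = 8e6
    sampling_rate: float = 40e6
    speckle_amplitude: float = 15.0
    point_targets: list = field(default_factory=list)
    cyst_regions: list = field(default_factory=list)
    bit_depth: int = 12
    fractional_bandwidth: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"invalid frame dimensions {self.rows}x{self.cols}")
        if not 0 < self.center_frequency < self.sampling_rate / 2:
            raise ValueError(
                "center frequency must lie below Nyquist "
                f"({self.center_frequency} vs {self.sampling_rate / 2})"
            )
        if self.speckle_amplitude < 0:
            raise ValueError("speckle amplitude must be >= 0")
        for r, c, _ in self.point_targets:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"point target ({r}, {c}) outside frame")
        for r, c, rad, e in self.cyst_regions:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise ValueError(f"cyst center ({r}, {c}) outside frame")
            if rad <= 0 or not 0 <= e <= 1:
                raise ValueError(f"invalid cyst radius/echogenicity ({rad}, {e})")


def _pulse(config: PhantomConfig) -> np.ndarray:
    """Gaussian-windowed sinusoid at the center frequency, unit L2 norm.

    Unit norm makes the RMS of (white scatterers * pulse) equal the
    scatterer RMS, so ``speckle_amplitude`` is the output speckle RMS.
    """
    fc, fs = config.center_frequency, config.sampling_rate
    bw = config.fractional_bandwidth
    # Gaussian envelope: fractional −6 dB bandwidth bw at fc
    sigma_t = np.sqrt(2 * np.log(2)) / (np.pi * bw * fc)
    half = max(2, int(np.ceil(3 * sigma_t * fs)))
    t = np.arange(-half, half + 1) / fs
    h = np.exp(-(t**2) / (2 * sigma_t**2)) * np.sin(2 * np.pi * fc * t)
    return h / np.linalg.norm(h)


def _quantize(x: np.ndarray, bit_depth: int) -> tuple[np.ndarray, float]:
    """Round to integers and clip to the signed range; report clip fraction."""
    lo, hi = -(1 << (bit_depth - 1)), (1 << (bit_depth - 1)) - 1
    q = np.rint(x)
    clipped = float(np.mean((q < lo) | (q > hi)))
    return np.clip(q, lo, hi).astype(np.int16), clipped


def generate_rf_frame(config: PhantomConfig) -> SampleFrame:
    """Simulate one pre-beamformed RF frame (rows = depth, cols = channels).

    Each column is an independent white Gaussian scatterer sequence, scaled
    by the cyst echogenicity map, convolved with the transmit pulse; point
    targets add scaled pulses at their location.  Deterministic given the
    seed.  The returned frame carries the realized clip fraction in its
    ``clip_fraction`` attribute.
    """
    rng = np.random.default_rng(config.seed)
    strength = np.full((config.rows, config.cols), config.speckle_amplitude)
    if config.cyst_regions:
        rr, cc = np.mgrid[0 : config.rows, 0 : config.cols]
        for r0, c0, rad, echo in config.cyst_regions:
            inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            strength[inside] *= echo
    scatterers = rng.standard_normal((config.rows, config.cols)) * strength
    h = _pulse(config)
    peak = float(np.max(np.abs(h)))
    for r0, c0, amp in config.point_targets:
        scatterers[r0, c0] += amp / peak  # so the echo peaks near amp
    rf = np.empty_like(scatterers)
    for c in range(config.cols):
        rf[:, c] = np.convolve(scatterers[:, c], h, mode="same")
    samples, clip_fraction = _quantize(rf, config.bit_depth)
    frame = SampleFrame(
        samples=samples,
        stage="pre-beamformed",
        bit_depth=config.bit_depth,
        sampling_rate=config.sampling_rate,
    )
    frame.clip_fraction = clip_fraction
    return frame


def beamform_columns(frame: SampleFrame, group: int = 8) -> SampleFrame:
    """Emulate beamformed scanlines by summing groups of adjacent channel
    columns (coherent summation stand-in; no delay geometry).

    The summed amplitude grows roughly with sqrt(group) for incoherent
    speckle, reproducing the larger dynamic range of beamformed data.
    Columns beyond the last full group are dropped; sums are clipped to the
    frame's bit depth.
    """
    if group < 1 or frame.cols < group:
        raise ValueError(f"group {group} incompatible with {frame.cols} columns")
    n = frame.cols // group
    acc = frame.samples[:, : n * group].astype(np.int64)
    summed = acc.reshape(frame.rows, n, group).sum(axis=2)
    samples, _ = _quantize(summed.astype(np.float64), frame.bit_depth)
    return SampleFrame(
        samples=samples,
        stage="beamformed",
        bit_depth=frame.bit_depth,
        sampling_rate=frame.sampling_rate,
    )


def quadrature_demodulate(
    frame: SampleFrame,
    decimation: int = 1,
    center_frequency: float = 8e6,
    numtaps: int = 65,
) -> tuple[SampleFrame, SampleFrame]:
    """Demodulate an RF frame to baseband I/Q and decimate along depth.

    The frame is mixed with cos/−sin at the center frequency, low-pass
    filtered with a linear-phase FIR (cutoff at half the decimated Nyquist),
    decimated row-wise, and re-quantized at the frame's bit depth.  No
    post-mixing gain is applied, so each of I and Q carries about half the
    RF amplitude, as in a conventional demodulator followed by a decimator.
    """
    if not isinstance(decimation, (int, np.integer)) or decimation < 1:
        raise ValueError(f"decimation must be an integer >= 1, got {decimation!r}")
    fs = frame.sampling_rate
    if fs <= 2 * center_frequency:
        raise ValueError("sampling rate must exceed twice the center frequency")
    n = np.arange(frame.rows)[:, None]
    phase = 2 * np.pi * center_frequency * n / fs
    x = frame.samples.astype(np.float64)
    mixed_i = x * np.cos(phase)
    mixed_q = -x * np.sin(phase)
    nyq_dec = fs / (2 * decimation)
    cutoff = 0.5 * nyq_dec
    taps = signal.firwin(numtaps, cutoff, fs=fs)
    i_bb = np.apply_along_axis(np.convolve, 0, mixed_i, taps, "same")[::decimation]
    q_bb = np.apply_along_axis(np.convolve, 0, mixed_q, taps, "same")[::decimation]
    out = []
    for data, stage in ((i_bb, "I"), (q_bb, "Q")):
        samples, _ = _quantize(data, frame.bit_depth)
        out.append(
            SampleFrame(
                samples=samples,
                stage=stage,
                bit_depth=frame.bit_depth,
                sampling_rate=fs / decimation,
            )
        )
    return out[0], out[1]


def _dataset_config(name: str, rows: int, cols: int, seed: int) -> PhantomConfig:
    """Scene definitions: phantom scenes have sparse, weak speckle with
    strong structure; tissue-like scenes have denser, stronger speckle and
    low-contrast structure."""
    rng = np.random.default_rng(seed)
    if name == "point-targets":
        targets = [
            (int(r), int(c), 900.0)
            for r, c in zip(
                rng.integers(rows // 8, rows - rows // 8, size=6),
                rng.integers(4, cols - 4, size=6),
            )
        ]
        return PhantomConfig(
            rows=rows, cols=cols, speckle_amplitude=15.0,
            point_targets=targets, seed=seed,
        )
    if name == "cysts":
        cysts = [
            (rows // 4, cols // 3, rows // 12, 0.05),
            (rows // 2, 2 * cols // 3, rows // 10, 0.1),
            (3 * rows // 4, cols // 2, rows // 14, 0.05),
        ]
        return PhantomConfig(
            rows=rows, cols=cols, speckle_amplitude=15.0,
            cyst_regions=cysts, seed=seed,
        )
    if name in ("nerve-like", "thyroid-like"):
        # denser/stronger speckle with low-contrast inclusions
        cysts = [
            (rows // 3, cols // 2, rows // 10, 0.7),
            (2 * rows // 3, cols // 4, rows // 12, 0.8),
        ]
        targets = [
            (int(r), int(c), 300.0)
            for r, c in zip(
                rng.integers(rows // 8, rows - rows // 8, size=3),
                rng.integers(4, cols - 4, size=3),
            )
        ]
        amp = 35.0 if name == "nerve-like" else 32.0
        return PhantomConfig(
            rows=rows, cols=cols, speckle_amplitude=amp,
            cyst_regions=cysts, point_targets=targets, seed=seed,
        )
    raise KeyError(f"unknown data set {name!r}; known: {DATASETS}")


def make_benchmark_suite(
    seed: int = 0,
    rows: int = 2048,
    cols: int = 128,
    beamform_group: int = 8,
    decimation: int = 4,
) -> dict[tuple[str, str], SampleFrame]:
    """Generate the benchmark suite: four scenes, each as pre-beamformed RF,
    beamformed(-like) RF, and baseband I and Q.

    Returns a dict keyed by ``(dataset, stage)`` with stages
    ``pre-beamformed``, ``beamformed``, ``I``, ``Q`` — 16 frames in total.
    Byte-identical for a fixed seed.
    """
    suite: dict[tuple[str, str], SampleFrame] = {}
    for i, name in enumerate(DATASETS):
        config = _dataset_config(name, rows, cols, seed=seed * 7919 + i)
        rf = generate_rf_frame(config)
        bf = beamform_columns(rf, group=beamform_group)
        iq_i, iq_q = quadrature_demodulate(
            bf, decimation=decimation, center_frequency=config.center_frequency
        )
        suite[(name, "pre-beamformed")] = rf
        suite[(name, "beamformed")] = bf
        suite[(name, "I")] = iq_i
        suite[(name, "Q")] = iq_q
    return suite
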