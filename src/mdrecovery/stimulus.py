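"""Visual stimulus synthesis.

Two stimulus classes drive the whole pipeline:

* a **contrast-modulated Gaussian noise movie** — the Fourier inversion of a
  random spatiotemporal spectrum, low-pass limited at 0.05 cycles/degree in
  space and 4 Hz in time, then multiplied frame-by-frame by a slow contrast
  envelope that carries the stimulus from gray to full contrast and back with
  a 10-s period; and
* a **drifting sinusoidal grating protocol** — 12 equally spaced drift
  directions crossed with six spatial frequencies plus a zero-SF (full-field
  flicker / blank) condition, 1.5 s per trial, repeated per eye.

Movies are stored as (time, y, x) stacks of signed contrast values in
[-1, 1].  Pixel (0, 0) is the top-left corner; x increases rightward
(azimuth) and y downward (elevation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.fft

__all__ = [
    "NoiseMovieSpec",
    "StimulusMovie",
    "GRATING_SPATIAL_FREQS_CPD",
    "GRATING_N_DIRECTIONS",
    "GRATING_TEMPORAL_FREQ_HZ",
    "GRATING_TRIAL_DURATION_S",
    "contrast_envelope",
    "synthesize_noise_movie",
    "build_grating_protocol",
    "write_movie_tiff",
    "read_movie_tiff",
]

# Grating protocol constants: six nonzero spatial frequencies, octave-spaced,
# plus SF = 0 denoting the full-field flicker / blank condition.
GRATING_SPATIAL_FREQS_CPD = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32)
GRATING_N_DIRECTIONS = 12
GRATING_TEMPORAL_FREQ_HZ = 2.0
GRATING_TRIAL_DURATION_S = 1.5

#: Alternative envelope ``|sin(pi t / P)|`` — same endpoints, sharper minimum.
ENVELOPE_FORMS = ("raised_cosine", "abs_sine")


@dataclass(frozen=True)
class NoiseMovieSpec:
    """Parameters of the band-limited noise movie.

    Defaults match the experimental stimulus: 60 x 60 pixels spanning 30
    visual degrees, 30 frames/s, 5 minutes long, spatial cutoff 0.05 cpd,
    temporal cutoff 4 Hz, 10-s contrast-modulation period.
    """

    grid_px: int = 60
    span_deg: float = 30.0
    fps: float = 30.0
    duration_s: float = 300.0
    sf_cutoff_cpd: float = 0.05
    tf_cutoff_hz: float = 4.0
    contrast_period_s: float = 10.0
    seed: int = 0
    envelope_form: str = "raised_cosine"

    def __post_init__(self) -> None:
        for name in ("grid_px", "span_deg", "fps", "duration_s",
                     "sf_cutoff_cpd", "tf_cutoff_hz", "contrast_period_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        nyq_sf = self.grid_px / (2.0 * self.span_deg)
        if self.sf_cutoff_cpd >= nyq_sf:
            raise ValueError(
                f"sf_cutoff_cpd={self.sf_cutoff_cpd} is at or above the "
                f"spatial Nyquist frequency {nyq_sf} cpd "
                f"({self.grid_px} px over {self.span_deg} deg)")
        if self.tf_cutoff_hz >= self.fps / 2.0:
            raise ValueError(
                f"tf_cutoff_hz={self.tf_cutoff_hz} is at or above the "
                f"temporal Nyquist frequency {self.fps / 2.0} Hz")
        if self.envelope_form not in ENVELOPE_FORMS:
            raise ValueError(f"envelope_form must be one of {ENVELOPE_FORMS}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class StimulusMovie:
    """A synthesized movie plus its calibration.

    ``frames`` holds the contrast-enveloped stack; ``base_frames`` the same
    stack before enveloping (needed to measure the intrinsic spatiotemporal
    spectrum without the envelope's sidebands).  ``contrast_trace`` is the
    per-frame envelope value in [0, 1].
    """

    frames: np.ndarray            # (t, y, x), signed contrast in [-1, 1]
    fps: float
    span_deg: float
    contrast_trace: np.ndarray    # (t,), in [0, 1]
    contrast_period_s: float
    base_frames: np.ndarray | None = None
    spec: NoiseMovieSpec | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def contrast_envelope(t, period: float, form: str = "raised_cosine"):
    """Contrast-modulation envelope at time ``t`` seconds.

    Raised cosine ``(1 - cos(2 pi t / P)) / 2``: 0 at the start of each
    cycle (gray screen), 1 at mid-cycle (full contrast), 0 again at the end.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if form == "raised_cosine":
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
    elif form == "abs_sine":
        env = np.abs(np.sin(np.pi * t / period))
    else:
        raise ValueError(f"unknown envelope form {form!r}")
    # analytic form is already in [0, 1]; clip only rounding spill
    return np.clip(env, 0.0, 1.0)[()] if env.ndim == 0 else np.clip(env, 0.0, 1.0)


def synthesize_noise_movie(spec: NoiseMovieSpec) -> StimulusMovie:
    """Synthesize the band-limited contrast-modulated noise movie.

    A real Gaussian white-noise field is Fourier transformed, every
    coefficient outside the pass band (radial spatial frequency above
    ``sf_cutoff_cpd`` or |temporal frequency| above ``tf_cutoff_hz``) is set
    to zero, and the stack is inverse transformed.  Starting from a real
    field keeps the spectrum Hermitian, so the inverse transform is real to
    machine precision and the spectrum is hard-zero outside the cutoffs.
    The result is rescaled so the global maximum |value| is 1 — a linear
    operation that preserves the band limits exactly — and multiplied by
    the contrast envelope.
    """
    rng = np.random.default_rng(spec.seed)
    nt, n = spec.n_frames, spec.grid_px

    white = rng.standard_normal((nt, n, n)).astype(np.float32)
    spectrum = scipy.fft.fftn(white, axes=(0, 1, 2))

    ft = scipy.fft.fftfreq(nt, d=1.0 / spec.fps)              # Hz
    fs = scipy.fft.fftfreq(n, d=spec.span_deg / n)            # cpd
    f_rad = np.hypot(fs[:, None], fs[None, :])                # radial cpd
    keep = ((np.abs(ft)[:, None, None] <= spec.tf_cutoff_hz)
            & (f_rad[None, :, :] <= spec.sf_cutoff_cpd))
    spectrum *= keep

    base = scipy.fft.ifftn(spectrum, axes=(0, 1, 2)).real.astype(np.float32)
    del spectrum, white

    scale = np.abs(base).max()
    if scale > 0:
        base /= np.float32(scale)

    t = np.arange(nt) / spec.fps
    trace = contrast_envelope(t, spec.contrast_period_s, spec.envelope_form)
    frames = base * trace[:, None, None].astype(np.float32)

    return StimulusMovie(
        frames=frames, fps=spec.fps, span_deg=spec.span_deg,
        contrast_trace=trace, contrast_period_s=spec.contrast_period_s,
        base_frames=base, spec=spec)


def build_grating_protocol(repeats: int = 6, seed: int = 0,
                           n_directions: int = GRATING_N_DIRECTIONS,
                           spatial_freqs=GRATING_SPATIAL_FREQS_CPD,
                           eyes=("contra", "ipsi")) -> pd.DataFrame:
    """Build a randomized drifting-grating trial sequence.

    Every (direction, spatial frequency) condition — including the SF = 0
    blank/flicker condition at each direction — appears exactly ``repeats``
    times per eye.  Trials are shuffled within each repeat block so blanks
    are interspersed throughout.  Columns: ``trial_index, eye,
    direction_deg, sf_cpd, is_blank``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    directions = np.arange(n_directions) * (360.0 / n_directions)
    conditions = [(d, sf) for d in directions for sf in spatial_freqs]
    conditions += [(d, 0.0) for d in directions]  # blank / full-field flicker

    rows = []
    for eye in eyes:
        for _ in range(repeats):
            block = list(conditions)
            rng.shuffle(block)
            for d, sf in block:
                rows.append((eye, d, sf, sf == 0.0))
    df = pd.DataFrame(rows, columns=["eye", "direction_deg", "sf_cpd",
                                     "is_blank"])
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


# ---------------------------------------------------------------------------
# I/O: multi-frame 32-bit float TIFF with a JSON calibration sidecar

def write_movie_tiff(movie: StimulusMovie, path) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    sidecar = {
        "fps": movie.fps,
        "span_deg": movie.span_deg,
        "contrast_period_s": movie.contrast_period_s,
        "seed": movie.spec.seed if movie.spec is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_movie_tiff(path) -> StimulusMovie:
    import tifffile

    path = Path(path)
    frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    t = np.arange(frames.shape[0]) / meta["fps"]
    trace = contrast_envelope(t, meta["contrast_period_s"])
    return StimulusMovie(frames=frames, fps=meta["fps"],
                         span_deg=meta["span_deg"], contrast_trace=trace,
                         contrast_period_s=meta["contrast_period_s"])
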