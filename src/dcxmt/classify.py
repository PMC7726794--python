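"""Protofilament-number classification and the moire diagnostic.

Microtubules polymerised in vitro close with 11-16 protofilaments (PFs).
Segments are assigned a PF number by matched filtering against noiseless
synthetic reference projections, one per candidate architecture, after a
15 Angstrom low-pass and 4x binning: the score for each architecture is the
maximum normalised cross-correlation over in-plane rotation and axial shift
within one dimer repeat, and the best-scoring architecture wins.  This is a
2D projection-matching analogue of supervised 3D classification against
synthetic volumes; the acceptance surface is recovery of known synthetic
mixtures, not any particular experimental class split.

Segments whose best score falls below a noise-calibrated floor (mean + 5
s.d. of the best scores of pure-noise images) are flagged "poor" and
excluded from the architecture fractions' named classes; fractions
including "poor" always sum to 1.

The moire filter provides the classical visual diagnostic in quantitative
form: non-13-PF architectures have skewed PFs, so the projected PF stripe
pattern beats along the axis with the analytic period
L_N = (2*pi*rho_N)^2 / (N*|S*a - N*r|); unskewed 13-PF lattices show no
finite beat (reported as infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FrequencyError, GeometryError, ParameterError
from .simulate import RenderParams, SegmentStack, lattice_for_box, render_segment

__all__ = ["ReferenceBank", "ClassificationResult", "build_references",
           "classify_segment", "classify_stack", "moire_filter",
           "MoireResult"]

DEFAULT_ARCHS = (11, 12, 13, 14, 15, 16)

#: fixed seed for the pure-noise score calibration of the "poor" floor
_FLOOR_SEED = 927154873


def _bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-average binning; trailing rows/cols that do not fill a block
    are cropped."""
    ny, nx = img.shape
    ny2, nx2 = ny // factor, nx // factor
    img = img[: ny2 * factor, : nx2 * factor]
    return img.reshape(ny2, factor, nx2, factor).mean(axis=(1, 3))


def _lowpass(img: np.ndarray, pixel_size: float, cutoff_A: float) -> np.ndarray:
    """Isotropic Fourier low-pass with a raised-cosine edge (+-10 % of the
    cutoff frequency)."""
    ny, nx = img.shape
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx = np.fft.fftfreq(nx, d=pixel_size)
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    nu_c = 1.0 / cutoff_A
    lo, hi = 0.9 * nu_c, 1.1 * nu_c
    h = np.clip((hi - r) / (hi - lo), 0.0, 1.0)
    h = 0.5 - 0.5 * np.cos(np.pi * h)
    return np.fft.ifft2(np.fft.fft2(img) * h).real


def _preprocess(img: np.ndarray, pixel_size: float, lowpass_A: float,
                bin_factor: int) -> np.ndarray:
    binned = _bin_image(np.asarray(img, dtype=np.float64), bin_factor)
    out = _lowpass(binned, pixel_size * bin_factor, lowpass_A)
    return out - out.mean()


@dataclass
class ReferenceBank:
    """Noiseless, low-passed, binned reference projections, one per
    architecture, plus the preprocessing geometry needed to score segments
    against them."""

    archs: tuple[int, ...]
    references: dict[int, np.ndarray]
    render_params: RenderParams
    lowpass_A: float
    bin_factor: int
    noise_floor: float | None = None
    _ref_fft: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    _ref_norm: dict[int, float] = field(default_factory=dict, repr=False)

    @property
    def binned_pixel(self) -> float:
        return self.render_params.pixel_size * self.bin_factor

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.references.values())).shape

    def _ensure_ffts(self):
        if not self._ref_fft:
            for n, ref in self.references.items():
                self._ref_fft[n] = np.conj(np.fft.fft2(ref))
                self._ref_norm[n] = float(np.linalg.norm(ref))


def build_references(arch_list=DEFAULT_ARCHS, rp: RenderParams | None = None,
                     lowpass_A: float = 15.0, bin_factor: int = 4,
                     **lattice_kw) -> ReferenceBank:
    """Render one noiseless, undecorated reference projection per
    architecture and preprocess it to the classification geometry."""
    if not arch_list:
        raise ParameterError("arch_list: empty architecture list")
    rp = rp or RenderParams()
    if lowpass_A < 2.0 * rp.pixel_size * bin_factor:
        raise FrequencyError(
            f"lowpass_A={lowpass_A} is beyond the Nyquist limit "
            f"{2 * rp.pixel_size * bin_factor:.2f} A after {bin_factor}x binning")
    refs = {}
    clean = RenderParams(**{**rp.__dict__, "occupancy_p": 0.0, "noise_sigma": 0.0})
    for n in arch_list:
        lat, sites = lattice_for_box(n, clean, **lattice_kw)
        img, _ = render_segment(lat, sites, clean)
        refs[n] = _preprocess(img, rp.pixel_size, lowpass_A, bin_factor)
    return ReferenceBank(archs=tuple(arch_list), references=refs,
                         render_params=rp, lowpass_A=lowpass_A,
                         bin_factor=bin_factor)


def _score_against_bank(prepped: np.ndarray, bank: ReferenceBank,
                        rot_range: tuple[float, float], rot_step: float,
                        max_lateral_shift_px: int) -> dict[int, float]:
    """Best normalised cross-correlation per architecture, maximised over
    in-plane rotation and (axial within one dimer repeat, small lateral)
    circular shifts."""
    bank._ensure_ffts()
    ny, nx = prepped.shape
    max_dy = max(1, int(round(80.0 / bank.binned_pixel)))
    max_dx = max_lateral_shift_px
    ys = np.r_[0:max_dy + 1, ny - max_dy:ny] if max_dy * 2 < ny else np.arange(ny)
    xs = np.r_[0:max_dx + 1, nx - max_dx:nx] if max_dx * 2 < nx else np.arange(nx)

    angles = np.arange(rot_range[0], rot_range[1] + 1e-9, rot_step)
    scores = {n: -np.inf for n in bank.archs}
    for ang in angles:
        if abs(ang) < 1e-12:
            rot = prepped
        else:
            rot = ndimage.rotate(prepped, ang, reshape=False, order=1,
                                 mode="constant", cval=0.0)
        rot = rot - rot.mean()
        norm = np.linalg.norm(rot)
        if norm == 0:
            continue
        f = np.fft.fft2(rot)
        for n in bank.archs:
            cc = np.fft.ifft2(f * bank._ref_fft[n]).real
            best = cc[np.ix_(ys, xs)].max() / (norm * bank._ref_norm[n])
            if best > scores[n]:
                scores[n] = float(best)
    return scores


def classify_segment(image: np.ndarray, bank: ReferenceBank,
                     rot_range: tuple[float, float] = (-10.0, 10.0),
                     rot_step: float = 2.0,
                     max_lateral_shift_px: int = 2) -> tuple[int, dict[int, float]]:
    """Assign a PF number to one raw segment image.

    Returns ``(best_n, scores)``; scores are reported for every
    architecture in the bank.  The image must match the bank's raw box
    geometry.
    """
    expect = (bank.shape[0] * bank.bin_factor, bank.shape[1] * bank.bin_factor)
    if image.shape[0] // bank.bin_factor != bank.shape[0] or \
       image.shape[1] // bank.bin_factor != bank.shape[1]:
        raise GeometryError(
            f"image shape {image.shape} does not match the bank's raw geometry "
            f"~{expect} (bin {bank.bin_factor}x)")
    prepped = _preprocess(image, bank.render_params.pixel_size,
                          bank.lowpass_A, bank.bin_factor)
    scores = _score_against_bank(prepped, bank, rot_range, rot_step,
                                 max_lateral_shift_px)
    best = max(scores, key=scores.get)
    return best, scores


def _calibrate_floor(bank: ReferenceBank, n_noise: int = 32,
                     rot_range=(-10.0, 10.0), rot_step=2.0,
                     max_lateral_shift_px=2) -> float:
    """"Poor" threshold: mean + 5 s.d. of the best scores of pure-noise
    calibration images (scores are scale invariant, so unit noise suffices).
    Deterministic per bank geometry."""
    rng = np.random.default_rng(_FLOOR_SEED)
    ny, nx = bank.render_params.shape
    best_scores = []
    for _ in range(n_noise):
        noise = rng.normal(size=(ny, nx))
        prepped = _preprocess(noise, bank.render_params.pixel_size,
                              bank.lowpass_A, bank.bin_factor)
        s = _score_against_bank(prepped, bank, rot_range, rot_step,
                                max_lateral_shift_px)
        best_scores.append(max(s.values()))
    return float(np.mean(best_scores) + 5.0 * np.std(best_scores, ddof=1))


@dataclass
class ClassificationResult:
    """Per-segment PF assignments and per-stack class fractions."""

    per_segment: pd.DataFrame       # best_n, score, poor (+ true_n if known)
    fractions: dict                 # arch (and "poor") -> fraction; sums to 1
    noise_floor: float
    confusion: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"fractions": {str(k): v for k, v in self.fractions.items()},
                "noise_floor": self.noise_floor,
                "n_segments": len(self.per_segment)}


def classify_stack(stack: SegmentStack, bank: ReferenceBank,
                   rot_range: tuple[float, float] = (-10.0, 10.0),
                   rot_step: float = 2.0,
                   max_lateral_shift_px: int = 2) -> ClassificationResult:
    """Classify every segment of a stack and summarise class fractions.

    Segments scoring below the noise floor are assigned to the "poor"
    class.  When the stack carries ground-truth labels a confusion matrix
    (true architecture x assigned class) is included.
    """
    if len(stack) < 1:
        raise GeometryError("stack is empty")
    floor = bank.noise_floor
    if floor is None:
        floor = _calibrate_floor(bank, rot_range=rot_range, rot_step=rot_step,
                                 max_lateral_shift_px=max_lateral_shift_px)
        bank.noise_floor = floor

    rows = []
    for img in stack.images:
        best, scores = classify_segment(img, bank, rot_range, rot_step,
                                        max_lateral_shift_px)
        rows.append({"best_n": best, "score": scores[best],
                     "poor": scores[best] < floor,
                     **{f"score_{n}": s for n, s in scores.items()}})
    per_seg = pd.DataFrame(rows)

    n = len(per_seg)
    fractions = {}
    for arch in bank.archs:
        fractions[arch] = int(((per_seg.best_n == arch) & ~per_seg.poor).sum()) / n
    fractions["poor"] = int(per_seg.poor.sum()) / n

    confusion = None
    if "n_pf" in stack.truth.columns:
        per_seg = per_seg.assign(true_n=stack.truth["n_pf"].to_numpy())
        assigned = np.where(per_seg.poor, "poor", per_seg.best_n.astype(str))
        confusion = pd.crosstab(per_seg.true_n, pd.Series(assigned, name="assigned"))
    return ClassificationResult(per_segment=per_seg, fractions=fractions,
                                noise_floor=floor, confusion=confusion)


@dataclass
class MoireResult:
    """Band-pass filtered image and the axial beat-period estimate."""

    filtered: np.ndarray
    period_A: float          # inf when no finite beat is detected
    reliable: bool           # False when no PF stripe signal is present
    band_A: tuple[float, float]
    envelope: np.ndarray = field(repr=False, default=None)  # type: ignore


def moire_filter(image: np.ndarray, pixel_size: float,
                 band_A: tuple[float, float] = (40.0, 80.0),
                 envelope_smooth_A: float = 100.0,
                 min_period_A: float = 500.0,
                 max_lag_frac: float = 0.45,
                 peak_threshold: float = 0.3,
                 presence_factor: float = 1.2) -> MoireResult:
    """Fourier-filter the lateral PF-stripe band and estimate the moire beat.

    The image is band-passed in lateral frequency (periods between
    ``band_A[0]`` and ``band_A[1]``, all axial frequencies kept); the axial
    envelope of band power, smoothed over ``envelope_smooth_A``, beats with
    the projected moire period (:func:`dcxmt.lattice.moire_beat_period`)
    for skewed lattices.  The period is read from the dominant
    autocorrelation peak between ``min_period_A`` and ``max_lag_frac`` of
    the record length.

    Returns ``period_A = inf`` when the stripe signal is present but
    unmodulated (unskewed 13-PF lattices) and ``reliable = False`` when the
    band holds no more power than noise would put there.
    """
    lo_A, hi_A = min(band_A), max(band_A)
    nyq = 1.0 / (2.0 * pixel_size)
    if 1.0 / lo_A > nyq:
        raise FrequencyError(
            f"band {band_A} A reaches {1 / lo_A:.4g}/A, beyond Nyquist {nyq:.4g}/A")
    img = np.asarray(image, dtype=np.float64)
    img = img - img.mean()
    ny, nx = img.shape
    fx = np.fft.fftfreq(nx, d=pixel_size)
    keep = (np.abs(fx) >= 1.0 / hi_A) & (np.abs(fx) <= 1.0 / lo_A)
    f = np.fft.fft2(img)
    f[:, ~keep] = 0.0
    filtered = np.fft.ifft2(f).real

    # is there any PF stripe signal at all?  a flat (noise) spectrum puts
    # exactly band_frac of the total power into the band (ratio 1, sub-%
    # fluctuation at these image sizes); require a presence_factor excess
    band_frac = keep.sum() / nx
    total_power = float((img ** 2).sum())
    band_power = float((filtered ** 2).sum())
    reliable = total_power > 0 and band_power > presence_factor * band_frac * total_power

    p = (filtered ** 2).mean(axis=1)
    p = ndimage.gaussian_filter1d(p, sigma=max(envelope_smooth_A / pixel_size, 1.0),
                                  mode="reflect")
    envelope = p.copy()
    if not reliable:
        return MoireResult(filtered=filtered, period_A=math.nan, reliable=False,
                           band_A=(lo_A, hi_A), envelope=envelope)

    q = p - p.mean()
    denom = float((q ** 2).sum())
    if denom == 0:
        return MoireResult(filtered=filtered, period_A=math.inf, reliable=True,
                           band_A=(lo_A, hi_A), envelope=envelope)
    ac = np.correlate(q, q, mode="full")[len(q) - 1:] / denom
    min_lag = int(round(min_period_A / pixel_size))
    max_lag = int(round(max_lag_frac * len(ac)))
    if min_lag >= max_lag - 2:
        return MoireResult(filtered=filtered, period_A=math.inf, reliable=True,
                           band_A=(lo_A, hi_A), envelope=envelope)
    seg = ac[min_lag:max_lag]
    k = int(np.argmax(seg))
    if seg[k] < peak_threshold or k + min_lag >= len(ac) - 1:
        return MoireResult(filtered=filtered, period_A=math.inf, reliable=True,
                           band_A=(lo_A, hi_A), envelope=envelope)
    # parabolic refinement around the discrete peak
    i = k + min_lag
    y0, y1, y2 = ac[i - 1], ac[i], ac[i + 1]
    denom2 = (y0 - 2 * y1 + y2)
    shift = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
    period = (i + shift) * pixel_size
    return MoireResult(filtered=filtered, period_A=float(period), reliable=True,
                       band_A=(lo_A, hi_A), envelope=envelope)
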