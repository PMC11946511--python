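"""Post-acquisition processing of ESEEM/HYSCORE time traces.

The chain mirrors standard pulsed-EPR practice: first-point intensity
normalization, background removal (exponential decay fit, or polynomial),
apodization (one-sided Chebyshev by default), zero filling, FFT magnitude
spectra, and peak picking with parabolic sub-bin refinement.  All spectra
are magnitude spectra; frequencies are in MHz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as _dfield
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal.windows import chebwin, hamming

from .eseem import TimeTrace1D
from .hyscore import TimeTrace2D

Trace = Union[TimeTrace1D, TimeTrace2D]


class DegenerateTraceError(ValueError):
    """Raised when a trace cannot be normalized (zero first point)."""


@dataclass
class Spectrum1D:
    freq_MHz: np.ndarray
    magnitude: np.ndarray
    provenance: dict = _dfield(default_factory=dict)

    def __post_init__(self):
        self.freq_MHz = np.asarray(self.freq_MHz, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")


@dataclass
class Spectrum2D:
    f1_MHz: np.ndarray
    f2_MHz: np.ndarray
    magnitude: np.ndarray
    provenance: dict = _dfield(default_factory=dict)

    def __post_init__(self):
        self.f1_MHz = np.asarray(self.f1_MHz, dtype=float)
        self.f2_MHz = np.asarray(self.f2_MHz, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.magnitude.shape != (len(self.f1_MHz), len(self.f2_MHz)):
            raise ValueError("magnitude shape does not match axes")


@dataclass(frozen=True)
class Peak:
    nu1: float
    nu2: Optional[float]
    height: float
    label: str = ""


@dataclass
class PeakList:
    entries: list[Peak] = _dfield(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def by_label(self, label: str) -> Peak:
        for p in self.entries:
            if p.label == label:
                return p
        raise KeyError(f"no peak labelled {label!r}")


# ---------------------------------------------------------------------------
# Normalization and background subtraction
# ---------------------------------------------------------------------------

def normalize_trace(trace: Trace) -> Trace:
    """Divide by the first-point echo amplitude so the trace starts at 1."""
    first = trace.values.flat[0]
    if first == 0:
        raise DegenerateTraceError("first-point amplitude is zero")
    md = dict(trace.metadata)
    md["normalized_first_point"] = True
    if isinstance(trace, TimeTrace1D):
        return TimeTrace1D(trace.t_axis, trace.values / first, md)
    return TimeTrace2D(trace.t1_axis, trace.t2_axis, trace.values / first, md)


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares a*exp(-t/tc) + c fit; returns the fitted baseline."""
    span = y.max() - y.min()
    p0 = (span if span > 0 else 1.0, max(t[-1], 1.0) / 3.0, y.min())

    def model(t, a, tc, c):
        return a * np.exp(-t / tc) + c

    popt, _ = curve_fit(
        model, t, y, p0=p0, maxfev=5000,
        bounds=((-np.inf, 1e-3, -np.inf), (np.inf, np.inf, np.inf)),
    )
    return model(t, *popt)


def _fit_polynomial(t: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    # polyfit handles y with multiple columns at once
    coeff = np.polynomial.polynomial.polyfit(t, y, order)
    return np.polynomial.polynomial.polyval(t, coeff, tensor=True).T if y.ndim > 1 \
        else np.polynomial.polynomial.polyval(t, coeff)


def subtract_background(trace: Trace, model: str = "exponential") -> Trace:
    """Remove the slow echo-decay envelope, keeping the modulation residual.

    ``model`` is ``"exponential"`` or ``"polynomial<order>"`` (e.g.
    ``"polynomial3"``).  For 2D traces the fit is applied sequentially
    along t1 then t2.  An exponential fit that fails to converge falls
    back to a cubic polynomial with a warning.
    """
    if trace.values.size < 8:
        raise ValueError("background subtraction needs >= 8 points")
    if model.startswith("polynomial"):
        order = int(model[len("polynomial"):] or 3)
        fit_1d = lambda t, y: _fit_polynomial(t, y, order)  # noqa: E731
    elif model == "exponential":
        def fit_1d(t, y):
            if y.ndim > 1:
                return np.stack([fit_1d(t, y[:, j]) for j in range(y.shape[1])], axis=1)
            try:
                return _fit_exponential(t, y)
            except Exception:
                warnings.warn(
                    "exponential background fit failed; falling back to "
                    "polynomial order 3", RuntimeWarning, stacklevel=2,
                )
                return _fit_polynomial(t, y, 3)
    else:
        raise ValueError(f"unknown background model {model!r}")

    md = dict(trace.metadata)
    md["background_model"] = model
    if isinstance(trace, TimeTrace1D):
        resid = trace.values - fit_1d(trace.t_axis, trace.values)
        return TimeTrace1D(trace.t_axis, resid, md)
    vals = trace.values - fit_1d(trace.t1_axis, trace.values)
    vals = (vals.T - fit_1d(trace.t2_axis, vals.T)).T
    return TimeTrace2D(trace.t1_axis, trace.t2_axis, vals, md)


# ---------------------------------------------------------------------------
# Apodization + FFT
# ---------------------------------------------------------------------------

#: default Chebyshev window sidelobe attenuation (dB)
CHEBYSHEV_ATTENUATION_DB = 100.0


def _window(name: str, n: int) -> np.ndarray:
    """One-sided apodization window (maximum at t = 0, decaying)."""
    if name == "none":
        return np.ones(n)
    if name == "chebyshev":
        return chebwin(2 * n, at=CHEBYSHEV_ATTENUATION_DB, sym=True)[n:]
    if name == "hamming":
        return hamming(2 * n, sym=True)[n:]
    raise ValueError(f"unknown window {name!r}")


def to_spectrum(
    trace: Trace,
    window: str = "chebyshev",
    zerofill: int = 0,
) -> Union[Spectrum1D, Spectrum2D]:
    """Windowed, zero-filled FFT magnitude spectrum of a time trace.

    Expects background-subtracted input; any residual mean is removed
    before the transform.  Defaults: zero-fill to 2048 points (1D) or
    1024 x 1024 (2D).  For 2D input the nonnegative-frequency quadrant is
    returned (the (-,+) strong-coupling quadrant is stored under
    ``provenance["quadrant_mp"]``).
    """
    prov = {
        "window": window,
        "source": dict(trace.metadata),
    }
    if isinstance(trace, TimeTrace1D):
        n = len(trace.values)
        zf = zerofill or 2048
        if zf < n:
            raise ValueError(f"zerofill {zf} smaller than trace length {n}")
        dt = trace.t_axis[1] - trace.t_axis[0]
        x = (trace.values - trace.values.mean()) * _window(window, n)
        mag = np.abs(np.fft.rfft(x, n=zf))
        freq = np.fft.rfftfreq(zf, d=dt * 1e-3)  # MHz
        prov["zerofill"] = zf
        return Spectrum1D(freq, mag, prov)

    n1, n2 = trace.values.shape
    zf = zerofill or 1024
    if zf < max(n1, n2):
        raise ValueError(f"zerofill {zf} smaller than trace length {max(n1, n2)}")
    dt1 = trace.t1_axis[1] - trace.t1_axis[0]
    dt2 = trace.t2_axis[1] - trace.t2_axis[0]
    w = np.outer(_window(window, n1), _window(window, n2))
    x = (trace.values - trace.values.mean()) * w
    F = np.fft.fft2(x, s=(zf, zf))
    f1 = np.fft.fftfreq(zf, d=dt1 * 1e-3)
    f2 = np.fft.fftfreq(zf, d=dt2 * 1e-3)
    half = zf // 2
    mag_pp = np.abs(F[:half, :half])
    # (-,+) quadrant, ordered with |f1| ascending
    mag_mp = np.abs(F[::-1, :half][: half - 1, :])
    prov["zerofill"] = zf
    prov["quadrant_mp"] = mag_mp
    return Spectrum2D(f1[:half], f2[:half], mag_pp, prov)


# ---------------------------------------------------------------------------
# Peak picking
# ---------------------------------------------------------------------------

def _parabolic_refine(y_m1: float, y_0: float, y_p1: float) -> float:
    """Sub-bin offset of a parabola through three points, clipped to [-1, 1]."""
    denom = y_m1 - 2 * y_0 + y_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -1.0, 1.0))


def pick_peaks(
    spec: Union[Spectrum1D, Spectrum2D],
    min_height_frac: float = 0.05,
    box: float = 0.1,
) -> PeakList:
    """Local maxima above ``min_height_frac`` of the global maximum.

    Positions are refined by 3-point (1D) or separable 3x3 (2D) parabolic
    interpolation.  ``box`` (MHz) is the minimum separation between
    reported peaks; of two close maxima the higher wins.  Deterministic
    ordering: descending height, ties by ascending nu1.
    """
    if isinstance(spec, Spectrum1D):
        y = spec.magnitude
        f = spec.freq_MHz
        if y.size == 0 or y.max() == 0:
            return PeakList([])
        thr = min_height_frac * y.max()
        idx = [
            i for i in range(1, len(y) - 1)
            if y[i] > y[i - 1] and y[i] >= y[i + 1] and y[i] >= thr
        ]
        df = f[1] - f[0]
        cands = []
        for i in idx:
            off = _parabolic_refine(y[i - 1], y[i], y[i + 1])
            cands.append(Peak(nu1=f[i] + off * df, nu2=None, height=float(y[i])))
        return _dedupe(cands, box)

    y = spec.magnitude
    if y.size == 0 or y.max() == 0:
        return PeakList([])
    thr = min_height_frac * y.max()
    df1 = spec.f1_MHz[1] - spec.f1_MHz[0]
    df2 = spec.f2_MHz[1] - spec.f2_MHz[0]
    core = y[1:-1, 1:-1]
    neighborhood = np.stack([
        y[1 + di:y.shape[0] - 1 + di, 1 + dj:y.shape[1] - 1 + dj]
        for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)
    ])
    is_max = (core >= neighborhood.max(axis=0)) & (core >= thr)
    # strictness against plateaus: require strictly greater than at least one
    is_max &= core > neighborhood.min(axis=0)
    cands = []
    for i, j in zip(*np.nonzero(is_max)):
        ii, jj = i + 1, j + 1
        o1 = _parabolic_refine(y[ii - 1, jj], y[ii, jj], y[ii + 1, jj])
        o2 = _parabolic_refine(y[ii, jj - 1], y[ii, jj], y[ii, jj + 1])
        cands.append(
            Peak(
                nu1=spec.f1_MHz[ii] + o1 * df1,
                nu2=spec.f2_MHz[jj] + o2 * df2,
                height=float(y[ii, jj]),
            )
        )
    return _dedupe(cands, box)


def _dedupe(cands: list[Peak], box: float) -> PeakList:
    cands.sort(key=lambda p: (-p.height, p.nu1))
    kept: list[Peak] = []
    for p in cands:
        clash = False
        for q in kept:
            d1 = abs(p.nu1 - q.nu1)
            d2 = abs((p.nu2 or 0.0) - (q.nu2 or 0.0))
            if max(d1, d2) < box:
                clash = True
                break
        if not clash:
            kept.append(p)
    return PeakList(kept)


def height_at(
    spec: Union[Spectrum1D, Spectrum2D],
    nu1: float,
    nu2: Optional[float] = None,
    box: float = 0.15,
) -> float:
    """Maximum magnitude within a +/- box (MHz) neighborhood of a position.

    This is the peak-height convention used for intensity ratios.
    """
    if isinstance(spec, Spectrum1D):
        m = np.abs(spec.freq_MHz - nu1) <= box
        return float(spec.magnitude[m].max()) if m.any() else 0.0
    m1 = np.abs(spec.f1_MHz - nu1) <= box
    m2 = np.abs(spec.f2_MHz - nu2) <= box
    if not (m1.any() and m2.any()):
        return 0.0
    return float(spec.magnitude[np.ix_(m1, m2)].max())


def region_centroid(
    spec: Union[Spectrum1D, Spectrum2D],
    nu1_range: tuple[float, float],
    nu2_range: Optional[tuple[float, float]] = None,
):
    """Magnitude-weighted centroid position over a frequency region.

    Powder cross peaks and combination lines are extended ridges whose
    absolute maximum sits on processing-sensitive edge singularities; the
    centroid over the closed-form ridge region is the robust location
    measure and corresponds to where a broadened contour plot peaks.
    Returns nu1 (1D) or (nu1, nu2).
    """
    if isinstance(spec, Spectrum1D):
        m = (spec.freq_MHz >= nu1_range[0]) & (spec.freq_MHz <= nu1_range[1])
        w = spec.magnitude[m]
        if w.sum() == 0:
            raise ValueError("empty region")
        return float((w * spec.freq_MHz[m]).sum() / w.sum())
    m1 = (spec.f1_MHz >= nu1_range[0]) & (spec.f1_MHz <= nu1_range[1])
    m2 = (spec.f2_MHz >= nu2_range[0]) & (spec.f2_MHz <= nu2_range[1])
    w = spec.magnitude[np.ix_(m1, m2)]
    if w.sum() == 0:
        raise ValueError("empty region")
    c1 = float((w.sum(axis=1) * spec.f1_MHz[m1]).sum() / w.sum())
    c2 = float((w.sum(axis=0) * spec.f2_MHz[m2]).sum() / w.sum())
    return c1, c2


def line_prominence(
    spec: Spectrum1D, nu_range: tuple[float, float]
) -> tuple[float, float]:
    """Height of a line above the local linear baseline across a region.

    The baseline is the chord joining the spectrum values at the region
    edges; the skirt of a strong neighboring line is baseline, not peak,
    so a region containing no line returns ~0.  Returns (prominence,
    position of the maximum excess).
    """
    f, y = spec.freq_MHz, spec.magnitude
    idx = np.nonzero((f >= nu_range[0]) & (f <= nu_range[1]))[0]
    if len(idx) < 3:
        raise ValueError("region too narrow for the frequency grid")
    i0, i1 = idx[0], idx[-1]
    base = np.interp(f[idx], [f[i0], f[i1]], [y[i0], y[i1]])
    excess = y[idx] - base
    j = int(np.argmax(excess))
    return float(max(excess[j], 0.0)), float(f[idx][j])


def peak_height_ratio(
    peaks: PeakList, reference_label: str, others: Sequence[str]
) -> list[float]:
    """Peak heights relative to a labelled reference peak (reference -> 1.0)."""
    ref = peaks.by_label(reference_label).height
    out = [1.0]
    for lbl in others:
        out.append(peaks.by_label(lbl).height / ref)
    return out


# ---------------------------------------------------------------------------
# Convenience pipelines
# ---------------------------------------------------------------------------

def process_trace(
    trace: Trace,
    background: Optional[str] = "polynomial3",
    window: str = "chebyshev",
    zerofill: int = 0,
) -> Union[Spectrum1D, Spectrum2D]:
    """normalize -> background subtract -> window -> zero-fill -> FFT."""
    t = normalize_trace(trace)
    if background is not None:
        t = subtract_background(t, model=background)
    return to_spectrum(t, window=window, zerofill=zerofill)
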