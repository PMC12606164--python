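"""Segmentation and averaging of ligament stress-stretch curves.

A ligament tensile curve has three phases: a concave-up *toe* region where
crimped collagen straightens, a *linear* region of engaged fibers, and a
concave-down *subfailure* region.  They are bounded by four characteristic
points: the origin (stretch 1, stress 0), the I and II transition points,
and the failure point (maximum stress).

The transition points are located from the data itself: the discrete second
derivative of stress with respect to stretch is computed with a central
finite-difference scheme, its zero crossing (the inflection) is linearly
interpolated, a line is anchored on the two samples bracketing the
inflection, and the linear region is grown outward as far as the relative
deviation of the data from that line stays below 1%.  The longest such
region wins; its end points are the I and II transitions.

Per-ligament averaged curves are rebuilt from the averaged characteristic
points as an exact interpolant: a toe segment (quadratic-through-origin
polynomial or saturating exponential) through the origin, point I and point
II, continued by a subfailure quadratic that matches value and slope at
point II and passes through the failure point.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import brentq
from scipy.signal import savgol_filter

__all__ = [
    "StressStretchCurve",
    "CharacteristicPoints",
    "PointStats",
    "AveragedCurve",
    "ToeForm",
    "NoInflectionError",
    "DegenerateRegionError",
    "second_derivative",
    "find_inflection",
    "linear_region",
    "characteristic_points",
    "average_characteristic_points",
    "build_averaged_curve",
]


#: a candidate linear region must be at least this stiff relative to the
#: stiffest part of the curve (see linear_region)
_SLOPE_FRACTION = 0.9
_SLOPE_QUANTILE = 95


class NoInflectionError(ValueError):
    """Second derivative never changes sign (pure convex/concave/linear data)."""


class DegenerateRegionError(ValueError):
    """No linear region of at least 3 samples could be established."""


class ToeForm(str, Enum):
    POLYNOMIAL = "polynomial"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class StressStretchCurve:
    """Ordered (stretch, first Piola-Kirchhoff stress) samples of one test.

    ``lam`` starts at 1 and is strictly increasing; ``P`` (MPa) starts at 0.
    """

    lam: np.ndarray
    P: np.ndarray
    specimen_id: str = ""
    ligament: str = ""

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "P", P)
        if lam.shape != P.shape or lam.ndim != 1:
            raise ValueError("lam and P must be 1-D arrays of equal length")
        if lam.size < 11:
            raise ValueError(f"curve needs at least 11 samples, got {lam.size}")
        if not np.all(np.diff(lam) > 0):
            k = int(np.flatnonzero(np.diff(lam) <= 0)[0]) + 1
            raise ValueError(f"stretch must be strictly increasing (violated at sample {k})")
        if abs(lam[0] - 1.0) > 1e-9:
            raise ValueError(f"first stretch must be 1, got {lam[0]}")
        if abs(P[0]) > 1e-9:
            raise ValueError(f"first stress must be 0, got {P[0]}")
        if not np.all(np.isfinite(P)):
            raise ValueError("stresses must be finite")

    def __len__(self) -> int:
        return self.lam.size


@dataclass(frozen=True)
class CharacteristicPoints:
    """(stretch, stress) at the I transition, II transition and failure."""

    ptI: tuple[float, float]
    ptII: tuple[float, float]
    fail: tuple[float, float]

    def __post_init__(self):
        lI, pI = self.ptI
        lII, pII = self.ptII
        lf, pf = self.fail
        if not (1.0 < lI < lII < lf):
            raise ValueError(f"stretch ordering 1 < {lI} < {lII} < {lf} violated")
        if not (0.0 < pI < pII < pf):
            raise ValueError(f"stress ordering 0 < {pI} < {pII} < {pf} violated")


@dataclass(frozen=True)
class PointStats:
    """Mean and sample SD (n-1) of characteristic points over a cohort."""

    mean: CharacteristicPoints
    sd_ptI: tuple[float, float]
    sd_ptII: tuple[float, float]
    sd_fail: tuple[float, float]
    n: int


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def second_derivative(x, y):
    """Three-point central second derivative on a possibly non-uniform grid.

    Returns an array the same length as the input with endpoints masked as
    NaN; interior values are O(h^2) accurate on uniform grids.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples for a second derivative")
    h1 = x[1:-1] - x[:-2]
    h2 = x[2:] - x[1:-1]
    d2 = 2.0 * (
        y[:-2] / (h1 * (h1 + h2))
        - y[1:-1] / (h1 * h2)
        + y[2:] / (h2 * (h1 + h2))
    )
    out = np.full(x.size, np.nan)
    out[1:-1] = d2
    return out


def _smooth(P: np.ndarray, window: int | None) -> np.ndarray:
    """Savitzky-Golay smoothing (cubic) used before differencing noisy data."""
    if window is None:
        window = max(5, (P.size // 15) | 1)
    if window <= 3:
        return P
    window = min(window | 1, P.size - (1 - P.size % 2))
    return savgol_filter(P, window, polyorder=3)


def _sign_crossings(lam, d2, y_scale, tol_rel=1e-7):
    """(+ -> -) and (- -> +) crossings of the discrete second derivative.

    Samples with |d2| below a tolerance (relative to the largest curvature,
    with an absolute floor covering the round-off of exactly linear data)
    are treated as zero so that a straight mid-region does not generate
    spurious crossings; a crossing is interpolated between the bracketing
    non-zero samples.  Returns a list of (lam0, i, j, downstream_run)
    with i < j the bracketing sample indices; the downstream run tolerates
    brief opposite-sign blips of up to two samples.
    """
    lam = np.asarray(lam, dtype=float)
    valid = np.isfinite(d2)
    h_min = float(np.min(np.diff(lam)))
    floor = 1e-10 * y_scale / h_min**2  # round-off scale of the difference quotient
    peak = np.nanmax(np.abs(d2)) if valid.any() else 0.0
    tol = max(tol_rel * peak, floor)
    sign = np.zeros(d2.size, dtype=int)
    sign[valid] = np.where(np.abs(d2[valid]) <= tol, 0, np.sign(d2[valid])).astype(int)
    nz = np.flatnonzero(sign != 0)
    crossings = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] * sign[b] < 0:
            # linear interpolation of the zero between samples a and b
            lam0 = lam[a] + (lam[b] - lam[a]) * d2[a] / (d2[a] - d2[b])
            crossings.append((float(lam0), int(a), int(b)))
    if not crossings:
        raise NoInflectionError("second derivative has no sign change")
    out = []
    for lam0, a, b in crossings:
        s = sign[b]
        run, blip = 0, 0
        for k in range(b, d2.size):
            if sign[k] == -s:
                blip += 1
                if blip > 2:
                    break
            else:
                blip = 0
            run += 1
        out.append((lam0, a, b, run - blip))
    return out


def find_inflection(curve: StressStretchCurve, smooth_window: int | None = None) -> float:
    """Stretch at the interpolated zero of the discrete second derivative.

    With several crossings, the one bounding the longest downstream
    sign-consistent run is returned (ties broken toward smaller stretch).
    """
    P = _smooth(curve.P, smooth_window)
    d2 = second_derivative(curve.lam, P)
    crossings = _sign_crossings(curve.lam, d2, float(np.max(np.abs(P))))
    best = max(crossings, key=lambda c: (c[3], -c[0]))
    return best[0]


def linear_region(curve: StressStretchCurve, smooth_window: int | None = None,
                  rel_tol: float = 0.01):
    """Locate the linear region; its end points are the I and II transitions.

    For each inflection candidate, a line is built through the two samples
    bracketing it and grown outward sample by sample while the relative
    deviation ``|P - P_line| / max(|P_line|, P_floor)`` stays below
    ``rel_tol`` (the stress floor, 1% of the curve's peak stress, guards the
    near-zero toe).  The linear region of a ligament curve is its stiffest
    phase -- the toe is still recruiting fibers and the subfailure phase is
    softening -- so candidates whose line is noticeably shallower than the
    steepest tangent of the curve (shallow arcs of the toe or subfailure
    that happen to hide inside the band) are rejected.  The longest
    surviving region wins.  Returns ``(ptI, ptII)`` as (stretch, stress)
    tuples taken from the raw samples.
    """
    lam = curve.lam
    Ps = _smooth(curve.P, smooth_window)
    d2 = second_derivative(lam, Ps)
    crossings = _sign_crossings(lam, d2, float(np.max(np.abs(Ps))))
    floor = rel_tol * float(np.max(np.abs(curve.P)))
    # noise-robust tangent-slope profile (the derivative of the smoothed
    # curve, smoothed again) and the stiffest tangent, for the slope filter
    slope_prof = _smooth(np.gradient(Ps, lam), smooth_window)
    # robust stiffest-tangent estimate: the linear region occupies a sizable
    # share of the samples, so a high quantile reaches it while ignoring
    # isolated noise peaks of the derivative estimate
    slope_cap = float(np.percentile(slope_prof, _SLOPE_QUANTILE))

    best = None
    for lam0, _a, _b, _run in crossings:
        k = int(np.searchsorted(lam, lam0)) - 1
        k = min(max(k, 0), lam.size - 2)
        if slope_prof[k] < _SLOPE_FRACTION * slope_cap:
            continue

        def grow(m, p0):
            line = p0 + m * (lam - lam[k])
            ok = np.abs(Ps - line) / np.maximum(np.abs(line), floor) < rel_tol
            # an isolated off-band sample (noise) does not end the region --
            # only three consecutive violations do; trailing ones not kept
            lo, miss = k, 0
            while lo > 0 and miss < 3:
                miss = miss + 1 if not ok[lo - 1] else 0
                lo -= 1
            while lo < k and not ok[lo]:
                lo += 1
            hi, miss = k + 1, 0
            while hi < lam.size - 1 and miss < 3:
                miss = miss + 1 if not ok[hi + 1] else 0
                hi += 1
            while hi > k + 1 and not ok[hi]:
                hi -= 1
            return lo, hi

        # line through the two samples adjacent to the inflection, then one
        # least-squares refit over the found region to shed the noise of
        # the two anchoring samples, and a regrow with the refitted line
        m = (Ps[k + 1] - Ps[k]) / (lam[k + 1] - lam[k])
        lo, hi = grow(m, Ps[k])
        if hi - lo + 1 >= 5:
            m, p0 = np.polyfit(lam[lo:hi + 1] - lam[k], Ps[lo:hi + 1], 1)
            lo, hi = grow(m, p0)
        if hi - lo + 1 < 3:
            continue
        extent = lam[hi] - lam[lo]
        if best is None or extent > best[0]:
            best = (extent, lo, hi)
    if best is None:
        raise DegenerateRegionError("no linear region of >= 3 samples found")
    _, lo, hi = best
    ptI = (float(lam[lo]), float(curve.P[lo]))
    ptII = (float(lam[hi]), float(curve.P[hi]))
    return ptI, ptII


def characteristic_points(curve: StressStretchCurve,
                          smooth_window: int | None = None) -> CharacteristicPoints:
    """I/II transition points from the linear region; failure = peak stress."""
    ptI, ptII = linear_region(curve, smooth_window)
    k = int(np.argmax(curve.P))
    fail = (float(curve.lam[k]), float(curve.P[k]))
    return CharacteristicPoints(ptI, ptII, fail)


def average_characteristic_points(points: list[CharacteristicPoints]) -> PointStats:
    """Arithmetic mean and sample SD of each characteristic-point coordinate."""
    if len(points) < 2:
        raise ValueError("need at least 2 specimens to average")
    arr = np.array([[p.ptI, p.ptII, p.fail] for p in points])  # (n, 3, 2)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    return PointStats(
        mean=CharacteristicPoints(tuple(mean[0]), tuple(mean[1]), tuple(mean[2])),
        sd_ptI=tuple(sd[0]),
        sd_ptII=tuple(sd[1]),
        sd_fail=tuple(sd[2]),
        n=len(points),
    )


# ---------------------------------------------------------------------------
# averaged-curve construction
# ---------------------------------------------------------------------------

def _solve_exponential(x1, p1, x2, p2):
    """A, B with A (exp(B x) - 1) through (x1, p1) and (x2, p2), x in stretch-1."""
    ratio = p2 / p1

    def g(B):
        return np.expm1(B * x2) / np.expm1(B * x1) - ratio

    # at B -> 0 the ratio tends to x2/x1; a convex toe needs ratio > x2/x1
    g0 = x2 / x1 - ratio
    if abs(g0) < 1e-12:
        return None  # collinear with origin: exponential ill-posed
    if g0 < 0:
        lo, hi = 1e-9, 1.0
        while g(hi) < 0:
            hi *= 2.0
            if hi > 1e4:
                raise ValueError("exponential toe: no bracket for B")
        B = brentq(g, lo, hi, xtol=1e-14)
    else:
        # concave data: negative exponent
        lo, hi = -1.0, -1e-9
        while g(lo) > 0:
            lo *= 2.0
            if lo < -1e4:
                raise ValueError("exponential toe: no bracket for B")
        B = brentq(g, lo, hi, xtol=1e-14)
    A = p1 / np.expm1(B * x1)
    return float(A), float(B)


@dataclass(frozen=True)
class AveragedCurve:
    """Exact C1 interpolant through (1, 0), point I, point II and failure.

    Toe-and-linear segment on [1, lam_II]; subfailure quadratic on
    [lam_II, lam_fail] matching value and slope at the II transition.
    """

    toe_form: ToeForm
    points: CharacteristicPoints
    # toe parameters: polynomial P = a s^2 + b s, or exponential P = A (e^{B s} - 1)
    toe_params: tuple[float, float]
    # subfailure quadratic P = pII + s2 * d + c2 * d^2, d = lam - lam_II
    sub_slope: float
    sub_curv: float

    def __call__(self, lam):
        lam = np.asarray(lam, dtype=float)
        s = lam - 1.0
        if self.toe_form is ToeForm.POLYNOMIAL:
            a, b = self.toe_params
            toe = a * s**2 + b * s
        else:
            A, B = self.toe_params
            toe = A * np.expm1(B * s)
        lII, pII = self.points.ptII
        d = lam - lII
        sub = pII + self.sub_slope * d + self.sub_curv * d**2
        out = np.where(lam <= lII, toe, sub)
        return out if out.ndim else float(out)

    def derivative(self, lam):
        lam = np.asarray(lam, dtype=float)
        s = lam - 1.0
        if self.toe_form is ToeForm.POLYNOMIAL:
            a, b = self.toe_params
            toe = 2 * a * s + b
        else:
            A, B = self.toe_params
            toe = A * B * np.exp(B * s)
        lII, _ = self.points.ptII
        sub = self.sub_slope + 2 * self.sub_curv * (lam - lII)
        out = np.where(lam <= lII, toe, sub)
        return out if out.ndim else float(out)

    @property
    def lam_II(self) -> float:
        return self.points.ptII[0]

    @property
    def lam_fail(self) -> float:
        return self.points.fail[0]

    def is_monotone(self, n: int = 2001) -> bool:
        lam = np.linspace(1.0, self.lam_fail, n)
        return bool(np.all(np.diff(self(lam)) >= -1e-12))


def build_averaged_curve(points: CharacteristicPoints,
                         toe_form: ToeForm | str = ToeForm.EXPONENTIAL) -> AveragedCurve:
    """Exact interpolant through the averaged characteristic points.

    The toe segment passes through the origin (automatic for both forms),
    point I and point II; the polynomial form is the quadratic-through-origin
    ``a (lam-1)^2 + b (lam-1)``, the exponential form ``A (e^{B(lam-1)} - 1)``.
    If the three points are collinear through the origin the exponential
    rate degenerates (B -> 0) and the polynomial form with a = 0 is used
    instead.  The subfailure quadratic matches value and slope at the II
    transition and passes through the failure point.
    """
    toe_form = ToeForm(toe_form)
    x1, p1 = points.ptI[0] - 1.0, points.ptI[1]
    x2, p2 = points.ptII[0] - 1.0, points.ptII[1]
    if toe_form is ToeForm.POLYNOMIAL:
        a = (p2 / x2 - p1 / x1) / (x2 - x1)
        b = p1 / x1 - a * x1
        toe_params = (float(a), float(b))
        slope_II = 2 * a * x2 + b
    else:
        sol = _solve_exponential(x1, p1, x2, p2)
        if sol is None:
            import warnings

            warnings.warn("characteristic points collinear with the origin: "
                          "exponential toe ill-posed, falling back to linear polynomial")
            toe_form = ToeForm.POLYNOMIAL
            toe_params = (0.0, float(p1 / x1))
            slope_II = p1 / x1
        else:
            A, B = sol
            toe_params = (A, B)
            slope_II = A * B * np.exp(B * x2)
    dl = points.fail[0] - points.ptII[0]
    dp = points.fail[1] - points.ptII[1]
    sub_curv = (dp - slope_II * dl) / dl**2
    return AveragedCurve(toe_form, points, toe_params, float(slope_II), float(sub_curv))
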