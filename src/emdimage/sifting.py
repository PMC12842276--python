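"""One-dimensional empirical mode decomposition (EMD).

EMD adaptively splits a signal x(t) into intrinsic mode functions (IMFs)
c_1..c_n plus a residue r_n, by iterative *sifting*: at each step the mean
of the upper and lower extrema envelopes is subtracted from the current
candidate until the candidate oscillates symmetrically about zero. An IMF
satisfies two conditions:

1. its numbers of extrema and zero crossings are equal or differ by one;
2. the mean of the envelopes through its maxima and minima is (near) zero.

Extraction proceeds from the fastest oscillation (c_1) to the slowest; the
residue carries the remaining monotone or near-extrema-free trend, so the
decomposition telescopes back to the input exactly:

    x(t) = sum_i c_i(t) + r_n(t)

Envelope construction uses natural cubic splines through the extrema, with
the two extrema nearest each end mirrored beyond the boundary before
interpolation to suppress end swings. Sifting stops via a Cauchy-type
criterion SD = sum(m^2)/sum(h^2) < sd_threshold combined with the IMF test,
capped at ``max_sift_iters`` iterations. All arithmetic is float64.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "SiftConfig",
    "ExtremaSet",
    "EnvelopePair",
    "IMFCheck",
    "SiftResult",
    "Decomposition",
    "NotEnoughExtremaError",
    "find_extrema",
    "compute_envelopes",
    "count_zero_crossings",
    "is_imf",
    "sift_imf",
    "decompose",
]


class NotEnoughExtremaError(ValueError):
    """Raised when a signal has too few extrema to build both envelopes."""


@dataclass(frozen=True)
class SiftConfig:
    """Tunable knobs of the sifting loop.

    The stopping conditions (monotone residue, extrema/zero-crossing parity,
    zero mean envelope) come from the method definition; the numeric
    tolerances here are implementation choices, since exact zeros are
    unattainable in floating point.

    Parameters
    ----------
    sd_threshold
        Cauchy stopping threshold on SD = sum(m^2)/sum(h^2) between
        consecutive sift iterates (classical value 0.2).
    max_sift_iters
        Hard cap on sift iterations per IMF; hitting it is recorded in
        diagnostics rather than raising.
    max_imfs
        Maximum number of IMFs to extract; ``None`` decomposes fully.
    imf_mean_tolerance
        The mean envelope is accepted as "zero" when its max magnitude is
        below this fraction of the candidate's RMS.
    """

    sd_threshold: float = 0.2
    max_sift_iters: int = 100
    max_imfs: int | None = None
    imf_mean_tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be positive")
        if self.max_sift_iters < 1:
            raise ValueError("max_sift_iters must be a positive integer")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be a positive integer or None")
        if self.imf_mean_tolerance <= 0:
            raise ValueError("imf_mean_tolerance must be positive")


@dataclass(frozen=True)
class ExtremaSet:
    """Interior local extrema of a signal, plateau-collapsed.

    A constant plateau that is a local max/min contributes a single index at
    its midpoint (lower index on even-length ties). Endpoints are never
    reported.
    """

    maxima: np.ndarray
    minima: np.ndarray

    @property
    def n_extrema(self) -> int:
        return len(self.maxima) + len(self.minima)


@dataclass(frozen=True)
class EnvelopePair:
    """Upper/lower extrema envelopes and their pointwise mean."""

    upper: np.ndarray
    lower: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.upper + self.lower)


@dataclass(frozen=True)
class IMFCheck:
    """Outcome of the two IMF conditions, with diagnostics."""

    is_imf: bool
    counts_ok: bool
    mean_ok: bool
    n_extrema: int
    n_zero_crossings: int
    max_abs_mean_env: float


@dataclass(frozen=True)
class SiftResult:
    imf: np.ndarray
    sift_count: int
    converged: bool
    # extrema ran out mid-sift: the candidate cannot support envelopes and
    # so can never satisfy the IMF conditions; it belongs to the residue
    exhausted: bool = False


@dataclass
class Decomposition:
    """Ordered IMFs (c_1 = fastest) plus residue, with sift diagnostics."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def diagnostics(self) -> dict:
        """JSON-serializable sifting diagnostics."""
        return {
            "n_imfs": self.n,
            "sift_counts": list(map(int, self.sift_counts)),
            "converged": list(map(bool, self.converged)),
        }


def _as_signal(values, min_len: int = 3) -> np.ndarray:
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError(f"expected a 1D signal, got shape {x.shape}")
    if len(x) < min_len:
        raise ValueError(f"signal too short: length {len(x)} < {min_len}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return x


def find_extrema(values) -> ExtremaSet:
    """Locate interior local maxima and minima with plateau collapsing.

    Runs of equal values are compressed first; a run strictly above (below)
    both neighbouring runs yields one maximum (minimum) at the plateau
    midpoint, lower index on even-length ties. The first and last samples
    are never extrema.
    """
    x = _as_signal(values)
    # run-length encode: starts[i] is the first index of run i
    change = np.flatnonzero(np.diff(x) != 0.0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [len(x) - 1]))  # inclusive
    rv = x[starts]
    if len(rv) < 3:
        return ExtremaSet(np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp))
    left = rv[:-2]
    mid = rv[1:-1]
    right = rv[2:]
    is_max = (mid > left) & (mid > right)
    is_min = (mid < left) & (mid < right)
    mid_idx = (starts[1:-1] + ends[1:-1]) // 2
    return ExtremaSet(mid_idx[is_max], mid_idx[is_min])


def _mirrored_knots(indices: np.ndarray, values: np.ndarray, n: int):
    """Mirror the two extrema nearest each end beyond the boundary.

    Reflection is about sample 0 on the left and sample n-1 on the right,
    which anchors the spline outside the observed range and damps end
    swings that would otherwise leak into late IMFs.
    """
    li = -indices[:2][::-1]
    lv = values[:2][::-1]
    ri = 2 * (n - 1) - indices[-2:][::-1]
    rv = values[-2:][::-1]
    knots_i = np.concatenate((li, indices, ri))
    knots_v = np.concatenate((lv, values, rv))
    # guard against coincident knots (extremum exactly at a boundary sample)
    keep = np.concatenate(([True], np.diff(knots_i) > 0))
    return knots_i[keep], knots_v[keep]


def _envelope(indices: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    knots_i, knots_v = _mirrored_knots(indices, values, n)
    t = np.arange(n)
    if len(knots_i) < 4:
        return np.interp(t, knots_i, knots_v)
    return CubicSpline(knots_i, knots_v, bc_type="natural")(t)


def compute_envelopes(values, extrema: ExtremaSet | None = None) -> EnvelopePair:
    """Interpolate upper/lower envelopes through the maxima/minima.

    Requires at least two maxima and two minima; otherwise the caller should
    treat the decomposition as complete (:class:`NotEnoughExtremaError`).
    """
    x = _as_signal(values)
    if extrema is None:
        extrema = find_extrema(x)
    if len(extrema.maxima) < 2 or len(extrema.minima) < 2:
        raise NotEnoughExtremaError(
            f"need >= 2 maxima and >= 2 minima, got "
            f"{len(extrema.maxima)} / {len(extrema.minima)}"
        )
    upper = _envelope(extrema.maxima, x[extrema.maxima], len(x))
    lower = _envelope(extrema.minima, x[extrema.minima], len(x))
    return EnvelopePair(upper=upper, lower=lower)


def count_zero_crossings(values) -> int:
    """Sign changes between consecutive samples.

    An exact zero inherits the previous nonzero sign (so a touch-and-go zero
    is counted once); leading zeros are ignored.
    """
    x = np.asarray(values, dtype=np.float64)
    s = np.sign(x)
    nz = s[s != 0.0]
    if len(nz) < 2:
        return 0
    return int(np.count_nonzero(np.diff(nz) != 0.0))


def is_imf(values, config: SiftConfig | None = None) -> IMFCheck:
    """Test the two IMF conditions on a candidate signal.

    Condition 1: |#extrema - #zero crossings| <= 1.
    Condition 2: max |mean envelope| <= imf_mean_tolerance * RMS(candidate).
    A candidate without two extrema on each side fails condition 2 outright
    (the mean envelope is not even computable).
    """
    cfg = config or SiftConfig()
    x = _as_signal(values)
    ext = find_extrema(x)
    nzc = count_zero_crossings(x)
    counts_ok = abs(ext.n_extrema - nzc) <= 1
    rms = float(np.sqrt(np.mean(x**2)))
    try:
        env = compute_envelopes(x, ext)
    except NotEnoughExtremaError:
        return IMFCheck(False, counts_ok, False, ext.n_extrema, nzc, float("nan"))
    max_abs_mean = float(np.max(np.abs(env.mean)))
    mean_ok = max_abs_mean <= cfg.imf_mean_tolerance * rms if rms > 0 else True
    return IMFCheck(counts_ok and mean_ok, counts_ok, mean_ok, ext.n_extrema, nzc, max_abs_mean)


def sift_imf(values, config: SiftConfig | None = None) -> SiftResult:
    """Extract one IMF by iterative envelope-mean subtraction.

    Each iteration forms h_k = h_{k-1} - m_{k-1} where m is the envelope
    mean. The loop stops as soon as the Cauchy criterion
    SD = sum(m^2)/sum(h^2) < sd_threshold holds *and* the candidate passes
    the IMF test; a candidate that already is an IMF is returned untouched
    with sift_count 0. Hitting ``max_sift_iters`` returns the current
    candidate with ``converged=False``.
    """
    cfg = config or SiftConfig()
    h = _as_signal(values).copy()
    for k in range(cfg.max_sift_iters):
        ext = find_extrema(h)
        if len(ext.maxima) < 2 or len(ext.minima) < 2:
            return SiftResult(h, k, converged=True, exhausted=True)
        env = compute_envelopes(h, ext)
        m = env.mean
        denom = float(np.sum(h**2))
        if denom == 0.0:
            return SiftResult(h, k, converged=True, exhausted=True)
        sd = float(np.sum(m**2)) / denom
        if sd < cfg.sd_threshold and is_imf(h, cfg).is_imf:
            return SiftResult(h, k, converged=True)
        h = h - m
    return SiftResult(h, cfg.max_sift_iters, converged=bool(is_imf(h, cfg).is_imf))


def decompose(values, config: SiftConfig | None = None) -> Decomposition:
    """Full EMD: peel IMFs off successive residues until none remain.

    Extraction stops when the residue is monotone or lacks two extrema on
    either side (so no envelope pair exists), or when ``max_imfs`` is
    reached. A candidate whose RMS is below 1e-12 of the input's RMS is
    discarded and ends the loop: such "oscillations" are float rounding
    noise on an otherwise flat residue, not signal. The telescoping
    construction makes ``sum(imfs) + residue == input`` hold to rounding
    error.
    """
    x = _as_signal(values)
    cfg = config or SiftConfig()
    floor = 1e-12 * float(np.sqrt(np.mean(x**2)))
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    converged: list[bool] = []
    while cfg.max_imfs is None or len(imfs) < cfg.max_imfs:
        ext = find_extrema(residue)
        if len(ext.maxima) < 2 or len(ext.minima) < 2:
            break
        result = sift_imf(residue, cfg)
        if result.exhausted:
            # the residue's remaining oscillation is too weak to yield a
            # valid IMF (counts differ by <= 1 after a few subtractions):
            # stop here, leaving it in the residue
            break
        if float(np.sqrt(np.mean(result.imf**2))) <= floor:
            break
        imfs.append(result.imf)
        counts.append(result.sift_count)
        converged.append(result.converged)
        residue = residue - result.imf
    return Decomposition(imfs=imfs, residue=residue, sift_counts=counts, converged=converged)
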