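"""Approximate entropy and cross approximate entropy (C-ApEn).

C-ApEn quantifies the asynchrony between two simultaneously recorded
signals: delay-embedded templates of one series are matched against the
other series under the Chebyshev (maximum-coordinate) norm, and the
entropy is the drop in log conditional match probability when the
template length grows from ``m`` to ``m + 1``.  A *higher* value means
the series are harder to predict from one another (more asynchrony);
for EEG channel pairs it is read as weaker waveform coupling between
the underlying cortical sites.

Both series are standardized to zero mean and unit variance before
matching, so the tolerance ``r`` is expressed as a fraction of the
signal SD and the measure is invariant under positive affine rescaling
of either input.

Unlike single-series ApEn, a cross template has no guaranteed
self-match, so a template may match nothing and the log would diverge.
Following common practice we substitute the minimal nonzero probability
``1/n_targets`` and flag the value (``floor_triggered``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateEpochError",
    "EmbeddingParams",
    "SignalEpoch",
    "CApEnValue",
    "standardize",
    "embed",
    "match_fraction",
    "phi",
    "cross_apen",
    "cross_apen_epochs",
    "apen",
    "cross_apen_naive",
]

logger = logging.getLogger(__name__)


class DegenerateEpochError(ValueError):
    """Raised when an epoch has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class EmbeddingParams:
    """Parameters of the entropy estimator.

    Parameters
    ----------
    m : int
        Embedding (template) dimension. Default 2, the standard choice
        for ApEn-family estimators on EEG.
    r_frac : float
        Match tolerance as a fraction of the (unit) standard deviation,
        ``0 < r_frac < 1``. Default 0.2.
    lag : int
        Embedding delay in samples. Default 1.
    epoch_len : int
        Samples per analysis window; 1000 corresponds to 2 s at 500 Hz.
    """

    m: int = 2
    r_frac: float = 0.2
    lag: int = 1
    epoch_len: int = 1000

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if not 0.0 < self.r_frac < 1.0:
            raise ValueError(f"r_frac must lie in (0, 1), got {self.r_frac}")
        if self.lag < 1:
            raise ValueError(f"lag must be >= 1, got {self.lag}")
        min_len = (self.m + 1) * self.lag + 10
        if self.epoch_len <= min_len:
            raise ValueError(
                f"epoch_len must exceed (m+1)*lag + 10 = {min_len}, got {self.epoch_len}"
            )


@dataclass(frozen=True)
class SignalEpoch:
    """One channel's samples for one analysis epoch."""

    samples: np.ndarray
    rate: float
    channel: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(samples) < 100:
            raise ValueError(f"epoch needs >= 100 samples, got {len(samples)}")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"epoch for channel {self.channel!r} contains non-finite samples")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")


@dataclass(frozen=True)
class CApEnValue:
    """A C-ApEn (or ApEn) estimate with its bookkeeping flags."""

    value: float
    n_templates_m: int
    floor_triggered: bool = False
    degenerate: bool = False


def _as_array(x) -> np.ndarray:
    if isinstance(x, SignalEpoch):
        return x.samples
    return np.asarray(x, dtype=float)


def standardize(epoch):
    """Scale to zero mean and unit SD.

    Accepts a :class:`SignalEpoch` (returned as a new ``SignalEpoch``)
    or a plain sequence (returned as an array). Raises
    :class:`DegenerateEpochError` on constant input; callers inside the
    pipeline route that case to the constant-series convention of
    :func:`cross_apen` instead.
    """
    x = _as_array(epoch)
    sd = float(x.std())
    if sd == 0.0 or not math.isfinite(sd):
        raise DegenerateEpochError("constant epoch: standard deviation is zero")
    z = (x - x.mean()) / sd
    if isinstance(epoch, SignalEpoch):
        return SignalEpoch(z, epoch.rate, epoch.channel)
    return z


def embed(series, m: int, lag: int = 1) -> np.ndarray:
    """Delay-embed ``series`` into ``m``-dimensional vectors.

    Returns an ``(n, m)`` array with ``n = N - (m - 1) * lag`` rows;
    row ``i`` is ``(series[i], series[i + lag], ..., series[i + (m-1)lag])``.
    """
    x = _as_array(series)
    need = (m - 1) * lag + 1
    if len(x) < need:
        raise ValueError(
            f"series of length {len(x)} too short to embed: need at least "
            f"{need} samples for m={m}, lag={lag}"
        )
    n = len(x) - (m - 1) * lag
    idx = np.arange(n)[:, None] + lag * np.arange(m)[None, :]
    return x[idx]


def match_fraction(template, targets, r: float) -> float:
    """Fraction of ``targets`` within Chebyshev distance ``r`` of ``template``."""
    t = np.atleast_1d(np.asarray(template, dtype=float))
    targ = np.atleast_2d(np.asarray(targets, dtype=float))
    if targ.shape[0] == 0:
        raise ValueError("empty target set")
    if targ.shape[1] != t.shape[0]:
        raise ValueError(
            f"dimension mismatch: template has {t.shape[0]} coordinates, "
            f"targets have {targ.shape[1]}"
        )
    dist = np.max(np.abs(targ - t[None, :]), axis=1)
    return float(np.mean(dist <= r))


def phi(query_emb, target_emb, r: float, floor: bool = True) -> float:
    """Mean over query templates of ln(match fraction against targets).

    With ``floor`` on, a zero match fraction is replaced by
    ``1 / n_targets``; with it off, a zero fraction raises.
    """
    value, _ = _phi_flagged(query_emb, target_emb, r, floor)
    return value


def _phi_flagged(query_emb, target_emb, r: float, floor: bool) -> tuple[float, bool]:
    q = np.atleast_2d(np.asarray(query_emb, dtype=float))
    t = np.atleast_2d(np.asarray(target_emb, dtype=float))
    if q.shape[0] == 0 or t.shape[0] == 0:
        raise ValueError("embedded sets must be nonempty")
    if q.shape[1] != t.shape[1]:
        raise ValueError("embedded sets must have equal dimension")
    # Chebyshev distances, one query row at a time is avoided: broadcast.
    dist = np.max(np.abs(q[:, None, :] - t[None, :, :]), axis=2)
    counts = (dist <= r).sum(axis=1)
    n_targets = t.shape[0]
    floored = bool(np.any(counts == 0))
    if floored and not floor:
        raise ValueError("zero match fraction: logarithm undefined with floor disabled")
    frac = np.where(counts > 0, counts, 1) / n_targets
    return float(np.mean(np.log(frac))), floored


try:  # optional JIT acceleration; the numpy path below is the reference
    import numba as _numba

    @_numba.njit(cache=False)
    def _capen_epoch_jit(x, y, r, m, lag):  # pragma: no cover - jitted
        """Symmetrized C-ApEn of one standardized epoch pair.

        Sort-accelerated exact counting: candidates for the first
        template coordinate come from a binary-search window on the
        sorted target series; remaining coordinates are checked
        explicitly, so results equal full enumeration bit-for-bit.
        Returns (value, floored).
        """
        N = x.shape[0]
        n_m = N - (m - 1) * lag
        n_m1 = N - m * lag
        cm_q = np.zeros(n_m, np.int64)
        cm_t = np.zeros(n_m, np.int64)
        c1_q = np.zeros(n_m1, np.int64)
        c1_t = np.zeros(n_m1, np.int64)
        y0 = y[:n_m]
        order = np.argsort(y0)
        ys = y0[order]
        for i in range(n_m):
            xi = x[i]
            lo = np.searchsorted(ys, xi - r, side="left")
            hi = np.searchsorted(ys, xi + r, side="right")
            for k in range(lo, hi):
                j = order[k]
                ok = True
                for c in range(1, m):
                    if abs(x[i + c * lag] - y[j + c * lag]) > r:
                        ok = False
                        break
                if ok:
                    cm_q[i] += 1
                    cm_t[j] += 1
                    if i < n_m1 and j < n_m1:
                        if abs(x[i + m * lag] - y[j + m * lag]) <= r:
                            c1_q[i] += 1
                            c1_t[j] += 1
        floored = False
        phi_m_q = 0.0
        phi_m_t = 0.0
        for i in range(n_m):
            cq = cm_q[i]
            ct = cm_t[i]
            if cq == 0:
                cq = 1
                floored = True
            if ct == 0:
                ct = 1
                floored = True
            phi_m_q += np.log(cq / n_m)
            phi_m_t += np.log(ct / n_m)
        phi_m_q /= n_m
        phi_m_t /= n_m
        phi_1_q = 0.0
        phi_1_t = 0.0
        for i in range(n_m1):
            cq = c1_q[i]
            ct = c1_t[i]
            if cq == 0:
                cq = 1
                floored = True
            if ct == 0:
                ct = 1
                floored = True
            phi_1_q += np.log(cq / n_m1)
            phi_1_t += np.log(ct / n_m1)
        phi_1_q /= n_m1
        phi_1_t /= n_m1
        value = 0.5 * (phi_m_q - phi_1_q) + 0.5 * (phi_m_t - phi_1_t)
        return value, floored

    @_numba.njit(cache=False)
    def _capen_batch_jit(X, Y, r, m, lag):  # pragma: no cover - jitted
        E = X.shape[0]
        values = np.empty(E)
        floors = np.zeros(E, np.bool_)
        for e in range(E):
            v, f = _capen_epoch_jit(X[e], Y[e], r, m, lag)
            values[e] = v
            floors[e] = f
        return values, floors

except ImportError:  # pragma: no cover
    _capen_epoch_jit = None
    _capen_batch_jit = None


def _phi_pair_from_mask(mask: np.ndarray, m: int, lag: int) -> tuple[float, float, bool]:
    """Both directional Phi^m values from a level-1 match mask.

    ``mask[i, j]`` is ``|u_i - v_j| <= r``.  The level-``m`` match matrix
    is the AND of ``m`` lag-shifted diagonal blocks; the v->u direction
    is its transpose, so one matrix serves both directions.
    """
    n = mask.shape[0] - (m - 1) * lag
    if n < 1:
        raise ValueError(f"series too short for m={m}, lag={lag}")
    a = mask[:n, :n]
    if m > 1:
        a = a.copy()
        for k in range(1, m):
            s = k * lag
            a &= mask[s : s + n, s : s + n]
    counts_uv = a.sum(axis=1)
    counts_vu = a.sum(axis=0)
    floored = bool((counts_uv == 0).any() or (counts_vu == 0).any())
    phi_uv = float(np.mean(np.log(np.where(counts_uv > 0, counts_uv, 1) / n)))
    phi_vu = float(np.mean(np.log(np.where(counts_vu > 0, counts_vu, 1) / n)))
    return phi_uv, phi_vu, floored


def cross_apen(u, v, params: EmbeddingParams | None = None) -> CApEnValue:
    """Direction-symmetrized cross approximate entropy of two epochs.

    Both inputs are standardized internally, so the tolerance is
    ``params.r_frac`` in units of each signal's SD.  The value is

    ``1/2 [Phi^m(u->v) - Phi^{m+1}(u->v)] + 1/2 [Phi^m(v->u) - Phi^{m+1}(v->u)]``

    averaging the two template/target orderings, which an unordered
    electrode pair does not distinguish.  A constant epoch in either
    input returns 0 (perfectly predictable) with ``degenerate=True``.
    """
    params = params or EmbeddingParams()
    x = _as_array(u)
    y = _as_array(v)
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    m, lag, r = params.m, params.lag, params.r_frac
    n_m = len(x) - (m - 1) * lag
    n_m1 = len(x) - m * lag
    if n_m1 < 1:
        raise ValueError(
            f"series of length {len(x)} too short: need > {m * lag} samples "
            f"for m={m}, lag={lag}"
        )
    if x.std() == 0.0 or y.std() == 0.0:
        logger.warning("degenerate (constant) epoch: returning C-ApEn = 0 by convention")
        return CApEnValue(0.0, n_m, floor_triggered=False, degenerate=True)
    x = standardize(x)
    y = standardize(y)
    if _capen_epoch_jit is not None:
        value, floored = _capen_epoch_jit(x, y, float(r), m, lag)
    else:
        mask = np.abs(x[:, None] - y[None, :]) <= r
        pm_uv, pm_vu, fl_m = _phi_pair_from_mask(mask, m, lag)
        pm1_uv, pm1_vu, fl_m1 = _phi_pair_from_mask(mask, m + 1, lag)
        floored = fl_m or fl_m1
        value = 0.5 * (pm_uv - pm1_uv) + 0.5 * (pm_vu - pm1_vu)
    return CApEnValue(float(value), n_m, floor_triggered=bool(floored))


def cross_apen_epochs(
    X, Y, params: EmbeddingParams | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """C-ApEn for stacked epochs of one channel pair.

    ``X`` and ``Y`` are ``(n_epochs, epoch_len)`` arrays.  Returns
    ``(values, floored, degenerate)`` per epoch; equivalent to calling
    :func:`cross_apen` epoch by epoch but amortizes the dispatch.
    """
    params = params or EmbeddingParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"epoch stacks differ in shape: {X.shape} vs {Y.shape}")
    E = X.shape[0]
    values = np.zeros(E)
    floors = np.zeros(E, dtype=bool)
    degen = np.zeros(E, dtype=bool)
    sx = X.std(axis=1)
    sy = Y.std(axis=1)
    degen = (sx == 0.0) | (sy == 0.0)
    if degen.any():
        logger.warning(
            "%d degenerate (constant) epochs: C-ApEn = 0 by convention",
            int(degen.sum()),
        )
    ok = ~degen
    if ok.any():
        Xs = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sx[ok, None]
        Ys = (Y[ok] - Y[ok].mean(axis=1, keepdims=True)) / sy[ok, None]
        if _capen_batch_jit is not None:
            v, f = _capen_batch_jit(
                np.ascontiguousarray(Xs),
                np.ascontiguousarray(Ys),
                float(params.r_frac),
                params.m,
                params.lag,
            )
        else:
            v = np.empty(Xs.shape[0])
            f = np.zeros(Xs.shape[0], dtype=bool)
            for e in range(Xs.shape[0]):
                res = cross_apen(Xs[e], Ys[e], params)
                v[e] = res.value
                f[e] = res.floor_triggered
        values[ok] = v
        floors[ok] = f
    return values, floors, degen


def apen(u, params: EmbeddingParams | None = None) -> CApEnValue:
    """Approximate entropy: the self-comparison special case of C-ApEn."""
    return cross_apen(u, u, params)


def cross_apen_naive(u, v, params: EmbeddingParams | None = None) -> float:
    """Brute-force reference implementation (O(N^2) double loop).

    Enumerates every template/target pair explicitly in pure Python.
    Kept as an independent validation path for the vectorized
    :func:`cross_apen`; orders of magnitude slower.
    """
    params = params or EmbeddingParams()
    x = _as_array(u)
    y = _as_array(v)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    x = ((x - x.mean()) / x.std()).tolist()
    y = ((y - y.mean()) / y.std()).tolist()
    m, lag, r = params.m, params.lag, params.r_frac
    N = len(x)

    def phi_dir(a, b, d):
        n = N - (d - 1) * lag
        total = 0.0
        for i in range(n):
            c = 0
            for j in range(n):
                dist = 0.0
                for k in range(d):
                    delta = abs(a[i + k * lag] - b[j + k * lag])
                    if delta > dist:
                        dist = delta
                if dist <= r:
                    c += 1
            total += math.log(c / n) if c > 0 else math.log(1.0 / n)
        return total / n

    val = 0.0
    for a, b in ((x, y), (y, x)):
        val += 0.5 * (phi_dir(a, b, m) - phi_dir(a, b, m + 1))
    return val
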