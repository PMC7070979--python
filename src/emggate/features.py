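"""The 26 streaming time-domain feature state machines.

Every feature is an event or magnitude stream pushed through the same
accumulate-and-scale smoother (an exponentially decaying moving average)::

    feat_i = saturate((feat_{i-1} + f(x_i)) * b, lb, ub)

where ``f`` depends on the family:

* **ZCR** — zero crossings of the signal beyond a hysteresis band; each
  crossing contributes 100.
* **MCR** — crossings of the (delayed, scaled) signal through its own
  smoothed version; detects the small artifact superimposed on short
  contractions.
* **SSC** — slope-sign changes of the smoothed signal, optionally requiring
  the slope to persist between ``dmin`` and ``dmax`` samples.
* **WFL** — scaled first difference magnitude (waveform length).
* **MAV1 / MAV2** — mean absolute value, and the smoothed magnitude of its
  change over a short delay.
* **WAM1 / WAM2** — threshold exceedances of the signal (Willison
  amplitude), raw or relative to the smoothed signal.
* **VAR** — the squared signal.

All arithmetic is integer with dyadic coefficients (multiply + arithmetic
right shift); the saturation bounds double as overflow protection and, for
the tight "S" variants, as a transition accelerator. Batch execution runs
through a numba kernel; :class:`FeatureStream` is the sample-by-sample
reference and is bit-identical to the batch path. A floating-point
reference (same recursions, no truncation) is exposed for fidelity checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from numba import njit

from .fixed_point import FxCoeff, fx_scale, quantize_coeff, saturate

__all__ = [
    "FeatureParams",
    "FeatureStream",
    "FeatureBank",
    "registry",
    "feature_names",
    "run_feature",
    "run_feature_float",
]

_FAMILY_CODE = {"ZCR": 0, "MCR": 1, "SSC": 2, "WFL": 3, "MAV1": 4, "MAV2": 5, "WAM1": 6, "WAM2": 7, "VAR": 8}
_ONE = FxCoeff(1.0, 1, 0)


@dataclass(frozen=True)
class FeatureParams:
    """Constants of one feature variant (one row of the parameter registry)."""

    name: str
    family: str
    b: FxCoeff
    c: FxCoeff = _ONE
    d: FxCoeff = _ONE
    e: FxCoeff = _ONE
    delay: int = 0
    hyst: int = 0
    lb: int = 0
    ub: int = 2**16 - 1
    ub_inner: int = 2**16 - 1  # bound on MAV2's internal MAV1 recursion
    thresh: int = 0
    dmin: int = 0
    dmax: int = 2**16 - 1
    update_value: int = 100

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ValueError(f"{self.name}: lb > ub")
        if self.dmin > self.dmax:
            raise ValueError(f"{self.name}: dmin > dmax")
        if self.update_value not in (10, 100):
            raise ValueError(f"{self.name}: update_value must be 10 or 100")


def _coeff(value: float | int) -> FxCoeff:
    if isinstance(value, int) or float(value).is_integer():
        return FxCoeff(float(value), int(value), 0)
    return quantize_coeff(float(value), k_max=8)


def _load_registry() -> dict[str, FeatureParams]:
    raw = json.loads(resources.files("emggate.data").joinpath("feature_params.json").read_text())
    out: dict[str, FeatureParams] = {}
    for row in raw["features"]:
        fam = row["family"]
        out[row["name"]] = FeatureParams(
            name=row["name"],
            family=fam,
            b=_coeff(row["b"]),
            c=_coeff(row.get("c", 1)),
            d=_coeff(row.get("d", 1)),
            e=_coeff(row.get("e", 1)),
            delay=int(row.get("delay", 0)),
            hyst=int(row.get("hyst", 0)),
            lb=int(row.get("lb", 0)),
            ub=int(row.get("ub2", row.get("ub", 2**16 - 1))),
            ub_inner=int(row.get("ub1", 2**16 - 1)),
            thresh=int(row.get("thresh", 0)),
            dmin=int(row.get("dmin", 0)),
            dmax=int(row.get("dmax", 2**16 - 1)),
            update_value=int(row.get("update_value", 100)),
        )
    return out


_REGISTRY: dict[str, FeatureParams] | None = None


def registry() -> dict[str, FeatureParams]:
    """All 26 canonical feature variants, in canonical (table) order."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return _REGISTRY


def feature_names() -> list[str]:
    return list(registry().keys())


@njit(cache=True)
def _kernel_int(x, kind, m_b, k_b, m_c, k_c, m_d, k_d, m_e, k_e,
                delay, hyst, lb, ub, ub_inner, thresh, dmin, dmax, upd):  # pragma: no cover
    n = x.shape[0]
    out = np.empty(n, dtype=np.int64)
    feat = np.int64(lb)
    smo = np.int64(0)
    s = 0
    w = 0
    p = 0
    xprev = np.int64(0)
    mav1 = np.int64(0)
    buflen = delay if delay > 0 else 1
    mbuf = np.zeros(buflen, dtype=np.int64)  # MAV2's delayed inner-MAV1 ring
    for i in range(n):
        xi = x[i]
        f = np.int64(0)
        if kind == 0:  # ZCR
            if xi > hyst and s == 0:
                f = upd
                s = 1
            elif xi < -hyst and s == 1:
                f = upd
                s = 0
        elif kind == 1:  # MCR
            smo = ((smo + xi) * m_c) >> k_c
            v = (smo * m_e) >> k_e
            xd = x[i - delay] if i >= delay else np.int64(0)
            xd = (xd * m_d) >> k_d
            if xd > v + hyst and s == 0:
                f = upd
                s = 1
            elif xd < v - hyst and s == 1:
                f = upd
                s = 0
        elif kind == 2:  # SSC (ordered branch cascade)
            u = smo
            smo = ((smo + xi) * m_c) >> k_c
            v = smo
            if v > u and s == 0 and w >= dmin and p < dmax:
                f = upd
                s = 1
                w = 0
                p = 0
            elif v > u and s == 0 and w >= dmin:
                s = 1
                w = 0
                p = 0
            elif v > u and s == 0:
                w += 1
            elif v > u:
                s = 1
                w = 0
                p += 1
            elif v < u and s == 1 and w >= dmin and p < dmax:
                f = upd
                s = 0
                w = 0
                p = 0
            elif v < u and s == 1 and w >= dmin:
                s = 0
                w = 0
                p = 0
            elif v < u and s == 1:
                w += 1
            elif v < u:
                s = 0
                w = 0
                p += 1
        elif kind == 3:  # WFL
            dd = xi - xprev
            if dd < 0:
                dd = -dd
            f = (dd * m_d) >> k_d
            xprev = xi
        elif kind == 4:  # MAV1
            f = xi if xi >= 0 else -xi
        elif kind == 5:  # MAV2
            ax = xi if xi >= 0 else -xi
            mav1 = ((mav1 + ax) * m_b) >> k_b
            if mav1 > ub_inner:
                mav1 = np.int64(ub_inner)
            if delay > 0:
                old = mbuf[i % buflen]
                mbuf[i % buflen] = mav1
                dd = mav1 - old
                f = dd if dd >= 0 else -dd
        elif kind == 6:  # WAM1
            ax = xi if xi >= 0 else -xi
            if ax > thresh:
                f = upd
        elif kind == 7:  # WAM2
            smo = ((smo + xi) * m_c) >> k_c
            xd = x[i - delay] if i >= delay else np.int64(0)
            dd = ((xd * m_d) >> k_d) - smo
            if dd < 0:
                dd = -dd
            if dd > thresh:
                f = upd
        else:  # VAR
            f = xi * xi
        if kind == 5:
            feat = ((feat + f) * m_c) >> k_c
        else:
            feat = ((feat + f) * m_b) >> k_b
        if feat > ub:
            feat = np.int64(ub)
        elif feat < lb:
            feat = np.int64(lb)
        out[i] = feat
    return out


@njit(cache=True)
def _kernel_float(x, kind, b, c, d, e, delay, hyst, lb, ub, ub_inner,
                  thresh, dmin, dmax, upd):  # pragma: no cover
    n = x.shape[0]
    out = np.empty(n, dtype=np.float64)
    feat = float(lb)
    smo = 0.0
    s = 0
    w = 0
    p = 0
    xprev = 0.0
    mav1 = 0.0
    buflen = delay if delay > 0 else 1
    mbuf = np.zeros(buflen, dtype=np.float64)
    for i in range(n):
        xi = x[i]
        f = 0.0
        if kind == 0:
            if xi > hyst and s == 0:
                f = upd
                s = 1
            elif xi < -hyst and s == 1:
                f = upd
                s = 0
        elif kind == 1:
            smo = (smo + xi) * c
            v = smo * e
            xd = x[i - delay] if i >= delay else 0.0
            xd = xd * d
            if xd > v + hyst and s == 0:
                f = upd
                s = 1
            elif xd < v - hyst and s == 1:
                f = upd
                s = 0
        elif kind == 2:
            u = smo
            smo = (smo + xi) * c
            v = smo
            if v > u and s == 0 and w >= dmin and p < dmax:
                f = upd
                s = 1
                w = 0
                p = 0
            elif v > u and s == 0 and w >= dmin:
                s = 1
                w = 0
                p = 0
            elif v > u and s == 0:
                w += 1
            elif v > u:
                s = 1
                w = 0
                p += 1
            elif v < u and s == 1 and w >= dmin and p < dmax:
                f = upd
                s = 0
                w = 0
                p = 0
            elif v < u and s == 1 and w >= dmin:
                s = 0
                w = 0
                p = 0
            elif v < u and s == 1:
                w += 1
            elif v < u:
                s = 0
                w = 0
                p += 1
        elif kind == 3:
            f = abs(xi - xprev) * d
            xprev = xi
        elif kind == 4:
            f = abs(xi)
        elif kind == 5:
            mav1 = (mav1 + abs(xi)) * b
            if mav1 > ub_inner:
                mav1 = float(ub_inner)
            if delay > 0:
                old = mbuf[i % buflen]
                mbuf[i % buflen] = mav1
                f = abs(mav1 - old)
        elif kind == 6:
            if abs(xi) > thresh:
                f = upd
        elif kind == 7:
            smo = (smo + xi) * c
            xd = x[i - delay] if i >= delay else 0.0
            if abs(xd * d - smo) > thresh:
                f = upd
        else:
            f = xi * xi
        if kind == 5:
            feat = (feat + f) * c
        else:
            feat = (feat + f) * b
        if feat > ub:
            feat = float(ub)
        elif feat < lb:
            feat = float(lb)
        out[i] = feat
    return out


def run_feature(params: FeatureParams, x: np.ndarray) -> np.ndarray:
    """Batch fixed-point evaluation of one feature over an integer signal."""
    xs = np.ascontiguousarray(x, dtype=np.int64)
    return _kernel_int(
        xs, _FAMILY_CODE[params.family],
        params.b.m, params.b.k, params.c.m, params.c.k,
        params.d.m, params.d.k, params.e.m, params.e.k,
        params.delay, params.hyst, params.lb, params.ub, params.ub_inner,
        params.thresh, params.dmin, params.dmax, params.update_value,
    )


def run_feature_float(params: FeatureParams, x: np.ndarray) -> np.ndarray:
    """Floating-point reference: same recursions with the exact dyadic
    coefficient values but no integer truncation."""
    xs = np.ascontiguousarray(x, dtype=np.float64)
    return _kernel_float(
        xs, _FAMILY_CODE[params.family],
        params.b.value, params.c.value, params.d.value, params.e.value,
        params.delay, params.hyst, params.lb, params.ub, params.ub_inner,
        params.thresh, params.dmin, params.dmax, params.update_value,
    )


class FeatureStream:
    """Sample-by-sample fixed-point evaluation of one feature variant.

    Mirrors the batch kernel exactly; exists both as the embedded-style
    reference implementation and to make the streamed-equals-batch
    equivalence testable.
    """

    def __init__(self, params: FeatureParams) -> None:
        self.p = params
        self._kind = _FAMILY_CODE[params.family]
        self.reset()

    def reset(self) -> None:
        p = self.p
        self.feat = p.lb
        self.smo = 0
        self.s = 0
        self.w = 0
        self.p_count = 0
        self.xprev = 0
        self.mav1 = 0
        n = max(p.delay, 1)
        self._xbuf = [0] * (n + 1)
        self._mbuf = [0] * (p.delay if p.delay > 0 else 1)
        self._i = 0

    def step(self, x_i: int) -> int:
        p = self.p
        xi = int(x_i)
        f = 0
        kind = self._kind
        if kind == 0:
            if xi > p.hyst and self.s == 0:
                f, self.s = p.update_value, 1
            elif xi < -p.hyst and self.s == 1:
                f, self.s = p.update_value, 0
        elif kind == 1:
            self.smo = fx_scale(self.smo + xi, p.c)
            v = fx_scale(self.smo, p.e)
            xd = self._delayed(xi)
            xd = fx_scale(xd, p.d)
            if xd > v + p.hyst and self.s == 0:
                f, self.s = p.update_value, 1
            elif xd < v - p.hyst and self.s == 1:
                f, self.s = p.update_value, 0
        elif kind == 2:
            u = self.smo
            self.smo = fx_scale(self.smo + xi, p.c)
            v = self.smo
            if v > u and self.s == 0 and self.w >= p.dmin and self.p_count < p.dmax:
                f, self.s, self.w, self.p_count = p.update_value, 1, 0, 0
            elif v > u and self.s == 0 and self.w >= p.dmin:
                self.s, self.w, self.p_count = 1, 0, 0
            elif v > u and self.s == 0:
                self.w += 1
            elif v > u:
                self.s, self.w = 1, 0
                self.p_count += 1
            elif v < u and self.s == 1 and self.w >= p.dmin and self.p_count < p.dmax:
                f, self.s, self.w, self.p_count = p.update_value, 0, 0, 0
            elif v < u and self.s == 1 and self.w >= p.dmin:
                self.s, self.w, self.p_count = 0, 0, 0
            elif v < u and self.s == 1:
                self.w += 1
            elif v < u:
                self.s, self.w = 0, 0
                self.p_count += 1
        elif kind == 3:
            f = fx_scale(abs(xi - self.xprev), p.d)
            self.xprev = xi
        elif kind == 4:
            f = abs(xi)
        elif kind == 5:
            self.mav1 = min(fx_scale(self.mav1 + abs(xi), p.b), p.ub_inner)
            if p.delay > 0:
                old = self._mbuf[self._i % len(self._mbuf)]
                self._mbuf[self._i % len(self._mbuf)] = self.mav1
                f = abs(self.mav1 - old)
        elif kind == 6:
            if abs(xi) > p.thresh:
                f = p.update_value
        elif kind == 7:
            self.smo = fx_scale(self.smo + xi, p.c)
            xd = self._delayed(xi)
            if abs(fx_scale(xd, p.d) - self.smo) > p.thresh:
                f = p.update_value
        else:
            f = xi * xi
        ema_coeff = p.c if kind == 5 else p.b
        self.feat = saturate(fx_scale(self.feat + f, ema_coeff), p.lb, p.ub)
        self._push(xi)
        self._i += 1
        return self.feat

    def _delayed(self, xi: int) -> int:
        # x_{i-delay}; the ring holds past inputs, zero before the start
        if self.p.delay == 0:
            return xi
        return self._xbuf[(self._i - self.p.delay) % len(self._xbuf)] if self._i >= self.p.delay else 0

    def _push(self, xi: int) -> None:
        self._xbuf[self._i % len(self._xbuf)] = xi


class FeatureBank:
    """Runs a configured subset of the 26 variants over one input stream."""

    def __init__(self, names: list[str] | None = None) -> None:
        reg = registry()
        self.names = list(names) if names is not None else list(reg.keys())
        unknown = set(self.names) - set(reg.keys())
        if unknown:
            raise KeyError(f"unknown feature variants: {sorted(unknown)}")
        self.params = [reg[n] for n in self.names]
        self._streams: list[FeatureStream] | None = None

    def run(self, x: np.ndarray, mode: str = "int") -> np.ndarray:
        """Batch evaluation: (n_samples, n_features) matrix at the input rate."""
        runner = run_feature if mode == "int" else run_feature_float
        cols = [runner(p, x) for p in self.params]
        return np.stack(cols, axis=1)

    def reset(self) -> None:
        self._streams = [FeatureStream(p) for p in self.params]

    def step(self, x_i: int) -> np.ndarray:
        """One 2 kHz tick of every configured variant (streaming mode)."""
        if self._streams is None:
            self.reset()
        assert self._streams is not None
        return np.array([s.step(x_i) for s in self._streams], dtype=np.int64)
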