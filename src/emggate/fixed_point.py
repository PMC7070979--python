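"""Integer arithmetic contract shared by the feature bank and quantized models.

Every multiplicative coefficient in the signal chain is a dyadic rational
``m / 2**k`` applied as a widening multiply followed by an arithmetic right
shift, mirroring what a 32-bit microcontroller with a hardware multiplier
does. Values are signed 32-bit; intermediate products are evaluated at
64-bit width before the shift. Shifts floor toward minus infinity
(two's-complement semantics), so ``fx_scale(-256, (1, 8)) == -1``.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FxCoeff",
    "FxOverflowError",
    "INT32_MIN",
    "INT32_MAX",
    "quantize_coeff",
    "fx_scale",
    "saturate",
    "check_int32",
]

INT32_MIN = -(2**31)
INT32_MAX = 2**31 - 1
_INT64_MIN = -(2**63)
_INT64_MAX = 2**63 - 1


class FxOverflowError(OverflowError):
    """A fixed-point value or intermediate product left its word width."""


@dataclass(frozen=True)
class FxCoeff:
    """A real coefficient and its dyadic approximation ``m / 2**k``.

    Parameters
    ----------
    target
        The real value the pair approximates (kept for round-tripping and
        reporting; arithmetic only ever uses ``m`` and ``k``).
    m
        Non-negative integer multiplier.
    k
        Right-shift amount in bits, 0–16.
    """

    target: float
    m: int
    k: int

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"multiplier must be non-negative, got {self.m}")
        if not 0 <= self.k <= 16:
            raise ValueError(f"shift must be in [0, 16], got {self.k}")

    @property
    def value(self) -> float:
        """The exact dyadic value ``m / 2**k``."""
        return self.m / (1 << self.k)

    def to_dict(self) -> dict:
        return {"target": self.target, "m": self.m, "k": self.k}

    @classmethod
    def from_dict(cls, d: dict) -> "FxCoeff":
        return cls(target=d["target"], m=int(d["m"]), k=int(d["k"]))


def quantize_coeff(target: float, k_max: int = 8) -> FxCoeff:
    """Best dyadic approximation ``m / 2**k`` of ``target`` with ``k <= k_max``.

    Ties between equally good ``(m, k)`` pairs are broken toward the smaller
    shift, so exact dyadic targets come back in lowest terms
    (``0.5 -> (1, 1)``, not ``(128, 8)``).

    Raises
    ------
    ValueError
        If ``target`` is negative or ``k_max`` outside [1, 16].
    """
    if target < 0:
        raise ValueError(f"coefficient targets are non-negative, got {target}")
    if not 1 <= k_max <= 16:
        raise ValueError(f"k_max must be in [1, 16], got {k_max}")
    if target == 0:
        return FxCoeff(target=0.0, m=0, k=0)
    best: tuple[float, int, int] | None = None
    for k in range(0, k_max + 1):
        m = round(target * (1 << k))
        err = abs(target - m / (1 << k))
        if best is None or err < best[0]:
            best = (err, m, k)
    assert best is not None
    return FxCoeff(target=float(target), m=best[1], k=best[2])


def check_int32(v: int) -> int:
    """Return ``v`` unchanged or raise if it leaves the signed 32-bit range."""
    if not INT32_MIN <= v <= INT32_MAX:
        raise FxOverflowError(f"value {v} outside signed 32-bit range")
    return v


def fx_scale(v: int, c: FxCoeff) -> int:
    """``floor(v * m / 2**k)`` with a 64-bit intermediate product.

    The shift is arithmetic, i.e. floors toward minus infinity for negative
    products, matching a two's-complement hardware shift.
    """
    prod = int(v) * c.m
    if not _INT64_MIN <= prod <= _INT64_MAX:
        raise FxOverflowError(f"intermediate product {v} * {c.m} exceeds 64 bits")
    return check_int32(prod >> c.k)


def saturate(v: int, lb: int, ub: int) -> int:
    """Clamp ``v`` into ``[lb, ub]``."""
    if lb > ub:
        raise ValueError(f"saturation bounds inverted: lb={lb} > ub={ub}")
    return min(max(int(v), lb), ub)
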