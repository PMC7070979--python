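"""Online decision post-processing between classifier and prosthesis drive.

A raw per-sample decision stream is *debounced*: the gated output may only
change class after strictly more than ``n_slope`` consecutive equal
decisions of the new class (i.e. at the (n_slope+1)-th), which suppresses
isolated misclassifications at the cost of ``n_slope + 1`` decision periods
of latency. Offline, n_slope is 2 for the 40 Hz models (NN, tree, logistic
regression) and 3 for the 250 Hz recurrent network; online the 2 kHz models
use 20 so the wall-clock delay stays comparable. The debounced decision
gates the delayed EMG envelope: during detected contractions the envelope
passes through; during artifacts the drive is turned off or the last value
is held, per policy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RuntimeConfig", "DecisionTrace", "debounce", "gate_output", "align"]


@dataclass
class RuntimeConfig:
    n_slope: int = 2
    delay_ms: float = 100.0
    policy: str = "off"       # "off" | "hold"
    rate_hz: float = 40.0
    strict: bool = True       # True: switch at the (n_slope+1)-th decision

    def __post_init__(self) -> None:
        if self.n_slope < 1:
            raise ValueError("n_slope must be >= 1")
        if self.policy not in ("off", "hold"):
            raise ValueError("policy must be 'off' or 'hold'")


@dataclass
class DecisionTrace:
    """Per-step record of the decision chain on the 1024 = 1.0 scale."""

    raw: np.ndarray
    debounced: np.ndarray
    envelope: np.ndarray
    output: np.ndarray

    def to_array(self) -> np.ndarray:
        return np.stack([self.raw, self.debounced, self.envelope, self.output], axis=1)


def debounce(decisions: np.ndarray, n_slope: int, initial: int = 0,
             strict: bool = True) -> np.ndarray:
    """Run-length filter on a binary decision stream.

    With ``strict`` (the default) the output switches to a new class only at
    the (n_slope + 1)-th consecutive decision of that class; any interruption
    resets the count. ``strict=False`` switches already at the n_slope-th.
    The initial output state is artifact (0) — fail-safe at startup.
    """
    need = n_slope + 1 if strict else n_slope
    out = np.empty(len(decisions), dtype=np.int64)
    state = initial
    run_val = initial
    run_len = 0
    for i, d in enumerate(np.asarray(decisions).astype(int)):
        if d == run_val:
            run_len += 1
        else:
            run_val = d
            run_len = 1
        if run_val != state and run_len >= need:
            state = run_val
        out[i] = state
    return out


def gate_output(debounced: np.ndarray, delayed_envelope: np.ndarray,
                policy: str = "off") -> np.ndarray:
    """Multiply the debounced decision into the delayed envelope.

    ``off``: artifact decisions force the output to zero. ``hold``: artifact
    decisions freeze the output at the last contraction-phase value.
    """
    d = np.asarray(debounced).astype(int)
    env = np.asarray(delayed_envelope)
    if len(d) != len(env):
        raise ValueError("decision and envelope streams differ in length")
    if policy == "off":
        return np.where(d == 1, env, 0)
    if policy != "hold":
        raise ValueError("policy must be 'off' or 'hold'")
    out = np.empty(len(env), dtype=env.dtype)
    held = 0
    for i in range(len(env)):
        if d[i] == 1:
            held = env[i]
        out[i] = held
    return out


def align(decisions: np.ndarray, envelope: np.ndarray, delay_ms: float,
          decision_hz: float, envelope_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Pair a decision stream with the envelope at the envelope rate.

    Decisions are upsampled by zero-order hold when the envelope runs
    faster; the envelope is delayed by ``round(delay_ms * envelope_hz /
    1000)`` samples (zero-padded head) so it lines up with the decision that
    gates it. Returns (decisions, delayed_envelope), equal length.
    """
    d = np.asarray(decisions).astype(int)
    env = np.asarray(envelope)
    if envelope_hz > decision_hz:
        if envelope_hz % decision_hz != 0:
            raise ValueError("envelope rate must be a multiple of the decision rate")
        rep = int(envelope_hz // decision_hz)
        d = np.repeat(d, rep)
    elif envelope_hz < decision_hz:
        raise ValueError("envelope rate below decision rate is not supported")
    k = int(round(delay_ms * envelope_hz / 1000.0))
    if k > 0:
        env = np.concatenate([np.zeros(k, dtype=env.dtype), env[:-k] if k < len(env) else env[:0]])
    n = min(len(d), len(env))
    return d[:n], env[:n]
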