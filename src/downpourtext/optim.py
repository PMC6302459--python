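"""Parameter-server optimizer rules: SGD, RMSProp, Adadelta, Adam.

Each rule maps a gradient packet (a dict of named tensors) to an additive
parameter delta, ``w <- w + delta``, advancing its per-tensor accumulator
state by one step.  The canonical published forms are used:

    SGD        delta = -eta * g
    RMSProp    E[g2] <- rho E[g2] + (1-rho) g2;  delta = -eta g / sqrt(E[g2] + eps)
    Adadelta   dual accumulators of g2 and delta2 (no learning rate):
               delta = -sqrt(E[d2] + eps) / sqrt(E[g2] + eps) * g
    Adam       bias-corrected first/second moments:
               delta = -eta * m_hat / (sqrt(v_hat) + eps)

Adam is implemented with bias correction (its canonical form).  Hyper-
parameter defaults follow the original publications: SGD eta=0.01; RMSProp
eta=0.001, rho=0.9, eps=1e-8; Adadelta rho=0.95, eps=1e-6; Adam eta=0.001,
beta1=0.9, beta2=0.999, eps=1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OPTIMIZER_NAMES", "OptimizerSpec", "OptimizerState",
    "init_state", "step", "converges_on_quadratic", "QUADRATIC_BUDGETS",
]

OPTIMIZER_NAMES = ("sgd", "rmsprop", "adadelta", "adam")

_DEFAULTS: dict[str, dict[str, float]] = {
    "sgd": {"learning_rate": 0.01},
    "rmsprop": {"learning_rate": 0.001, "rho": 0.9, "eps": 1e-8},
    "adadelta": {"rho": 0.95, "eps": 1e-6},
    "adam": {"learning_rate": 0.001, "beta1": 0.9, "beta2": 0.999, "eps": 1e-8},
}

# Iteration budgets for the 1-D quadratic sanity harness, frozen from
# running the scalar recursions under the default hyperparameters
# (convergence observed at 397 / 3053 / 985 / 6473 iterations).
QUADRATIC_BUDGETS: dict[str, int] = {
    "sgd": 2000,
    "rmsprop": 10000,
    "adadelta": 5000,
    "adam": 20000,
}


@dataclass(frozen=True)
class OptimizerSpec:
    """Optimizer name plus hyperparameters theta (unset ones take defaults).

    Adadelta takes no learning rate; passing one raises.
    """

    name: str
    learning_rate: float | None = None
    rho: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    eps: float | None = None

    def __post_init__(self) -> None:
        if self.name not in OPTIMIZER_NAMES:
            raise ValueError(f"unknown optimizer {self.name!r}; choose from {OPTIMIZER_NAMES}")
        if self.name == "adadelta" and self.learning_rate is not None:
            raise ValueError("adadelta takes no learning rate")
        for attr in ("rho", "beta1", "beta2"):
            v = getattr(self, attr)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"{attr} must lie in (0, 1)")
        for attr in ("learning_rate", "eps"):
            v = getattr(self, attr)
            if v is not None and v <= 0.0:
                raise ValueError(f"{attr} must be positive")

    def theta(self) -> dict[str, float]:
        """Resolved hyperparameters (defaults filled in), for logs/manifests."""
        out = dict(_DEFAULTS[self.name])
        for key in out:
            v = getattr(self, key)
            if v is not None:
                out[key] = v
        return out


@dataclass
class OptimizerState:
    """Per-tensor accumulators, shaped like the parameters; mutates via step."""

    spec: OptimizerSpec
    slots: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    t: int = 0


def init_state(spec: OptimizerSpec, shapes_like: dict[str, np.ndarray]) -> OptimizerState:
    """Zero-initialized accumulators matching the given parameter tensors."""
    slot_names = {
        "sgd": (),
        "rmsprop": ("sq_avg",),
        "adadelta": ("sq_avg", "delta_sq_avg"),
        "adam": ("m", "v"),
    }[spec.name]
    slots = {
        key: {name: np.zeros_like(tensor) for name in slot_names}
        for key, tensor in shapes_like.items()
    }
    return OptimizerState(spec=spec, slots=slots)


def step(
    spec: OptimizerSpec,
    state: OptimizerState,
    gradients: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """One optimizer application: returns the additive delta per tensor."""
    if state.spec.name != spec.name:
        raise ValueError("optimizer state was initialized for a different rule")
    for key, g in gradients.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in tensor {key!r}")
    theta = spec.theta()
    state.t += 1
    deltas: dict[str, np.ndarray] = {}
    if spec.name == "sgd":
        eta = theta["learning_rate"]
        for key, g in gradients.items():
            deltas[key] = -eta * g
    elif spec.name == "rmsprop":
        eta, rho, eps = theta["learning_rate"], theta["rho"], theta["eps"]
        for key, g in gradients.items():
            acc = state.slots[key]["sq_avg"]
            acc *= rho
            acc += (1.0 - rho) * g * g
            deltas[key] = -eta * g / np.sqrt(acc + eps)
    elif spec.name == "adadelta":
        rho, eps = theta["rho"], theta["eps"]
        for key, g in gradients.items():
            sq = state.slots[key]["sq_avg"]
            dsq = state.slots[key]["delta_sq_avg"]
            sq *= rho
            sq += (1.0 - rho) * g * g
            d = -np.sqrt(dsq + eps) / np.sqrt(sq + eps) * g
            dsq *= rho
            dsq += (1.0 - rho) * d * d
            deltas[key] = d
    else:  # adam
        eta, b1, b2, eps = theta["learning_rate"], theta["beta1"], theta["beta2"], theta["eps"]
        t = state.t
        for key, g in gradients.items():
            m = state.slots[key]["m"]
            v = state.slots[key]["v"]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = m / (1.0 - b1 ** t)
            v_hat = v / (1.0 - b2 ** t)
            deltas[key] = -eta * m_hat / (np.sqrt(v_hat) + eps)
    return deltas


def converges_on_quadratic(
    spec: OptimizerSpec,
    target: float = 3.0,
    w0: float = 0.0,
    tol: float = 1e-3,
    budget: int | None = None,
) -> np.ndarray:
    """Iterate the rule on the 1-D quadratic (w - target)^2 until |w - target| < tol.

    Returns the trace of iterates (including w0).  Raises if the budget is
    exhausted without convergence.
    """
    budget = QUADRATIC_BUDGETS[spec.name] if budget is None else budget
    w = np.array([w0])
    state = init_state(spec, {"w": w})
    trace = [w0]
    for _ in range(budget):
        g = 2.0 * (w - target)
        w = w + step(spec, state, {"w": g})["w"]
        trace.append(float(w[0]))
        if abs(float(w[0]) - target) < tol:
            return np.array(trace)
    raise RuntimeError(
        f"{spec.name} failed to reach |w - {target}| < {tol} within {budget} iterations"
    )
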