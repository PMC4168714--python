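"""Structural similarity scoring from probing reactivities.

The structural term τ(s, r) compares a query column's consensus pairedness
flag s (0 = paired, 1 = unpaired) with the target position's observed
reactivity r.  Undefined reactivities contribute 0.  Two scoring functions
are provided:

* simplified — a cutoff rule: the position is called unpaired when r > r_c
  and paired when r <= r_c; agreement with s scores +1, disagreement -1.
* protocol-specific (Bayesian) — the log-ratio
  log p(r | π = s) - log p(r | π != s) under protocol-calibrated conditional
  reactivity densities, assuming equal priors on paired/unpaired.

The conditional densities are configuration data, not constants: they vary
by probing protocol and processing pipeline.  The shipped default is a
SHAPE-like pair (paired mass concentrated near 0, unpaired heavy right
tail) intended as a starting point, to be re-tuned per protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

__all__ = [
    "ReactivityDensityModel",
    "StructuralScoringConfig",
    "f_simplified",
    "f_bayesian",
    "tau",
    "default_shape_model",
]

#: Densities are clamped at this floor before taking logs, so Bayesian
#: scores saturate instead of becoming infinite.
DENSITY_FLOOR = 1e-12

#: Distribution families accepted in density configs.
_FAMILIES = {
    "exponential": lambda p: stats.expon(scale=p["scale"]),
    "gamma": lambda p: stats.gamma(p["shape"], scale=p["scale"]),
    "gev": lambda p: stats.genextreme(p["shape"], loc=p["loc"], scale=p["scale"]),
    "normal": lambda p: stats.norm(loc=p["loc"], scale=p["scale"]),
}


@dataclass(frozen=True)
class Density:
    """One named parametric density, e.g. ``Density("gamma", {"shape": 1.5, "scale": 0.6})``."""

    family: str
    params: dict

    def frozen(self):
        try:
            make = _FAMILIES[self.family]
        except KeyError:
            raise ValueError(
                f"unknown density family {self.family!r}; choose from {sorted(_FAMILIES)}"
            ) from None
        return make(self.params)

    def pdf(self, r):
        return self.frozen().pdf(r)

    def sample(self, size, rng: np.random.Generator):
        return self.frozen().rvs(size=size, random_state=rng)

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Density":
        return cls(d["family"], dict(d["params"]))


@dataclass(frozen=True)
class ReactivityDensityModel:
    """Conditional reactivity densities p(r | paired) and p(r | unpaired)."""

    density_paired: Density
    density_unpaired: Density

    def log_ratio(self, r):
        """log p(r | paired) - log p(r | unpaired), floor-clamped."""
        lp = np.log(np.maximum(self.density_paired.pdf(r), DENSITY_FLOOR))
        lu = np.log(np.maximum(self.density_unpaired.pdf(r), DENSITY_FLOOR))
        return lp - lu

    def to_dict(self) -> dict:
        return {
            "paired": self.density_paired.to_dict(),
            "unpaired": self.density_unpaired.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactivityDensityModel":
        return cls(Density.from_dict(d["paired"]), Density.from_dict(d["unpaired"]))


def default_shape_model() -> ReactivityDensityModel:
    """Default SHAPE-like density pair (repo default, tune per protocol).

    Paired positions: Exponential with mean 0.15 — reactivities concentrated
    near zero.  Unpaired positions: Gamma(shape 1.5, scale 0.6), mean 0.9 —
    a heavy right tail.  These are documented repo defaults, not values
    calibrated on annotated probing data.
    """
    return ReactivityDensityModel(
        density_paired=Density("exponential", {"scale": 0.15}),
        density_unpaired=Density("gamma", {"shape": 1.5, "scale": 0.6}),
    )


@dataclass(frozen=True)
class StructuralScoringConfig:
    """Which structural scoring function to use, and its parameters."""

    mode: Literal["simplified", "protocol_specific"] = "simplified"
    r_c: float = 0.3
    model: ReactivityDensityModel | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.r_c):
            raise ValueError("r_c must be finite")
        if self.mode == "protocol_specific" and self.model is None:
            object.__setattr__(self, "model", default_shape_model())
        if self.mode not in ("simplified", "protocol_specific"):
            raise ValueError(f"unknown scoring mode {self.mode!r}")

    def to_dict(self) -> dict:
        d = {"mode": self.mode, "r_c": self.r_c}
        if self.model is not None:
            d.update(self.model.to_dict())
        return d


def f_simplified(s: int, r: float, r_c: float) -> float:
    """Cutoff structural score: ±1.

    The target position is called unpaired when r > r_c and paired when
    r <= r_c (the boundary counts as paired); agreement with the query flag
    s scores +1, disagreement -1.
    """
    target_unpaired = r > r_c
    return 1.0 if target_unpaired == bool(s) else -1.0


def f_bayesian(s: int, r: float, model: ReactivityDensityModel) -> float:
    """Log-ratio structural score log p(r|π=s) - log p(r|π≠s), natural log.

    Equal priors on paired/unpaired are assumed, so posterior and likelihood
    ratios coincide.  Densities are clamped at a small floor so the score
    saturates rather than diverging where one density underflows.
    """
    lr = float(model.log_ratio(r))
    return -lr if s else lr


def tau(s: int, r: float | None, cfg: StructuralScoringConfig) -> float:
    """Structural similarity at one aligned (column, position) pair.

    Returns 0 when the reactivity is undefined (None or NaN); otherwise
    dispatches to the configured scoring function.
    """
    if r is None or (isinstance(r, float) and np.isnan(r)):
        return 0.0
    if cfg.mode == "simplified":
        return f_simplified(s, r, cfg.r_c)
    return f_bayesian(s, r, cfg.model)


def tau_table(
    pairedness: np.ndarray,
    values: np.ndarray,
    defined: np.ndarray,
    cfg: StructuralScoringConfig,
) -> np.ndarray:
    """Precomputed τ for every (query column, target position) pair.

    Returns an (n, m) array used by the alignment DP; undefined positions
    are 0 in every row.
    """
    n, m = len(pairedness), len(values)
    out = np.zeros((n, m))
    if not defined.any():
        return out
    r = values[defined]
    if cfg.mode == "simplified":
        unp = (r > cfg.r_c).astype(float) * 2.0 - 1.0  # +1 unpaired call, -1 paired
        row_paired = -unp  # s = 0 agrees with a paired call
        row_unpaired = unp
    else:
        lr = cfg.model.log_ratio(r)
        row_paired = lr
        row_unpaired = -lr
    for i in range(n):
        out[i, defined] = row_paired if pairedness[i] == 0 else row_unpaired
    return out
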