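"""Sample-size and power calculations for pooled case-control analyses.

Analytic sample sizes for a main genetic effect and for a multiplicative
gene-environment interaction, each on the log-odds-ratio scale, plus a
simulation-based checker that estimates empirical power for any planned
size.  Formulas are documented inline; the simulator is the arbiter when
assumptions matter.

Main effect (carrier exposure, equal cases and controls): with control
carrier prevalence p0 and target odds ratio OR, the case prevalence is
p1 = p0*OR / (1 - p0 + p0*OR) and

    n per group = (z_{1-a/2} + z_{1-power})^2 * [1/(p1 q1) + 1/(p0 q0)] / (ln OR)^2,

the classical log-OR (Woolf variance) method.

Interaction (binary gene G, binary environment E, multiplicative
interaction OR_ge): assuming G and E independent among controls, the
2x2x2 cell probabilities among controls are the products of the margins;
among cases they are tilted by the main-effect ORs and the interaction OR
and renormalized.  The Woolf-type variance of the interaction log-OR is
the sum of reciprocal expected cell counts over all eight cells, and n
follows from the same normal-approximation identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PowerSpec",
    "sample_size_main",
    "sample_size_interaction",
    "power_by_simulation",
]


@dataclass
class PowerSpec:
    """Design parameters for a power/sample-size calculation.

    ``prevalence`` is the carrier (exposure) frequency among controls.
    For interaction calculations set ``interaction_or`` and
    ``env_prevalence``; ``or_gene``/``or_env`` are the main-effect odds
    ratios in the interaction model (default 1: pure interaction).
    """

    prevalence: float
    odds_ratio: float = 1.5
    alpha: float = 0.05
    power: float = 0.90
    interaction_or: float | None = None
    env_prevalence: float | None = None
    or_gene: float = 1.0
    or_env: float = 1.0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.env_prevalence is not None and not 0 < self.env_prevalence < 1:
            raise ValueError("environment prevalence must be in (0,1)")


def _z_sum(alpha: float, power: float) -> float:
    return stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)


def sample_size_main(spec: PowerSpec) -> int:
    """Cases (= controls) needed to detect a main carrier effect.

    Log-OR method with Woolf variance; see the module docstring for the
    formula.  Raises for OR = 1 (no effect: required n is infinite).
    """
    if spec.odds_ratio == 1.0:
        raise ValueError("odds ratio 1 means no effect: required n is infinite")
    p0 = spec.prevalence
    odds1 = spec.odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    v = 1 / (p1 * (1 - p1)) + 1 / (p0 * (1 - p0))
    n = _z_sum(spec.alpha, spec.power) ** 2 * v / math.log(spec.odds_ratio) ** 2
    return math.ceil(n)


def _interaction_cells(spec: PowerSpec):
    """Expected 2x2x2 cell probabilities (controls, cases) for G x E."""
    pg, pe = spec.prevalence, spec.env_prevalence
    ctrl = np.array([
        (1 - pg) * (1 - pe),  # g=0 e=0
        (1 - pg) * pe,        # g=0 e=1
        pg * (1 - pe),        # g=1 e=0
        pg * pe,              # g=1 e=1
    ])
    tilt = np.array([
        1.0,
        spec.or_env,
        spec.or_gene,
        spec.or_gene * spec.or_env * spec.interaction_or,
    ])
    case = ctrl * tilt
    case /= case.sum()
    return ctrl, case


def sample_size_interaction(spec: PowerSpec) -> int:
    """Cases (= controls) needed to detect a multiplicative G x E interaction.

    Uses the Woolf-type variance of the interaction log-OR (sum of
    reciprocal expected counts over the eight gene x environment x status
    cells); validated against :func:`power_by_simulation`.
    """
    if spec.interaction_or is None or spec.env_prevalence is None:
        raise ValueError("interaction_or and env_prevalence must be set")
    if spec.interaction_or == 1.0:
        raise ValueError("interaction OR 1 means no effect: required n is infinite")
    ctrl, case = _interaction_cells(spec)
    v = float((1 / ctrl).sum() + (1 / case).sum())
    n = _z_sum(spec.alpha, spec.power) ** 2 * v / math.log(spec.interaction_or) ** 2
    return math.ceil(n)


def power_by_simulation(spec: PowerSpec, n_per_group: int,
                        replicates: int = 1000, seed: int = 0) -> dict:
    """Empirical power of the planned design by Monte Carlo.

    Simulates case-control samples of ``n_per_group`` under the spec's
    generative model, computes the Wald test of the target log-OR (main
    effect, or the product-term coefficient of the saturated G x E model,
    which equals the cell-count cross-ratio contrast), with a 0.5
    continuity correction on zero cells, and counts two-sided p < alpha.

    Returns ``{"power", "ci_low", "ci_high", "replicates"}`` with a 95%
    binomial (Wilson) interval.
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1 - spec.alpha / 2)
    n = int(n_per_group)

    if spec.interaction_or is None:
        p0 = spec.prevalence
        odds1 = spec.odds_ratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        a = rng.binomial(n, p1, size=replicates).astype(float)  # exposed cases
        b = rng.binomial(n, p0, size=replicates).astype(float)  # exposed controls
        c, d = n - a, n - b
        cells = np.stack([a, b, c, d])
        zero = (cells == 0).any(axis=0)
        cells = cells + 0.5 * zero
        a, b, c, d = cells
        lor = np.log(a * d / (b * c))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    else:
        ctrl_p, case_p = _interaction_cells(spec)
        case = rng.multinomial(n, case_p, size=replicates).astype(float)
        ctrl = rng.multinomial(n, ctrl_p, size=replicates).astype(float)
        counts = np.concatenate([case, ctrl], axis=1)  # 8 cells per replicate
        zero = (counts == 0).any(axis=1, keepdims=True)
        counts = counts + 0.5 * zero
        case, ctrl = counts[:, :4], counts[:, 4:]
        lor = (np.log(case[:, 3] * case[:, 0] / (case[:, 1] * case[:, 2]))
               - np.log(ctrl[:, 3] * ctrl[:, 0] / (ctrl[:, 1] * ctrl[:, 2])))
        se = np.sqrt((1 / counts).sum(axis=1))

    reject = np.abs(lor / se) > z_crit
    p_hat = float(reject.mean())
    lo, hi = _wilson_ci(reject.sum(), replicates)
    return {"power": p_hat, "ci_low": lo, "ci_high": hi,
            "replicates": replicates}


def _wilson_ci(successes: int, trials: int, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2)) / denom
    return center - half, center + half
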