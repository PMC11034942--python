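"""Climate-effect sizes: log response ratios and the factorial interaction d_I.

Two effect measures are computed on per-replicate absolute growth rates:

* ``lnRR = ln(X_t / X_c)`` — the log response ratio of a climate treatment
  against the ambient control, one per single-factor and combined treatment.
* Hedges' ``d_I`` — the small-sample-corrected standardized interaction
  contrast of a 2x2 factorial (control c, single factors A and B, combined
  AB):

      d_I = [(X_AB - X_A) - (X_B - X_c)] / (2 s) * J(m)

  with ``s`` the four-group pooled standard deviation and
  ``J(m) = 1 - 3 / (4 (n_c + n_A + n_B + n_AB - 4) - 1)``.

Uncertainty for both is a percentile bootstrap over replicates within each
group; an effect is significant when its CI excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design import RunConfig


class EffectDomainError(ValueError):
    """Inputs outside the domain of an effect-size formula."""


@dataclass(frozen=True)
class GroupStats:
    """One factorial cell: per-replicate values plus summary moments."""

    label: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if self.n < 2:
            raise EffectDomainError(f"group {self.label!r} needs n >= 2 for sd")
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class EffectSizeRecord:
    """Point estimate with bootstrap CI for one taxon x comparison."""

    label: str
    measure: str            # "lnRR" or "hedges_dI"
    comparison: str
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


def ln_response_ratio(x_t: float, x_c: float) -> float:
    """lnRR = ln(x_t / x_c); both rates must be positive."""
    if x_t <= 0 or x_c <= 0:
        raise EffectDomainError(
            f"lnRR requires positive rates, got x_t={x_t}, x_c={x_c}"
        )
    return math.log(x_t / x_c)


def small_sample_correction(n_c: int, n_a: int, n_b: int, n_ab: int) -> float:
    """Hedges' small-sample bias correction J(m)."""
    m = n_c + n_a + n_b + n_ab - 4
    denom = 4 * m - 1
    if denom <= 0:
        raise EffectDomainError("total sample size too small for J(m)")
    return 1.0 - 3.0 / denom


def pooled_sd(groups: tuple[GroupStats, GroupStats, GroupStats, GroupStats]) -> float:
    """Four-group pooled standard deviation."""
    num = sum((g.n - 1) * g.sd**2 for g in groups)
    den = sum(g.n for g in groups) - 4
    if den <= 0:
        raise EffectDomainError("pooled sd undefined: no residual degrees of freedom")
    return math.sqrt(num / den)


def hedges_d_interaction(
    groups: tuple[GroupStats, GroupStats, GroupStats, GroupStats],
) -> float:
    """Point estimate of the interaction effect size d_I.

    ``groups`` are (control, factor A, factor B, combined AB).
    """
    c, a, b, ab = groups
    s = pooled_sd(groups)
    if s == 0:
        raise EffectDomainError("pooled sd is zero; d_I undefined for degenerate groups")
    j = small_sample_correction(c.n, a.n, b.n, ab.n)
    return ((ab.mean - a.mean) - (b.mean - c.mean)) / (2.0 * s) * j


_MAX_REJECT_INFLATION = 10


def _percentile_ci(draws: np.ndarray, ci_level: float) -> tuple[float, float]:
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(draws, (100 * alpha / 2, 100 * (1 - alpha / 2)))
    return float(lo), float(hi)


def bootstrap_lnrr(
    treatment_values,
    control_values,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    label: str = "",
    comparison: str = "",
) -> EffectSizeRecord:
    """lnRR of group means with a percentile bootstrap CI.

    Each bootstrap draw resamples both groups with replacement and takes the
    lnRR of the resampled means. Draws with a non-positive mean are rejected
    and redrawn (up to a 10x inflation of the draw budget).
    """
    xt = np.asarray(treatment_values, dtype=float)
    xc = np.asarray(control_values, dtype=float)
    if xt.size < 2 or xc.size < 2:
        raise EffectDomainError("bootstrap_lnrr needs >= 2 values per group")
    est = ln_response_ratio(float(xt.mean()), float(xc.mean()))
    if rng is None:
        rng = config.rng(20)
    B = config.n_bootstrap
    draws = np.empty(0)
    budget = B * _MAX_REJECT_INFLATION
    while draws.size < B and budget > 0:
        want = min(B - draws.size, budget)
        mt = xt[rng.integers(0, xt.size, size=(want, xt.size))].mean(axis=1)
        mc = xc[rng.integers(0, xc.size, size=(want, xc.size))].mean(axis=1)
        ok = (mt > 0) & (mc > 0)
        draws = np.concatenate([draws, np.log(mt[ok] / mc[ok])])
        budget -= want
    if draws.size < B:
        raise EffectDomainError(
            "bootstrap_lnrr: too many draws with non-positive resampled means"
        )
    lo, hi = _percentile_ci(draws[:B], config.ci_level)
    return EffectSizeRecord(label, "lnRR", comparison, est, lo, hi)


def bootstrap_dI(
    groups: tuple[GroupStats, GroupStats, GroupStats, GroupStats],
    config: RunConfig,
    rng: np.random.Generator | None = None,
    label: str = "",
    comparison: str = "",
) -> EffectSizeRecord:
    """Hedges' d_I with a percentile bootstrap CI over within-group resamples."""
    for g in groups:
        if g.n < 2:
            raise EffectDomainError(f"group {g.label!r} needs n >= 2")
    est = hedges_d_interaction(groups)
    if rng is None:
        rng = config.rng(21)
    B = config.n_bootstrap
    j = small_sample_correction(*(g.n for g in groups))
    arrs = [np.asarray(g.values, dtype=float) for g in groups]
    draws = np.empty(0)
    budget = B * _MAX_REJECT_INFLATION
    while draws.size < B and budget > 0:
        want = min(B - draws.size, budget)
        means = []
        vars_ = []
        dof = 0
        for arr in arrs:
            res = arr[rng.integers(0, arr.size, size=(want, arr.size))]
            means.append(res.mean(axis=1))
            vars_.append(res.var(axis=1, ddof=1) * (arr.size - 1))
            dof += arr.size - 1
        s = np.sqrt(sum(vars_) / dof)
        contrast = (means[3] - means[1]) - (means[2] - means[0])
        ok = s > 0
        draws = np.concatenate([draws, contrast[ok] / (2.0 * s[ok]) * j])
        budget -= want
    if draws.size < B:
        raise EffectDomainError("bootstrap_dI: degenerate (zero-variance) resamples")
    lo, hi = _percentile_ci(draws[:B], config.ci_level)
    return EffectSizeRecord(label, "hedges_dI", comparison, est, lo, hi)
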