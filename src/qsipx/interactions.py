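"""Classification of warming x precipitation interactions per taxon.

A taxon's combined response to two climate factors is typed against the
additive null (combined response = sum of the single-factor responses, i.e.
``X_AB = X_A + X_B - X_c`` on the rate scale), which the interaction effect
size d_I tests directly:

* **additive** — the d_I CI contains 0.
* **synergistic** — the combined effect overshoots the additive expectation
  in the direction the single effects point (d_I CI above 0 with both single
  effects positive, or below 0 with both negative / opposite signs).
* **antagonistic** — the combined effect falls short of the additive
  expectation; sub-typed on the lnRR magnitude scale as

  - **neutralizing** — the combined effect is indistinguishable from zero
    while at least one single effect is not;
  - **strong antagonistic** — combined effect nonzero but smaller in
    magnitude than both single effects;
  - **weak antagonistic** — combined magnitude at least the smaller single
    effect but below the summed (additive-expectation) magnitude.

Intensity scores place the five types on an antagonism scale:
synergistic -1, additive 0, weak antagonistic 1, strong antagonistic 2,
neutralizing 3.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .effects import EffectSizeRecord

INTERACTION_TYPES = (
    "synergistic",
    "additive",
    "weak_antagonistic",
    "strong_antagonistic",
    "neutralizing",
)

INTENSITY = {
    "synergistic": -1,
    "additive": 0,
    "weak_antagonistic": 1,
    "strong_antagonistic": 2,
    "neutralizing": 3,
}


def intensity_score(interaction_type: str) -> int:
    """Antagonism intensity of an interaction type on the -1..3 scale."""
    try:
        return INTENSITY[interaction_type]
    except KeyError:
        raise ValueError(f"unknown interaction type {interaction_type!r}") from None


@dataclass(frozen=True)
class InteractionCall:
    """One taxon x scenario classification with its evidence snapshot."""

    taxon: str
    scenario: str
    interaction_type: str
    audit_flag: bool = False
    effect_a: float = float("nan")
    effect_a_significant: bool = False
    effect_b: float = float("nan")
    effect_b_significant: bool = False
    effect_ab: float = float("nan")
    effect_ab_significant: bool = False
    d_i: float = float("nan")
    d_i_ci_low: float = float("nan")
    d_i_ci_high: float = float("nan")

    @property
    def intensity(self) -> int:
        return intensity_score(self.interaction_type)


def classify_interaction(
    effect_a: EffectSizeRecord,
    effect_b: EffectSizeRecord,
    effect_ab: EffectSizeRecord,
    d_i: EffectSizeRecord,
    taxon: str = "",
    scenario: str = "",
) -> InteractionCall:
    """Type one taxon x scenario from its single/combined lnRRs and d_I.

    The decision tree is applied in order: additive if the d_I CI contains
    zero; synergistic if d_I excludes zero on the side the single effects
    point; otherwise antagonistic, sub-typed neutralizing before strong
    before weak. An antagonistic call matching no sub-category (e.g. a
    significant combined effect at or beyond the additive-expectation
    magnitude) is returned as strong_antagonistic with ``audit_flag`` set
    rather than silently re-binned.
    """
    labels = {effect_a.label, effect_b.label, effect_ab.label, d_i.label}
    labels.discard("")
    if len(labels) > 1:
        raise ValueError(f"effect records refer to different taxa: {labels}")

    a, b, ab = effect_a.estimate, effect_b.estimate, effect_ab.estimate
    snapshot = dict(
        effect_a=a,
        effect_a_significant=effect_a.significant,
        effect_b=b,
        effect_b_significant=effect_b.significant,
        effect_ab=ab,
        effect_ab_significant=effect_ab.significant,
        d_i=d_i.estimate,
        d_i_ci_low=d_i.ci_low,
        d_i_ci_high=d_i.ci_high,
    )

    def call(kind: str, flag: bool = False) -> InteractionCall:
        return InteractionCall(taxon, scenario, kind, flag, **snapshot)

    if d_i.ci_low <= 0.0 <= d_i.ci_high:
        return call("additive")

    both_pos = a > 0 and b > 0
    both_neg = a < 0 and b < 0
    opposite = a * b < 0
    if (d_i.ci_high < 0 and (both_neg or opposite)) or (
        d_i.ci_low > 0 and both_pos
    ):
        return call("synergistic")

    # antagonistic branch: magnitudes compared on the |lnRR| scale
    min_single = min(abs(a), abs(b))
    additive_expectation = abs(a + b)
    if not effect_ab.significant and (
        effect_a.significant or effect_b.significant
    ):
        return call("neutralizing")
    if abs(ab) < min_single and effect_ab.significant:
        return call("strong_antagonistic")
    if min_single <= abs(ab) < additive_expectation:
        return call("weak_antagonistic")
    return call("strong_antagonistic", flag=True)


def community_antagonism(calls) -> float:
    """Proportion-weighted mean intensity over a scenario's calls; in [-1, 3]."""
    calls = list(calls)
    if not calls:
        raise ValueError("community_antagonism requires at least one call")
    counts = Counter(c.interaction_type for c in calls)
    total = sum(counts.values())
    return sum(INTENSITY[t] * n / total for t, n in counts.items())


def type_proportions(calls) -> dict[str, float]:
    calls = list(calls)
    counts = Counter(c.interaction_type for c in calls)
    total = sum(counts.values()) or 1
    return {t: counts.get(t, 0) / total for t in INTERACTION_TYPES}


def summarize_response_directions(
    control_dndt: dict[str, float], treatment_dndt: dict[str, float]
) -> dict[str, float]:
    """Proportions of positive/negative growth responders under a treatment.

    A taxon responds negatively when its point dN/dt under the treatment is
    below its control value; ties count as positive (documented tie-break).
    Only taxa present in both mappings are compared.
    """
    shared = sorted(set(control_dndt) & set(treatment_dndt))
    if not shared:
        return {"n": 0, "positive": float("nan"), "negative": float("nan")}
    neg = sum(1 for tx in shared if treatment_dndt[tx] < control_dndt[tx])
    n = len(shared)
    return {"n": n, "positive": (n - neg) / n, "negative": neg / n}


@dataclass
class ScenarioComparison:
    """Taxon-by-taxon contrast of interaction calls in two climate scenarios."""

    shared_taxa: list[str]
    intensity_shift: dict[str, int]
    n_higher_in_second: int
    crosstab: pd.DataFrame

    @property
    def n_shared(self) -> int:
        return len(self.shared_taxa)


def compare_scenarios(calls_first, calls_second) -> ScenarioComparison:
    """Compare per-taxon calls between two scenarios (e.g. WxD vs WxW).

    Returns the shared-incorporator set, each taxon's intensity shift
    (second minus first), the count whose antagonism ranks higher in the
    second scenario, and the full (type_first, type_second) cross-tabulation.
    """
    by_tax_1 = {c.taxon: c for c in calls_first}
    by_tax_2 = {c.taxon: c for c in calls_second}
    shared = sorted(set(by_tax_1) & set(by_tax_2))
    shift = {
        tx: by_tax_2[tx].intensity - by_tax_1[tx].intensity for tx in shared
    }
    n_higher = sum(1 for v in shift.values() if v > 0)
    crosstab = pd.DataFrame(
        0, index=list(INTERACTION_TYPES), columns=list(INTERACTION_TYPES)
    )
    for tx in shared:
        crosstab.loc[
            by_tax_1[tx].interaction_type, by_tax_2[tx].interaction_type
        ] += 1
    return ScenarioComparison(shared, shift, n_higher, crosstab)


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "taxon": c.taxon,
                "scenario": c.scenario,
                "type": c.interaction_type,
                "intensity": c.intensity,
                "audit_flag": c.audit_flag,
                "effect_a": c.effect_a,
                "effect_a_significant": c.effect_a_significant,
                "effect_b": c.effect_b,
                "effect_b_significant": c.effect_b_significant,
                "effect_ab": c.effect_ab,
                "effect_ab_significant": c.effect_ab_significant,
                "d_i": c.d_i,
                "d_i_ci_low": c.d_i_ci_low,
                "d_i_ci_high": c.d_i_ci_high,
            }
        )
    return pd.DataFrame(rows)
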