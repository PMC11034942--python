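"""Forward simulator of a density-gradient 18O-qSIP experiment.

Generates fraction tables (and a matching random phylogeny) with known
ground truth so every downstream stage — growth estimation, effect sizes,
interaction typing, NTI — can be validated by parameter recovery.

The measurement model per ultracentrifuge tube:

1. a 20-fraction density grid spanning the gradient, shifted by a
   tube-specific calibration offset;
2. each taxon's 16S copy mass is a Gaussian in density centred on its
   effective weighted-average density — the GC-predicted unlabeled density,
   shifted upward in the 18O tube according to its true excess atom
   fraction — integrated over the fraction bins (tail mass collects in the
   edge fractions, so copy mass is conserved);
3. qPCR totals per fraction are the summed expected copies times lognormal
   noise;
4. per-fraction relative abundances are multinomial sequencing draws.

Interaction types are *designed*: each active taxon receives single-factor
and combined rate multipliers constructed so that the taxon realises its
assigned type under the classifier's own rules (additive on the raw-rate
scale — the additive expectation X_AB = X_A + X_B - X_c — with antagonism
sub-types separated on the lnRR magnitude scale). Synergistic taxa are
given growth-enhancing single effects, because with suppressive single
effects the additive expectation is already near zero and an overshoot
beyond it is neither biologically plausible nor statistically detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .design import Design, SCENARIOS, CONTROL_TREATMENT
from .io import FractionTable, META_COLUMNS
from .qsip import QsipConstants, DEFAULT_CONSTANTS

INTERACTION_TYPE_NAMES = (
    "additive",
    "synergistic",
    "weak_antagonistic",
    "strong_antagonistic",
    "neutralizing",
)

#: default designed-type mix, qualitatively mirroring a community dominated
#: by antagonistic warming x precipitation interactions
DEFAULT_SCENARIO_SPEC = {
    "additive": 0.15,
    "synergistic": 0.05,
    "weak_antagonistic": 0.35,
    "strong_antagonistic": 0.15,
    "neutralizing": 0.30,
}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimNoise:
    """Magnitudes of the simulated measurement processes.

    tube_density_sd
        Tube-to-tube gradient calibration offset, g ml^-1.
    within_taxon_density_sd
        Spread of one taxon's DNA across the gradient, g ml^-1. This is
        physical dispersion, not measurement error: it is what distributes a
        taxon over several fractions and is kept nonzero even in "noise-free"
        runs (collapsing it makes the WAD degenerate to a bin centre).
    qpcr_cv
        Coefficient of variation of lognormal noise on per-fraction totals.
    reads_per_fraction
        Multinomial sequencing depth per fraction.
    replicate_growth_cv
        Lognormal biological variation of true rates across replicate tubes.
    """

    tube_density_sd: float = 0.002
    within_taxon_density_sd: float = 0.006
    qpcr_cv: float = 0.1
    reads_per_fraction: int = 10_000
    replicate_growth_cv: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "tube_density_sd",
            "within_taxon_density_sd",
            "qpcr_cv",
            "replicate_growth_cv",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        if self.reads_per_fraction < 1:
            raise SimConfigError("reads_per_fraction must be >= 1")

    @classmethod
    def zero(cls, reads_per_fraction: int = 1_000_000) -> "SimNoise":
        """All measurement noise off; physical density spread retained."""
        return cls(
            tube_density_sd=0.0,
            qpcr_cv=0.0,
            reads_per_fraction=reads_per_fraction,
            replicate_growth_cv=0.0,
        )


#: density grid of the simulated gradient (20 equal-width fractions)
GRID_RANGE = (1.66, 1.78)
N_FRACTIONS = 20


@dataclass
class TrueParams:
    """Ground truth of a simulated community.

    ``per_treatment`` has one row per (taxon, treatment) with the realised
    true fraction of new DNA, EAF, per-capita rate g and absolute rate
    dN/dt; ``designed_types`` one row per (taxon, scenario) with the
    designed interaction label (NaN rows for inactive taxa).
    """

    taxa: list[str]
    gc: np.ndarray
    baseline_abundance: np.ndarray
    n_total: np.ndarray
    per_treatment: pd.DataFrame
    designed_types: pd.DataFrame
    active: np.ndarray = field(default=None)

    def true_values(self, treatment: str, column: str) -> dict[str, float]:
        sub = self.per_treatment[self.per_treatment["treatment"] == treatment]
        return dict(zip(sub["taxon"], sub[column]))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _allocate_types(n: int, spec: dict[str, float], rng: np.random.Generator):
    """Deterministic largest-remainder allocation of type labels, shuffled."""
    names = list(spec)
    props = np.array([spec[k] for k in names], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise SimConfigError(
            f"scenario_spec proportions sum to {props.sum()}, expected 1"
        )
    raw = props * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() >= n:
            break
        counts[i] += 1
    labels = np.repeat(names, counts)
    return labels[rng.permutation(n)]


def _suppressive_multiplier(rng, size=None):
    return rng.uniform(0.55, 0.60, size=size)


def _enhancing_multiplier(rng, size=None):
    return rng.uniform(1.40, 1.60, size=size)


def _combined_multiplier(kind: str, m_a: float, m_b: float, rng) -> float:
    """Combined-treatment rate multiplier realising a designed type."""
    x_add = m_a + m_b - 1.0  # raw-scale additive expectation (control = 1)
    if kind == "additive":
        return x_add
    if kind == "synergistic":
        # overshoot beyond the additive expectation, same direction as singles
        return 1.35 * x_add
    lnrr_a, lnrr_b = abs(np.log(m_a)), abs(np.log(m_b))
    min_single = min(lnrr_a, lnrr_b)
    if kind == "weak_antagonistic":
        target = 0.5 * (min_single + (lnrr_a + lnrr_b))
        return float(np.exp(-target))
    if kind == "strong_antagonistic":
        return float(np.exp(-0.75 * min_single))
    if kind == "neutralizing":
        return 1.0
    raise SimConfigError(f"unknown interaction type {kind!r}")


MAX_NEW_FRACTION = 0.9  # cap on the fraction of DNA synthesised in t days


def simulate_community(
    n_taxa: int,
    design: Design,
    scenario_spec: dict[str, float] | None = None,
    seed=0,
    inactive_fraction: float = 0.0,
    community_total_copies: float = 1e9,
    control_growth_median: float = 0.15,
    control_growth_sigma: float = 0.25,
    constants: QsipConstants = DEFAULT_CONSTANTS,
) -> TrueParams:
    """Draw a ground-truth community with designed interaction types.

    GC contents are uniform on [0.3, 0.7]; baseline relative abundances are
    Dirichlet(1); control per-capita growth rates are lognormal with the
    given median (day^-1). ``inactive_fraction`` of taxa receive zero EAF in
    every treatment (non-growers, for false-positive calibration); the
    ``scenario_spec`` type proportions are realised exactly (largest
    remainder) among the active taxa, independently per scenario except that
    synergistic taxa keep the label in both scenarios, because their
    growth-enhancing warming response is a single shared treatment.
    """
    if n_taxa < 1:
        raise SimConfigError("n_taxa must be >= 1")
    if not (0.0 <= inactive_fraction < 1.0):
        raise SimConfigError("inactive_fraction must be in [0, 1)")
    spec = dict(scenario_spec or DEFAULT_SCENARIO_SPEC)
    rng = _as_rng(seed)

    taxa = [f"taxon_{i + 1:04d}" for i in range(n_taxa)]
    gc = rng.uniform(0.3, 0.7, size=n_taxa)
    abundance = rng.dirichlet(np.ones(n_taxa))
    n_total = abundance * community_total_copies
    g_control = control_growth_median * np.exp(
        rng.normal(0.0, control_growth_sigma, size=n_taxa)
    )

    n_inactive = int(round(inactive_fraction * n_taxa))
    active = np.ones(n_taxa, dtype=bool)
    if n_inactive:
        active[rng.permutation(n_taxa)[:n_inactive]] = False
    n_active = int(active.sum())

    scenario_names = list(SCENARIOS)
    types = {
        sc: np.full(n_taxa, None, dtype=object) for sc in scenario_names
    }
    if n_active:
        primary = _allocate_types(n_active, spec, rng)
        types[scenario_names[0]][active] = primary
        secondary = _allocate_types(n_active, spec, rng)
        # synergists keep their label across scenarios (shared warming regime)
        syn = primary == "synergistic"
        secondary[syn] = "synergistic"
        non_syn_slots = secondary == "synergistic"
        non_syn_slots &= ~syn
        if non_syn_slots.any():
            pool = [t for t in INTERACTION_TYPE_NAMES if t != "synergistic"]
            secondary[non_syn_slots] = rng.choice(pool, size=non_syn_slots.sum())
        types[scenario_names[1]][active] = secondary

    active_idx = np.where(active)[0]
    enhancing = np.zeros(n_taxa, dtype=bool)
    enhancing[active_idx] = types[scenario_names[0]][active_idx] == "synergistic"

    # rate multipliers relative to the control treatment (dN/dt scale)
    m_warm = np.ones(n_taxa)
    m_warm[active & ~enhancing] = _suppressive_multiplier(
        rng, size=int((active & ~enhancing).sum())
    )
    m_warm[enhancing] = _enhancing_multiplier(rng, size=int(enhancing.sum()))

    mult = {CONTROL_TREATMENT: np.ones(n_taxa)}
    warm_single = SCENARIOS[scenario_names[0]][0]
    mult[warm_single] = m_warm
    for sc in scenario_names:
        _, precip_tr, combined_tr = SCENARIOS[sc]
        m_p = np.ones(n_taxa)
        m_c = np.ones(n_taxa)
        for i in active_idx:
            kind = types[sc][i]
            if enhancing[i]:
                m_p[i] = float(_enhancing_multiplier(rng))
            else:
                m_p[i] = float(_suppressive_multiplier(rng))
            m_c[i] = _combined_multiplier(kind, m_warm[i], m_p[i], rng)
        mult.setdefault(precip_tr, np.ones(n_taxa))
        mult[precip_tr] = m_p
        mult[combined_tr] = m_c

    t = design.incubation_days
    frac_control = 1.0 - np.exp(-g_control * t)
    max_eaf = min(constants.max_eaf, design.labeled_water_atom_pct)

    rows = []
    for tr in design.treatments:
        m = mult.get(tr, np.ones(n_taxa))
        frac_new = np.clip(frac_control * m, 0.0, MAX_NEW_FRACTION)
        frac_new = np.where(active, frac_new, 0.0)
        eaf = frac_new * (1.0 - constants.p_nat_18o)
        eaf = np.minimum(eaf, max_eaf)
        g = -np.log(1.0 - frac_new) / t
        dndt = n_total * frac_new / t
        for i, tx in enumerate(taxa):
            rows.append(
                {
                    "taxon": tx,
                    "treatment": tr,
                    "rate_multiplier": float(m[i]),
                    "true_new_fraction": float(frac_new[i]),
                    "true_eaf": float(eaf[i]),
                    "true_g": float(g[i]),
                    "true_dndt": float(dndt[i]),
                    "n_total": float(n_total[i]),
                    "active": bool(active[i]),
                }
            )
    per_treatment = pd.DataFrame(rows)

    type_rows = []
    for sc in scenario_names:
        for i, tx in enumerate(taxa):
            type_rows.append(
                {
                    "taxon": tx,
                    "scenario": sc,
                    "designed_type": types[sc][i] if active[i] else None,
                }
            )
    designed_types = pd.DataFrame(type_rows)

    return TrueParams(
        taxa=taxa,
        gc=gc,
        baseline_abundance=abundance,
        n_total=n_total,
        per_treatment=per_treatment,
        designed_types=designed_types,
        active=active,
    )


def density_bin_weights(
    center: float, sd: float, edges: np.ndarray
) -> np.ndarray:
    """Mass of a Normal(center, sd) in each density bin; tails to edge bins.

    With sd = 0 all mass lands in the bin containing ``center``.
    """
    from scipy.stats import norm

    if sd <= 0:
        w = np.zeros(len(edges) - 1)
        idx = np.clip(np.searchsorted(edges, center, side="right") - 1, 0, len(w) - 1)
        w[idx] = 1.0
        return w
    cdf = norm.cdf(edges, loc=center, scale=sd)
    w = np.diff(cdf)
    w[0] += cdf[0]
    w[-1] += 1.0 - cdf[-1]
    return w


def effective_wad(
    gc: np.ndarray, eaf: np.ndarray, constants: QsipConstants = DEFAULT_CONSTANTS
) -> np.ndarray:
    """Labeled weighted-average density implied by GC content and true EAF."""
    w_light = constants.density_from_gc(gc)
    m_light = constants.mw_gc_slope * np.asarray(gc) + constants.mw_intercept
    frac = np.asarray(eaf) / (1.0 - constants.p_nat_18o)
    return w_light * (1.0 + frac * constants.delta_mw_18o_max / m_light)


def simulate_fraction_tables(
    true_params: TrueParams,
    design: Design,
    noise: SimNoise | None = None,
    seed=0,
    constants: QsipConstants = DEFAULT_CONSTANTS,
) -> tuple[FractionTable, pd.DataFrame]:
    """Simulate every tube of the design; returns (table, per-tube truth).

    The per-tube truth frame records each tube's realised (replicate-level)
    true EAF per taxon, for closed-loop validation.
    """
    noise = noise or SimNoise()
    rng = _as_rng(seed)
    taxa = true_params.taxa
    n_taxa = len(taxa)
    base_edges = np.linspace(*GRID_RANGE, N_FRACTIONS + 1)
    t = design.incubation_days

    eaf_by_treatment = {
        tr: np.array(
            [true_params.true_values(tr, "true_eaf")[tx] for tx in taxa]
        )
        for tr in design.treatments
    }
    frac_by_treatment = {
        tr: np.array(
            [true_params.true_values(tr, "true_new_fraction")[tx] for tx in taxa]
        )
        for tr in design.treatments
    }

    rows = []
    truth_rows = []
    for tr in design.treatments:
        for iso in design.isotopes:
            for rep in range(1, design.n_replicates + 1):
                tube_id = f"{tr}_{iso}_r{rep}"
                offset = (
                    rng.normal(0.0, noise.tube_density_sd)
                    if noise.tube_density_sd > 0
                    else 0.0
                )
                edges = base_edges + offset
                centers = 0.5 * (edges[:-1] + edges[1:])

                if iso == "18O":
                    frac_new = frac_by_treatment[tr].copy()
                    if noise.replicate_growth_cv > 0:
                        sigma = np.sqrt(
                            np.log1p(noise.replicate_growth_cv**2)
                        )
                        mult = np.exp(
                            rng.normal(-sigma**2 / 2, sigma, size=n_taxa)
                        )
                        frac_new = np.clip(frac_new * mult, 0.0, MAX_NEW_FRACTION)
                    eaf_tube = frac_new * (1.0 - constants.p_nat_18o)
                else:
                    eaf_tube = np.zeros(n_taxa)

                wads = effective_wad(true_params.gc, eaf_tube, constants)
                expected = np.zeros((N_FRACTIONS, n_taxa))
                for i in range(n_taxa):
                    expected[:, i] = true_params.n_total[i] * density_bin_weights(
                        float(wads[i]), noise.within_taxon_density_sd, edges
                    )
                frac_totals = expected.sum(axis=1)
                if noise.qpcr_cv > 0:
                    sigma = np.sqrt(np.log1p(noise.qpcr_cv**2))
                    frac_totals = frac_totals * np.exp(
                        rng.normal(-sigma**2 / 2, sigma, size=N_FRACTIONS)
                    )

                abund = np.zeros_like(expected)
                for f in range(N_FRACTIONS):
                    tot = expected[f].sum()
                    if tot <= 0:
                        continue
                    counts = rng.multinomial(
                        noise.reads_per_fraction, expected[f] / tot
                    )
                    abund[f] = counts / noise.reads_per_fraction

                for f in range(N_FRACTIONS):
                    row = {
                        "tube_id": tube_id,
                        "treatment": tr,
                        "isotope": iso,
                        "replicate": rep,
                        "fraction": f + 1,
                        "density": centers[f],
                        "total_copies": frac_totals[f],
                    }
                    row.update(dict(zip(taxa, abund[f])))
                    rows.append(row)
                for i, tx in enumerate(taxa):
                    truth_rows.append(
                        {
                            "tube_id": tube_id,
                            "treatment": tr,
                            "isotope": iso,
                            "replicate": rep,
                            "taxon": tx,
                            "true_eaf_tube": float(eaf_tube[i]),
                            "true_wad_tube": float(wads[i]),
                        }
                    )

    table = FractionTable(pd.DataFrame(rows, columns=list(META_COLUMNS) + taxa))
    return table, pd.DataFrame(truth_rows)


def simulate_tree(taxon_ids, seed=0) -> dendropy.Tree:
    """Random rooted binary tree by sequential random attachment.

    Branch lengths are Exponential(mean 1); tips carry ``taxon_ids``.
    """
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise SimConfigError("simulate_tree requires at least 2 taxa")
    rng = _as_rng(seed)

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def new_leaf(label):
        node = dendropy.Node()
        node.taxon = ns.new_taxon(label)
        node.edge.length = float(rng.exponential(1.0))
        return node

    first, second = new_leaf(taxon_ids[0]), new_leaf(taxon_ids[1])
    tree.seed_node.add_child(first)
    tree.seed_node.add_child(second)

    for label in taxon_ids[2:]:
        attachable = [
            n for n in tree.preorder_node_iter() if n is not tree.seed_node
        ]
        target = attachable[int(rng.integers(len(attachable)))]
        parent = target.parent_node
        split = dendropy.Node()
        split.edge.length = float(rng.uniform(0.0, target.edge.length))
        remaining = target.edge.length - split.edge.length
        parent.remove_child(target)
        parent.add_child(split)
        target.edge.length = remaining
        split.add_child(target)
        split.add_child(new_leaf(label))

    return tree
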