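"""The qSIP estimation chain: buoyant-density shifts to growth rates.

Growth is read off the density shift of a taxon's DNA between parallel
incubations with natural-abundance water and 98 atom% heavy (H2-18O) water:
DNA replicated during the incubation incorporates 18O from water and bands at
higher buoyant density. Per taxon the chain is

    copies per fraction  = relative abundance x qPCR total copies
    WAD                  = copy-weighted mean buoyant density across fractions
    GC                   = linear map from the unlabeled (16O) WAD
    M_light              = molecular weight of unlabeled DNA, from GC
    M_heavy              = M_light + maximum 18O mass gain (full labeling)
    M_lab                = M_light x (WAD_18O / WAD_16O)
    EAF                  = (M_lab - M_light) / (M_heavy - M_light) x (1 - p_nat)
    N_light              = N_total x (M_heavy - M_lab) / (M_heavy - M_light)
    g                    = ln(N_total / N_light) / t            [per day]
    dN/dt                = N_total (1 - e^(-g t)) / t           [copies/g soil/day]

Point estimates use the replicate-mean WADs; uncertainty comes from a
percentile bootstrap that resamples replicate tubes with replacement,
independently within the 16O and 18O sets. A taxon is an "incorporator" when
the lower bootstrap confidence bound of its growth rate is above zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Design, RunConfig
from .io import FractionTable, META_COLUMNS

logger = logging.getLogger(__name__)


class QsipDomainError(ValueError):
    """Inputs outside the domain of a qSIP equation."""


@dataclass(frozen=True)
class QsipConstants:
    """Constants of the GC/molecular-weight/labeling relations.

    Adopted from the qSIP methodology literature; overridable as a single
    object so an alternative calibration can be swapped in end to end.

    gc_slope_inv
        d(GC)/d(density), GC units per g ml^-1 (reciprocal of 0.083506).
    gc_intercept
        Buoyant density of GC=0 DNA, g ml^-1.
    mw_gc_slope, mw_intercept
        Linear map GC -> mean nucleotide molecular weight, g mol^-1.
    delta_mw_18o_max
        Mass gain of a fully 18O-labeled nucleotide, g mol^-1.
    p_nat_18o
        Natural-abundance atom fraction of 18O.
    """

    gc_slope_inv: float = 1.0 / 0.083506
    gc_intercept: float = 1.646057
    mw_gc_slope: float = 0.496
    mw_intercept: float = 307.691
    delta_mw_18o_max: float = 12.07747
    p_nat_18o: float = 0.002000429

    def density_from_gc(self, gc):
        """Inverse of :func:`gc_from_wad`: unlabeled WAD for a GC content."""
        return self.gc_intercept + np.asarray(gc) / self.gc_slope_inv

    @property
    def max_eaf(self) -> float:
        return 1.0 - self.p_nat_18o


DEFAULT_CONSTANTS = QsipConstants()


# ---------------------------------------------------------------------------
# elementary operations (array-aware; scalar domain errors raised eagerly)
# ---------------------------------------------------------------------------

def filter_window(table: FractionTable, window: tuple[float, float]) -> FractionTable:
    """Retain fractions whose density lies in the closed ``window``.

    Raises :class:`QsipDomainError` naming any tube left with zero fractions.
    """
    lo, hi = window
    dens = table.data["density"].to_numpy(dtype=float)
    keep = (dens >= lo) & (dens <= hi)
    out = FractionTable(table.data.loc[keep].reset_index(drop=True))
    kept_counts = out.data.groupby("tube_id").size()
    for tube in table.tubes:
        n = int(kept_counts.get(tube, 0))
        if n == 0:
            raise QsipDomainError(
                f"tube {tube!r} retains no fractions in density window "
                f"[{lo}, {hi}]"
            )
        logger.debug("tube %s: %d fractions in window [%g, %g]", tube, n, lo, hi)
    return out


def taxon_copies(table: FractionTable) -> pd.DataFrame:
    """Per-taxon 16S copies per fraction: relative abundance x qPCR total.

    Returns the metadata columns plus one copy-number column per taxon.
    """
    taxa = table.taxa
    ab = table.data[taxa].to_numpy(dtype=float)
    total = table.data["total_copies"].to_numpy(dtype=float)[:, None]
    return pd.concat(
        [
            table.data[list(META_COLUMNS)],
            pd.DataFrame(ab * total, columns=taxa, index=table.data.index),
        ],
        axis=1,
    )


def weighted_average_density(copies, densities, min_fractions_present: int = 1):
    """Copy-weighted mean buoyant density of one taxon in one tube.

    Returns ``nan`` (taxon absent) when the taxon has positive copies in
    fewer than ``min_fractions_present`` fractions.
    """
    c = np.asarray(copies, dtype=float)
    d = np.asarray(densities, dtype=float)
    if c.shape != d.shape:
        raise ValueError("copies and densities must align")
    if np.count_nonzero(c > 0) < min_fractions_present or c.sum() <= 0:
        return float("nan")
    return float((d * c).sum() / c.sum())


def gc_from_wad(w_light, k: QsipConstants = DEFAULT_CONSTANTS):
    """GC content from the unlabeled WAD; clamped to [0, 1] with a warning."""
    gc = (np.asarray(w_light, dtype=float) - k.gc_intercept) * k.gc_slope_inv
    if np.any(gc < 0) or np.any(gc > 1):
        warnings.warn(
            "GC content outside [0, 1] inferred from WAD; clamping",
            RuntimeWarning,
            stacklevel=2,
        )
    clipped = np.clip(gc, 0.0, 1.0)
    return float(clipped) if np.ndim(w_light) == 0 else clipped


def molecular_weights(gc, w_light, w_lab, k: QsipConstants = DEFAULT_CONSTANTS):
    """(M_light, M_lab, M_heavy) in g/mol for one taxon.

    M_lab rescales M_light by the observed labeled/unlabeled WAD ratio;
    M_heavy is the fully labeled bound.
    """
    gc = np.asarray(gc, dtype=float)
    w_light = np.asarray(w_light, dtype=float)
    w_lab = np.asarray(w_lab, dtype=float)
    ratio = w_lab / w_light
    if np.any(~np.isnan(ratio) & (ratio <= 0)):
        raise QsipDomainError("w_lab / w_light must be positive")
    m_light = k.mw_gc_slope * gc + k.mw_intercept
    m_heavy = m_light + k.delta_mw_18o_max
    m_lab = m_light * ratio
    return m_light, m_lab, m_heavy


def excess_atom_fraction(m_light, m_lab, m_heavy, k: QsipConstants = DEFAULT_CONSTANTS):
    """Excess atom fraction 18O of a taxon's DNA.

    May be negative under measurement noise; deliberately not clamped so that
    bootstrap distributions stay unbiased.
    """
    m_light = np.asarray(m_light, dtype=float)
    if np.any(np.asarray(m_heavy) <= m_light):
        raise QsipDomainError("m_heavy must exceed m_light")
    return (np.asarray(m_lab) - m_light) / (np.asarray(m_heavy) - m_light) * (
        1.0 - k.p_nat_18o
    )


def unlabeled_copies(n_total, m_light, m_lab, m_heavy):
    """N_light: copies attributable to pre-existing (unlabeled) DNA."""
    m_light = np.asarray(m_light, dtype=float)
    m_lab = np.asarray(m_lab, dtype=float)
    m_heavy = np.asarray(m_heavy, dtype=float)
    if np.any(~np.isnan(m_lab) & (m_lab > m_heavy)):
        raise QsipDomainError(
            "m_lab exceeds m_heavy (over-labeling); inputs are inconsistent"
        )
    return np.asarray(n_total, dtype=float) * (m_heavy - m_lab) / (m_heavy - m_light)


def growth_rate(n_total, n_light, t: float):
    """Per-capita growth rate g = ln(N_total / N_light) / t, per day."""
    n_total = np.asarray(n_total, dtype=float)
    n_light = np.asarray(n_light, dtype=float)
    if t <= 0:
        raise QsipDomainError("incubation time t must be > 0")
    if np.any(~np.isnan(n_light) & (n_light <= 0) & (n_total > 0)):
        raise QsipDomainError(
            "N_light <= 0 implies infinite growth; over-labeled input"
        )
    return np.log(n_total / n_light) / t


def absolute_growth(n_total, g, t: float):
    """dN/dt = N_total (1 - e^(-g t)) / t, new copies per g soil per day."""
    if t <= 0:
        raise QsipDomainError("incubation time t must be > 0")
    return np.asarray(n_total, dtype=float) * (1.0 - np.exp(-np.asarray(g) * t)) / t


# ---------------------------------------------------------------------------
# per-treatment estimation with bootstrap
# ---------------------------------------------------------------------------

def _chain(w_light, w_lab, n_total, t, k: QsipConstants):
    """Vectorised full chain; invalid inputs propagate as nan, not raise."""
    gc = np.clip((w_light - k.gc_intercept) * k.gc_slope_inv, 0.0, 1.0)
    m_light = k.mw_gc_slope * gc + k.mw_intercept
    m_heavy = m_light + k.delta_mw_18o_max
    m_lab = m_light * (w_lab / w_light)
    eaf = (m_lab - m_light) / (m_heavy - m_light) * (1.0 - k.p_nat_18o)
    n_light = n_total * (m_heavy - m_lab) / (m_heavy - m_light)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_light > 0, n_total / n_light, np.nan)
        g = np.log(ratio) / t
    dndt = n_total * (1.0 - np.exp(-g * t)) / t
    return eaf, g, dndt


@dataclass
class TreatmentArrays:
    """Per-tube WAD and copy-total matrices for one treatment."""

    treatment: str
    taxa: list[str]
    wad_16o: np.ndarray      # (n_tubes_16o, n_taxa), nan where absent
    wad_18o: np.ndarray      # (n_tubes_18o, n_taxa)
    totals_18o: np.ndarray   # (n_tubes_18o, n_taxa) summed window copies
    tubes_16o: list[str]
    tubes_18o: list[str]


def _per_tube_arrays(table: FractionTable, min_fractions_present: int):
    """WAD and summed copies per (tube, taxon); nan WAD marks absence."""
    taxa = table.taxa
    copies_df = taxon_copies(table)
    tubes = table.tubes
    n_taxa = len(taxa)
    wad = np.full((len(tubes), n_taxa), np.nan)
    totals = np.zeros((len(tubes), n_taxa))
    for i, tube in enumerate(tubes):
        sub = copies_df[copies_df["tube_id"] == tube]
        dens = sub["density"].to_numpy(dtype=float)
        c = sub[taxa].to_numpy(dtype=float)
        present = (c > 0).sum(axis=0) >= min_fractions_present
        csum = c.sum(axis=0)
        ok = present & (csum > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = (dens[:, None] * c).sum(axis=0) / csum
        wad[i, ok] = w[ok]
        totals[i] = csum
    return wad, totals, tubes


def treatment_arrays(
    table: FractionTable, treatment: str, config: RunConfig
) -> TreatmentArrays:
    sub = table.subset(treatment=treatment)
    t16 = sub.subset(isotope="16O")
    t18 = sub.subset(isotope="18O")
    if not len(t16) or not len(t18):
        raise QsipDomainError(
            f"treatment {treatment!r} needs at least one tube of each isotope"
        )
    w16, _, tubes16 = _per_tube_arrays(t16, config.min_fractions_present)
    w18, tot18, tubes18 = _per_tube_arrays(t18, config.min_fractions_present)
    return TreatmentArrays(
        treatment=treatment,
        taxa=sub.taxa,
        wad_16o=w16,
        wad_18o=w18,
        totals_18o=tot18,
        tubes_16o=tubes16,
        tubes_18o=tubes18,
    )


@dataclass
class GrowthResult:
    """Per-taxon growth estimates for one treatment.

    estimates
        One row per retained taxon: eaf/g/dndt point estimates with
        percentile-bootstrap CI bounds and the incorporator flag.
    replicate_dndt
        Per-replicate absolute growth (one row per 18O tube), the input to
        downstream effect-size bootstraps.
    bootstrap_dndt
        The (n_bootstrap, n_taxa) dN/dt draws, kept so phylum-level sums can
        inherit a CI.
    """

    treatment: str
    estimates: pd.DataFrame
    replicate_dndt: pd.DataFrame
    bootstrap_dndt: np.ndarray = field(repr=False)
    excluded_taxa: list[str] = field(default_factory=list)


def estimate_growth(
    table: FractionTable,
    design: Design,
    config: RunConfig,
    treatment: str | None = None,
    constants: QsipConstants = DEFAULT_CONSTANTS,
    rng: np.random.Generator | None = None,
    window: tuple[float, float] | None = None,
) -> GrowthResult | dict[str, GrowthResult]:
    """Estimate per-taxon EAF, g and dN/dt for one or all treatments.

    The fraction table is first restricted to the retained density window
    (``design.density_window`` unless overridden). Within a treatment, the
    point estimate uses the mean 16O-tube WAD as the unlabeled baseline, the
    mean 18O-tube WAD as the labeled density, and the mean 18O-tube summed
    window copies as N_total. The bootstrap resamples replicate tubes with
    replacement independently within each isotope set.

    A taxon is retained when it is present (positive copies in at least
    ``config.min_fractions_present`` fractions) in at least two tubes — or
    all tubes, if fewer than two — of *both* isotope sets; others are
    excluded and logged.
    """
    win = window if window is not None else design.density_window
    filtered = filter_window(table, win)
    if treatment is None:
        out: dict[str, GrowthResult] = {}
        for i, tr in enumerate(design.treatments):
            if not (filtered.data["treatment"] == tr).any():
                continue
            tr_rng = (
                np.random.default_rng(config.seed_sequence(10, i))
                if rng is None
                else rng
            )
            out[tr] = estimate_growth(
                filtered, design, config, tr, constants, tr_rng, window=(-np.inf, np.inf)
            )
        return out

    arrays = treatment_arrays(filtered, treatment, config)
    t = design.incubation_days
    n16, n18 = arrays.wad_16o.shape[0], arrays.wad_18o.shape[0]

    min_tubes_16 = min(2, n16)
    min_tubes_18 = min(2, n18)
    present16 = (~np.isnan(arrays.wad_16o)).sum(axis=0) >= min_tubes_16
    present18 = (~np.isnan(arrays.wad_18o)).sum(axis=0) >= min_tubes_18
    keep = present16 & present18
    excluded = [tx for tx, k_ in zip(arrays.taxa, keep) if not k_]
    if excluded:
        logger.info(
            "treatment %s: excluded %d taxa absent from replicate tubes",
            treatment,
            len(excluded),
        )
    taxa = [tx for tx, k_ in zip(arrays.taxa, keep) if k_]
    w16 = arrays.wad_16o[:, keep]
    w18 = arrays.wad_18o[:, keep]
    tot18 = arrays.totals_18o[:, keep]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        w_light = np.nanmean(w16, axis=0)
        w_lab = np.nanmean(w18, axis=0)
    n_total = tot18.mean(axis=0)
    eaf, g, dndt = _chain(w_light, w_lab, n_total, t, constants)

    if rng is None:
        rng = np.random.default_rng(config.seed_sequence(10))
    B = config.n_bootstrap
    idx16 = rng.integers(0, n16, size=(B, n16))
    idx18 = rng.integers(0, n18, size=(B, n18))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        wl_b = np.nanmean(w16[idx16], axis=1)      # (B, n_taxa)
        wlab_b = np.nanmean(w18[idx18], axis=1)
    nt_b = tot18[idx18].mean(axis=1)
    eaf_b, g_b, dndt_b = _chain(wl_b, wlab_b, nt_b, t, constants)

    alpha = 1.0 - config.ci_level
    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        eaf_lo, eaf_hi = np.nanpercentile(eaf_b, qs, axis=0)
        g_lo, g_hi = np.nanpercentile(g_b, qs, axis=0)
        d_lo, d_hi = np.nanpercentile(dndt_b, qs, axis=0)

    estimates = pd.DataFrame(
        {
            "taxon": taxa,
            "treatment": treatment,
            "wad_light": w_light,
            "wad_lab": w_lab,
            "n_total": n_total,
            "eaf": eaf,
            "eaf_ci_low": eaf_lo,
            "eaf_ci_high": eaf_hi,
            "g": g,
            "g_ci_low": g_lo,
            "g_ci_high": g_hi,
            "dndt": dndt,
            "dndt_ci_low": d_lo,
            "dndt_ci_high": d_hi,
            "incorporator": g_lo > 0,
        }
    )

    # per-replicate rates: each 18O tube against the treatment-mean baseline
    rep_rows = {}
    for r in range(n18):
        _, _, dndt_r = _chain(w_light, w18[r], tot18[r], t, constants)
        rep_rows[arrays.tubes_18o[r]] = dndt_r
    replicate_dndt = pd.DataFrame.from_dict(rep_rows, orient="index", columns=taxa)

    return GrowthResult(
        treatment=treatment,
        estimates=estimates,
        replicate_dndt=replicate_dndt,
        bootstrap_dndt=dndt_b,
        excluded_taxa=excluded,
    )


def phylum_cumulative_growth(
    result: GrowthResult, taxonomy: dict[str, str], ci_level: float = 0.95
) -> pd.DataFrame:
    """Cumulative absolute growth per phylum: sum of member-taxon dN/dt.

    Taxa missing from ``taxonomy`` are pooled as ``"unassigned"``. The phylum
    CI comes from summing the per-taxon bootstrap draws within each draw.
    """
    taxa = list(result.estimates["taxon"])
    phyla = np.array([taxonomy.get(tx, "unassigned") for tx in taxa])
    point = result.estimates["dndt"].to_numpy()
    draws = result.bootstrap_dndt
    alpha = 1.0 - ci_level
    rows = []
    for ph in dict.fromkeys(phyla):
        mask = phyla == ph
        ph_draws = np.nansum(draws[:, mask], axis=1)
        lo, hi = np.percentile(ph_draws, (100 * alpha / 2, 100 * (1 - alpha / 2)))
        rows.append(
            {
                "phylum": ph,
                "treatment": result.treatment,
                "n_taxa": int(mask.sum()),
                "dndt": float(np.nansum(point[mask])),
                "dndt_ci_low": float(lo),
                "dndt_ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
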