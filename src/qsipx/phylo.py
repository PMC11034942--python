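"""Phylogenetic clustering of response groups: MNTD and the nearest taxon index.

For each group of taxa sharing a growth response (here: an interaction type
within a climate scenario), the mean nearest taxon distance (MNTD) — the
average cophenetic distance from each group member to its closest other
member — is compared with a null distribution obtained by drawing random
equal-size tip sets from the full tip pool. The nearest taxon index

    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

is positive when group members sit closer together near the tips of the tree
than random sets do. Following the convention of the study design this
emulates, NTI > 0 with p < 0.05 is read as phylogenetic clustering, p in
[0.05, 0.95] as a random phylogenetic distribution, and NTI < 0 with
p > 0.95 as overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .design import RunConfig


class PhyloError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A tree plus its cached tip-to-tip path-length (cophenetic) matrix."""

    tree: dendropy.Tree
    tip_labels: list[str]
    dmat: np.ndarray

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "Phylogeny":
        labels, dmat = cophenetic_matrix(tree)
        return cls(tree=tree, tip_labels=labels, dmat=dmat)

    def indices(self, labels) -> np.ndarray:
        lookup = {l: i for i, l in enumerate(self.tip_labels)}
        try:
            return np.array([lookup[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise PhyloError(f"taxon {exc.args[0]!r} is not a tip of the tree")


def cophenetic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Pairwise tip-to-tip path lengths (sum of branch lengths on the path)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            dmat[i, j] = dmat[j, i] = d
    return labels, dmat


def mntd(group_idx: np.ndarray, dmat: np.ndarray) -> float:
    """Mean nearest taxon distance of one tip set, given the full matrix."""
    k = len(group_idx)
    if k < 2:
        raise PhyloError("MNTD requires a group of at least 2 taxa")
    sub = dmat[np.ix_(group_idx, group_idx)].astype(float).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _null_mntds(
    n_tips: int, k: int, dmat: np.ndarray, n_null: int, rng: np.random.Generator
) -> np.ndarray:
    """Null MNTD distribution for size-k tip sets.

    When the number of distinct subsets does not exceed the null budget the
    null is enumerated exactly (each subset once); otherwise it is sampled.
    """
    import itertools
    import math

    if k <= n_tips and math.comb(n_tips, k) <= n_null:
        combos = itertools.combinations(range(n_tips), k)
        out = np.empty(math.comb(n_tips, k))
        for i, idx in enumerate(combos):
            sub = dmat[np.ix_(idx, idx)].copy()
            np.fill_diagonal(sub, np.inf)
            out[i] = sub.min(axis=1).mean()
        return out
    out = np.empty(n_null)
    for i in range(n_null):
        idx = rng.choice(n_tips, size=k, replace=False)
        sub = dmat[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        out[i] = sub.min(axis=1).mean()
    return out


@dataclass(frozen=True)
class NtiResult:
    group_id: str
    n_group: int
    mntd_obs: float
    null_mean: float
    null_sd: float
    nti: float
    p_value: float
    verdict: str


def nti(
    group_labels,
    phylogeny: Phylogeny,
    config: RunConfig,
    rng: np.random.Generator | None = None,
    group_id: str = "",
) -> NtiResult:
    """NTI of one tip group against a random-tip-set null.

    The null draws ``config.n_null_nti`` tip sets of the group's size from
    the full tip pool of the supplied tree (or enumerates every distinct
    subset when there are no more of them than the draw budget, making the
    null exact on small pools). p is the rank-based tail
    probability ``(#{null <= observed} + 1) / (n_null + 1)``; the null sd is
    the sample (n-1) standard deviation. A zero null sd (e.g. the group is
    the whole tree) raises a degenerate-null error naming the group.
    """
    idx = phylogeny.indices(group_labels)
    if len(set(idx.tolist())) != len(idx):
        raise PhyloError(f"group {group_id!r} contains duplicate taxa")
    obs = mntd(idx, phylogeny.dmat)
    if rng is None:
        rng = config.rng(30)
    nulls = _null_mntds(
        len(phylogeny.tip_labels), len(idx), phylogeny.dmat, config.n_null_nti, rng
    )
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1)) if len(nulls) > 1 else 0.0
    if null_sd == 0 or not np.isfinite(null_sd):
        raise PhyloError(
            f"degenerate null distribution (sd = 0) for group {group_id!r}"
        )
    nti_value = -(obs - null_mean) / null_sd
    p = (int((nulls <= obs).sum()) + 1) / (len(nulls) + 1)
    if nti_value > 0 and p < 0.05:
        verdict = "clustered"
    elif nti_value < 0 and p > 0.95:
        verdict = "overdispersed"
    else:
        verdict = "random"
    return NtiResult(
        group_id=group_id,
        n_group=len(idx),
        mntd_obs=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        nti=nti_value,
        p_value=p,
        verdict=verdict,
    )
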