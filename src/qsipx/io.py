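"""Fraction-table container and TSV / newick readers and writers.

The raw measurement object of a density-gradient SIP experiment is the
fraction table: for every ultracentrifuge tube and every gradient fraction it
records the fraction's buoyant density, the total 16S rRNA gene copy number
measured by qPCR, and the relative abundance of each taxon from amplicon
sequencing of that fraction. Tables are wide TSV: one row per
(tube, fraction), metadata columns first, then one column per taxon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .design import Design, DesignError, unique_tube_check

META_COLUMNS = (
    "tube_id",
    "treatment",
    "isotope",
    "replicate",
    "fraction",
    "density",
    "total_copies",
)

_ROWSUM_TOL = 1e-9


class FormatError(ValueError):
    """Malformed input file (missing column, unparseable content)."""


class ValidationError(ValueError):
    """Well-formed input whose values violate an invariant."""


@dataclass
class FractionTable:
    """Tube x fraction records with per-taxon relative abundances.

    ``data`` holds one row per (tube, fraction): the metadata columns of
    :data:`META_COLUMNS` followed by one float column per taxon. Relative
    abundances in a row may sum to less than 1; the remainder is unclassified
    read mass and never enters per-taxon copy computation.
    """

    data: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLUMNS]

    @property
    def tubes(self) -> list[str]:
        return list(dict.fromkeys(self.data["tube_id"]))

    def __len__(self) -> int:
        return len(self.data)

    def validate(self, design: Design | None = None) -> "FractionTable":
        df = self.data
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        taxa = self.taxa
        if not taxa:
            raise FormatError("no taxon abundance columns present")
        ab = df[taxa].to_numpy(dtype=float)
        bad = np.where((ab < 0) | (ab > 1))
        if bad[0].size:
            r, c = int(bad[0][0]), int(bad[1][0])
            raise ValidationError(
                f"abundance outside [0, 1] at row {r}, taxon {taxa[c]!r}: {ab[r, c]}"
            )
        rowsum = ab.sum(axis=1)
        over = np.where(rowsum > 1.0 + _ROWSUM_TOL)[0]
        if over.size:
            r = int(over[0])
            raise ValidationError(
                f"taxon abundances sum to {rowsum[r]} > 1 at row {r}"
            )
        if (df["density"].to_numpy(dtype=float) <= 0).any():
            rows = np.where(df["density"].to_numpy(dtype=float) <= 0)[0]
            raise ValidationError(f"non-positive density at row(s) {rows.tolist()}")
        if (df["total_copies"].to_numpy(dtype=float) < 0).any():
            rows = np.where(df["total_copies"].to_numpy(dtype=float) < 0)[0]
            raise ValidationError(f"negative total_copies at row(s) {rows.tolist()}")
        dup = df.duplicated(subset=["tube_id", "fraction"])
        if dup.any():
            raise ValidationError(
                f"duplicate fraction index within tube at row(s) "
                f"{np.where(dup)[0].tolist()}"
            )
        if design is not None:
            for label in df["treatment"].unique():
                design.validate_treatment(str(label))
            for iso in df["isotope"].unique():
                design.validate_isotope(str(iso))
            unique_tube_check(
                df.drop_duplicates("tube_id")[
                    ["treatment", "isotope", "replicate"]
                ].itertuples(index=False, name=None)
            )
        return self

    def subset(self, **levels) -> "FractionTable":
        """Rows matching all given metadata values, e.g. ``treatment="T0nP"``."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in levels.items():
            mask &= self.data[col] == val
        return FractionTable(self.data.loc[mask].reset_index(drop=True))


def read_fraction_table(path: str | Path, design: Design | None = None) -> FractionTable:
    """Read and validate a wide fraction-table TSV.

    Raises :class:`FormatError` for missing columns, :class:`ValidationError`
    for invariant violations (naming the offending row), and
    :class:`~qsipx.design.DesignError` for treatment or isotope labels that do
    not resolve against ``design``.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message is adequate
        raise FormatError(f"could not parse TSV {path}: {exc}") from exc
    return FractionTable(df).validate(design)


def write_fraction_table(table: FractionTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick phylogeny whose tip labels are taxon ids.

    Branch lengths are required on every edge except the root edge (they are
    what MNTD measures); duplicate tip labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"duplicate tip label(s) in {path}: {exc}") from exc
        raise FormatError(f"could not parse newick {path}: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate tip label(s): {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError(
                "tree has edges without branch lengths; lengths are required "
                "for MNTD/NTI distance computation"
            )
        if edge.length < 0:
            raise ValidationError("negative branch length in tree")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
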