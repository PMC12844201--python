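"""Omics matrix container, gene/protein locus-tag matching and standardization.

The central container is :class:`OmicsMatrix`: a conditions x features
abundance table for one omics layer, backed by a pandas DataFrame whose
index holds condition IDs and whose columns hold locus tags. Transcript
locus tags are conventionally lower case (``rpa2624``) and protein tags
upper case (``RPA2624``); all matching here is case-insensitive because
both casings name the same locus.

The preprocessing contract for the downstream regressors is: keep only
genes whose protein was detected (``match_layers``), then transform each
feature to zero mean and unit population variance (``standardize``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlreadyStandardizedError,
    InputError,
    NoOverlapError,
)

logger = logging.getLogger(__name__)

LAYERS = ("transcriptomics", "proteomics")

#: Tolerances the standardization contract promises.
MEAN_TOL = 1e-12
VAR_TOL = 1e-9


@dataclass
class OmicsMatrix:
    """Conditions x features abundance table for one omics layer.

    Parameters
    ----------
    layer
        ``"transcriptomics"`` or ``"proteomics"``.
    data
        DataFrame with condition IDs as index and feature IDs (locus
        tags) as columns. Must be numeric and free of missing values:
        the loader fails fast rather than silently imputing, because
        with ~14 conditions per study any imputation is consequential.
    standardized
        Whether ``standardize`` has already been applied.
    """

    layer: str
    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise InputError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if not isinstance(self.data, pd.DataFrame):
            raise InputError("data must be a pandas DataFrame")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate condition IDs: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate feature IDs: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise InputError("abundance values must be numeric")
        if values.size and np.isnan(values.astype(float)).any():
            raise InputError(
                "matrix contains missing values; impute explicitly before constructing "
                "an OmicsMatrix (see impute_median)"
            )

    @property
    def condition_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_conditions(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, features: Sequence[str]) -> "OmicsMatrix":
        """Column subset (case-insensitive feature lookup), preserving order of `features`."""
        resolved = resolve_features(self.feature_ids, features)
        return replace(self, data=self.data.loc[:, resolved].copy())


def resolve_features(available: Sequence[str], wanted: Sequence[str]) -> list[str]:
    """Map requested feature IDs onto available ones, ignoring case.

    Raises
    ------
    InputError
        If any requested ID has no (case-insensitive) match.
    """
    lookup = {f.casefold(): f for f in available}
    missing = [w for w in wanted if w.casefold() not in lookup]
    if missing:
        raise InputError(f"unknown feature IDs: {missing}")
    return [lookup[w.casefold()] for w in wanted]


def impute_median(data: pd.DataFrame) -> pd.DataFrame:
    """Optional per-feature median imputation for matrices loaded with gaps."""
    return data.fillna(data.median(axis=0))


@dataclass(frozen=True)
class IdMap:
    """One-to-one gene <-> protein locus-tag pairs.

    Stored as an immutable tuple of ``(gene_id, protein_id)`` pairs; the
    mapping must be one-to-one on the retained set (checked on
    construction, case-insensitively).
    """

    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        genes = [g.casefold() for g, _ in self.pairs]
        prots = [p.casefold() for _, p in self.pairs]
        if len(set(genes)) != len(genes) or len(set(prots)) != len(prots):
            raise InputError("IdMap must be one-to-one: duplicate gene or protein IDs")

    def __len__(self) -> int:
        return len(self.pairs)

    def gene_to_protein(self) -> dict[str, str]:
        """Casefolded gene ID -> protein ID (original case)."""
        return {g.casefold(): p for g, p in self.pairs}

    def protein_to_gene(self) -> dict[str, str]:
        """Casefolded protein ID -> gene ID (original case)."""
        return {p.casefold(): g for g, p in self.pairs}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.pairs), columns=["gene_id", "protein_id"])


def build_locus_map(gene_ids: Iterable[str], protein_ids: Iterable[str]) -> IdMap:
    """Pair genes with proteins whose locus tags match up to case.

    This is the conventional situation for bacterial locus tags, where
    ``rpa2624`` (transcript) and ``RPA2624`` (protein) name one locus.
    """
    genes = {g.casefold(): g for g in gene_ids}
    prots = {p.casefold(): p for p in protein_ids}
    shared = sorted(set(genes) & set(prots))
    return IdMap(tuple((genes[tag], prots[tag]) for tag in shared))


def match_layers(
    trans: OmicsMatrix, prot: OmicsMatrix, id_map: IdMap
) -> tuple[OmicsMatrix, OmicsMatrix, IdMap]:
    """Keep only genes whose protein was detected, aligning feature order.

    Both returned matrices have the same feature count, column ``i`` of
    the transcriptomic output and column ``i`` of the proteomic output
    referring to the same locus under `id_map`. The retained set is
    sorted by casefolded gene tag, so the result does not depend on the
    input column order.

    Raises
    ------
    NoOverlapError
        If the map connects no feature present in both matrices.
    """
    if trans.layer != "transcriptomics" or prot.layer != "proteomics":
        raise InputError("match_layers expects (transcriptomics, proteomics) in that order")
    gene_cols = {f.casefold(): f for f in trans.feature_ids}
    prot_cols = {f.casefold(): f for f in prot.feature_ids}
    retained = [
        (gene_cols[g.casefold()], prot_cols[p.casefold()])
        for g, p in id_map.pairs
        if g.casefold() in gene_cols and p.casefold() in prot_cols
    ]
    retained.sort(key=lambda gp: gp[0].casefold())
    if not retained:
        raise NoOverlapError("no gene/protein pairs shared by both layers under the map")
    genes = [g for g, _ in retained]
    prots = [p for _, p in retained]
    logger.info("match_layers retained %d of %d mapped loci", len(retained), len(id_map))
    trans_out = replace(trans, data=trans.data.loc[:, genes].copy())
    prot_out = replace(prot, data=prot.data.loc[:, prots].copy())
    return trans_out, prot_out, IdMap(tuple(retained))


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Per-feature transform to zero mean and unit population variance.

    Uses the population (n-denominator) variance, i.e. the conventional
    z-score over the observed conditions. Zero-variance features carry
    no between-condition information and are mapped to all-zero columns
    with a warning.

    Raises
    ------
    AlreadyStandardizedError
        If `m` is already standardized — double scaling is always a bug.
    """
    if m.standardized:
        raise AlreadyStandardizedError(f"{m.layer} matrix is already standardized")
    X = m.values()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    # Numerically constant columns: spread at the rounding noise of the
    # column's own magnitude counts as zero variance.
    flat = sd <= 10.0 * np.finfo(float).eps * np.maximum(np.abs(mean), 1.0)
    if flat.any():
        names = [f for f, z in zip(m.feature_ids, flat) if z]
        warnings.warn(
            f"{flat.sum()} zero-variance feature(s) set to all-zeros: {names[:5]}"
            + ("..." if len(names) > 5 else ""),
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, flat] = 0.0
    out = pd.DataFrame(Z, index=m.data.index.copy(), columns=m.data.columns.copy())
    return replace(m, data=out, standardized=True)
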