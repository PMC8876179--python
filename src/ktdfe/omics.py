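"""Containers and preprocessing for multi-omics blocks sharing sample modes.

A *block* is one omics measurement (methylation, gene expression, a proteome,
...) stored feature-mode first: an array of shape ``N_k x M_1 x ... x M_m``
where the ``m`` trailing sample modes (time points, individuals, tissues, ...)
are identical across all blocks of a :class:`MultiOmicsTensorSet`.  Feature
counts ``N_k`` may differ freely between blocks — that is the point of the
kernel construction downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MultiOmicsBlock",
    "MultiOmicsTensorSet",
    "standardize_samples",
    "fill_missing",
    "validate_set",
    "read_block",
    "write_block",
]


@dataclass
class MultiOmicsBlock:
    """One omics data block, feature mode first.

    Parameters
    ----------
    omics_id : str
        Label for the omics type (e.g. ``"methylation"``).
    values : ndarray of shape (N_k, M_1, ..., M_m)
        Numeric measurements; may contain NaN before :func:`fill_missing`.
    feature_ids : sequence of str
        Unique identifiers, one per feature row.
    sample_mode_labels : list of list of str
        One label list per sample mode, lengths ``M_1 ... M_m``.
    """

    omics_id: str
    values: np.ndarray
    feature_ids: list = field(default_factory=list)
    sample_mode_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim < 2:
            raise ValueError("block values need a feature mode plus >=1 sample mode")
        n = self.values.shape[0]
        if not self.feature_ids:
            self.feature_ids = [f"{self.omics_id}:{i+1}" for i in range(n)]
        self.feature_ids = list(self.feature_ids)
        if len(self.feature_ids) != n:
            raise ValueError(
                f"{self.omics_id}: {len(self.feature_ids)} feature ids for {n} rows"
            )
        if not self.sample_mode_labels:
            self.sample_mode_labels = [
                [str(j + 1) for j in range(M)] for M in self.values.shape[1:]
            ]
        sizes = tuple(len(lv) for lv in self.sample_mode_labels)
        if sizes != self.values.shape[1:]:
            raise ValueError(
                f"{self.omics_id}: sample mode labels {sizes} do not match "
                f"shape {self.values.shape[1:]}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def sample_shape(self) -> tuple:
        return self.values.shape[1:]

    @property
    def n_sample_modes(self) -> int:
        return self.values.ndim - 1

    def duplicate_feature_ids(self) -> list:
        seen, dups = set(), []
        for f in self.feature_ids:
            if f in seen and f not in dups:
                dups.append(f)
            seen.add(f)
        return dups


@dataclass
class MultiOmicsTensorSet:
    """K omics blocks sharing identical sample modes."""

    blocks: list

    def __post_init__(self):
        if len(self.blocks) < 1:
            raise ValueError("tensor set needs at least one block")
        violations = validate_set(self)
        if violations:
            raise ValueError("invalid tensor set: " + "; ".join(violations))

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def sample_shape(self) -> tuple:
        return self.blocks[0].sample_shape

    @property
    def omics_ids(self) -> list:
        return [b.omics_id for b in self.blocks]


def validate_set(tset) -> list:
    """Return a list of violation messages; empty iff the set is consistent."""
    blocks = tset.blocks if hasattr(tset, "blocks") else list(tset)
    out = []
    if not blocks:
        return ["no blocks"]
    ref = blocks[0]
    for b in blocks:
        if b.sample_shape != ref.sample_shape:
            out.append(
                f"shape mismatch: {b.omics_id} has sample modes {b.sample_shape}, "
                f"expected {ref.sample_shape}"
            )
        elif b.sample_mode_labels != ref.sample_mode_labels:
            out.append(f"label mismatch: {b.omics_id} sample labels differ from {ref.omics_id}")
        dups = b.duplicate_feature_ids()
        if dups:
            out.append(f"duplicate feature ids in {b.omics_id}: {dups[:5]}")
        if b.values.size and not np.isfinite(b.values[~np.isnan(b.values)]).all():
            out.append(f"non-finite (inf) values in {b.omics_id}")
    return out


def standardize_samples(block: MultiOmicsBlock) -> MultiOmicsBlock:
    """Standardize each sample cell over features: sum 0, sum of squares N_k.

    For every sample coordinate tuple the N_k-vector of feature values x is
    replaced by ``(x - mean(x)) * sqrt(N_k / sum((x - mean(x))**2))``, so that
    all sample cells live on a common scale before the linear kernel sums over
    features.  Idempotent up to round-off.
    """
    x = block.values
    if not np.isfinite(x).all():
        raise ValueError(f"{block.omics_id}: non-finite values; impute first")
    n = block.n_features
    if n < 2:
        raise ValueError(f"{block.omics_id}: need >=2 features to standardize")
    centered = x - x.mean(axis=0, keepdims=True)
    ss = (centered**2).sum(axis=0)
    bad = np.argwhere(ss == 0)
    if bad.size:
        cell = tuple(int(c) + 1 for c in bad[0])
        raise ValueError(
            f"{block.omics_id}: zero variance across features at sample cell {cell}"
        )
    out = centered * np.sqrt(n / ss)
    return replace(block, values=out)


def fill_missing(block: MultiOmicsBlock, strategy: str = "zero") -> MultiOmicsBlock:
    """Replace missing (NaN) entries; only the ``"zero"`` strategy is supported."""
    if strategy != "zero":
        raise ValueError(f"unknown missing-value strategy: {strategy!r}")
    x = block.values
    mask = np.isnan(x)
    if not mask.any():
        return block
    axes = tuple(range(1, x.ndim))
    all_missing = mask.all(axis=axes)
    if all_missing.any():
        ids = [block.feature_ids[i] for i in np.flatnonzero(all_missing)[:5]]
        warnings.warn(
            f"{block.omics_id}: {int(all_missing.sum())} all-missing feature rows "
            f"zero-filled (e.g. {ids})",
            stacklevel=2,
        )
    out = np.where(mask, 0.0, x)
    return replace(block, values=out)


def read_block(path, sample_map, omics_id=None, sep="\t", na_values=("NA", "")) -> MultiOmicsBlock:
    """Read a feature-by-sample TSV/CSV into a block.

    The first column holds feature IDs; remaining columns are samples.
    ``sample_map`` maps each sample column name to a 1-based coordinate tuple
    in the sample modes, e.g. ``{"d0_subj1": (1, 1), ...}``.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=list(na_values), keep_default_na=False)
    missing = [c for c in df.columns if c not in sample_map]
    if missing:
        raise ValueError(f"{path}: columns not in sample map: {missing}")
    unmapped = [c for c in sample_map if c not in df.columns]
    if unmapped:
        raise ValueError(f"{path}: sample map names absent from file: {unmapped}")
    coords = {c: tuple(int(v) for v in np.atleast_1d(sample_map[c])) for c in df.columns}
    m = len(next(iter(coords.values())))
    shape = tuple(max(c[s] for c in coords.values()) for s in range(m))
    n = df.shape[0]
    values = np.full((n, *shape), np.nan)
    for col in df.columns:
        idx = tuple(c - 1 for c in coords[col])
        values[(slice(None), *idx)] = pd.to_numeric(df[col], errors="raise").to_numpy()
    block = MultiOmicsBlock(
        omics_id=omics_id or str(path),
        values=values,
        feature_ids=[str(f) for f in df.index],
    )
    dups = block.duplicate_feature_ids()
    if dups:
        raise ValueError(f"{path}: duplicate feature ids: {dups[:5]}")
    return block


def write_block(block: MultiOmicsBlock, path, sample_map=None, sep="\t") -> dict:
    """Write a block back to a feature-by-sample table; returns the sample map used.

    Inverse of :func:`read_block` up to numeric formatting.  If no map is
    given, column names are generated as ``s<i1>_<i2>...`` from 1-based
    coordinates.
    """
    shape = block.sample_shape
    coords = list(np.ndindex(*shape))
    if sample_map is None:
        sample_map = {
            "s" + "_".join(str(c + 1) for c in t): tuple(c + 1 for c in t) for t in coords
        }
    inv = {tuple(v): k for k, v in sample_map.items()}
    cols, data = [], {}
    for t in coords:
        name = inv[tuple(c + 1 for c in t)]
        cols.append(name)
        data[name] = block.values[(slice(None), *t)]
    df = pd.DataFrame(data, index=block.feature_ids, columns=cols)
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep)
    return sample_map
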