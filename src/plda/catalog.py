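"""Mutation-catalog and signature containers with TSV readers/writers.

A mutation catalog is the samples x 96 count matrix of somatic single-base
substitutions, with every sample labeled by tumor type (the combination of
primary lesion and histology, e.g. ``Skin-Melanoma``).  Counts are kept as
integers because the downstream model is a count model; real-valued inputs
are rejected rather than rounded.

Two on-disk dialects are supported:

* ``samples-as-rows`` (default): one row per sample with ``sample_id`` and
  ``tumor_type`` columns followed by the 96 counts;
* ``samples-as-columns``: the COSMIC-matrix layout, one row per trinucleotide
  context and one column per sample, accompanied by a two-column TSV mapping
  ``sample_id`` to ``tumor_type``.

Mutation-type headers may use either ``A[T>C]G`` or ``T>C,A,G`` notation;
columns are remapped to the canonical order of :mod:`plda.sbs96` on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sbs96
from .sbs96 import MUTATION_TYPES, N_TYPES

logger = logging.getLogger(__name__)


class CatalogFormatError(ValueError):
    """Raised for malformed catalog or signature files."""


def _grouped(type_labels, tumor_types):
    """Return the stable ordering that groups samples by tumor type."""
    rank = {t: i for i, t in enumerate(tumor_types)}
    return np.argsort([rank[t] for t in type_labels], kind="stable")


@dataclass(frozen=True)
class MutationCatalog:
    """Per-tumor-type collection of per-sample SBS96 count vectors.

    Samples are stored grouped by tumor type, in the order given by
    ``tumor_types``.  ``type_index[i]`` is the tumor-type index of sample
    ``i``.  An empty catalog (no tumor types, no samples) is legal as the
    result of filtering but cannot be written or fitted.
    """

    tumor_types: tuple[str, ...]
    sample_ids: tuple[str, ...]
    type_index: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != N_TYPES:
            raise CatalogFormatError(
                f"count matrix must have {N_TYPES} columns, got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            raise CatalogFormatError("counts must be integers (the model is a count model)")
        if (counts < 0).any():
            raise CatalogFormatError("negative mutation counts are not allowed")
        if len(self.sample_ids) != counts.shape[0]:
            raise CatalogFormatError("sample_ids and counts disagree on the number of samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            raise CatalogFormatError(
                f"duplicate sample IDs: {sorted(set(dupes[dupes.duplicated()]))}"
            )
        ti = np.asarray(self.type_index)
        if ti.shape != (counts.shape[0],):
            raise CatalogFormatError("type_index must have one entry per sample")
        if counts.shape[0] > 0:
            if len(self.tumor_types) < 1:
                raise CatalogFormatError("a non-empty catalog needs at least one tumor type")
            if (np.diff(ti) < 0).any():
                raise CatalogFormatError("samples must be grouped by tumor type")
            present = np.unique(ti)
            if not np.array_equal(present, np.arange(len(self.tumor_types))):
                raise CatalogFormatError("every tumor type must retain at least one sample")
        elif len(self.tumor_types) != 0:
            raise CatalogFormatError("an empty catalog cannot declare tumor types")
        if len(set(self.tumor_types)) != len(self.tumor_types):
            raise CatalogFormatError("duplicate tumor-type labels")

    # -- basic shape accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def L(self) -> int:
        """Number of tumor types."""
        return len(self.tumor_types)

    @property
    def V(self) -> int:
        return N_TYPES

    @property
    def samples_per_type(self) -> np.ndarray:
        """S_l: number of samples in each tumor type."""
        return np.bincount(self.type_index, minlength=self.L).astype(int)

    @property
    def n_mutations(self) -> np.ndarray:
        """n_ls: total mutation count of every sample, in storage order."""
        return self.counts.sum(axis=1)

    def samples_of_type(self, l: int) -> np.ndarray:
        """Row indices of the samples belonging to tumor type ``l``."""
        return np.flatnonzero(self.type_index == l)

    # -- construction ----------------------------------------------------------

    @classmethod
    def from_samples(cls, sample_ids, tumor_type_labels, counts) -> "MutationCatalog":
        """Build a catalog from parallel per-sample arrays, grouping by type.

        Tumor-type order is the order of first appearance in
        ``tumor_type_labels``; the grouping sort is stable, so within-type
        sample order is preserved.
        """
        sample_ids = [str(s) for s in sample_ids]
        labels = [str(t) for t in tumor_type_labels]
        if len(sample_ids) != len(labels):
            raise CatalogFormatError("sample_ids and tumor_type_labels differ in length")
        tumor_types = tuple(dict.fromkeys(labels))
        order = _grouped(labels, tumor_types)
        rank = {t: i for i, t in enumerate(tumor_types)}
        counts = np.asarray(counts)
        return cls(
            tumor_types=tumor_types,
            sample_ids=tuple(sample_ids[i] for i in order),
            type_index=np.array([rank[labels[i]] for i in order], dtype=int),
            counts=np.ascontiguousarray(counts[order]),
        )

    def sample_tumor_types(self) -> tuple[str, ...]:
        """Tumor-type label of each sample, in storage order."""
        return tuple(self.tumor_types[i] for i in self.type_index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(MUTATION_TYPES))
        df.insert(0, "tumor_type", list(self.sample_tumor_types()))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class SignatureSet:
    """K mutation signatures, each a probability distribution over 96 types."""

    names: tuple[str, ...]
    probs: np.ndarray  # (K, 96)

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != N_TYPES:
            raise ValueError(f"signature matrix must be K x {N_TYPES}, got {p.shape}")
        if len(self.names) != p.shape[0]:
            raise ValueError("one name per signature required")
        if (p < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9, rtol=0):
            raise ValueError("every signature must sum to 1 (within 1e-9)")

    @property
    def K(self) -> int:
        return self.probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """96 rows x K signature columns, indexed by context label."""
        return pd.DataFrame(
            self.probs.T, index=pd.Index(MUTATION_TYPES, name="Type"), columns=list(self.names)
        )


@dataclass(frozen=True)
class ActivityMatrix:
    """Per-sample signature activities theta; every row lies on the K-simplex."""

    sample_ids: tuple[str, ...]
    tumor_types: tuple[str, ...]  # per-sample labels, parallel to sample_ids
    signature_names: tuple[str, ...]
    values: np.ndarray  # (N, K)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("activity matrix must be 2-D")
        if len(self.sample_ids) != v.shape[0] or len(self.tumor_types) != v.shape[0]:
            raise ValueError("sample_ids/tumor_types must match the number of rows")
        if len(self.signature_names) != v.shape[1]:
            raise ValueError("one signature name per column required")
        if (v < 0).any() or not np.allclose(v.sum(axis=1), 1.0, atol=1e-9, rtol=0):
            raise ValueError("activity rows must be probability vectors (sum 1 within 1e-9)")

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.signature_names))
        df.insert(0, "tumor_type", list(self.tumor_types))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


# -- readers / writers ---------------------------------------------------------


def _context_permutation(labels) -> np.ndarray:
    """Map a sequence of 96 context labels to canonical indices.

    Raises :class:`CatalogFormatError` naming duplicated or missing contexts.
    """
    idx = []
    for lab in labels:
        try:
            idx.append(sbs96.label_index(str(lab)))
        except sbs96.MutationTypeError as e:
            raise CatalogFormatError(f"unrecognized mutation-type column {lab!r}: {e}") from e
    seen = np.bincount(idx, minlength=N_TYPES)
    if (seen > 1).any():
        dupes = [MUTATION_TYPES[i] for i in np.flatnonzero(seen > 1)]
        raise CatalogFormatError(f"duplicate mutation-type columns: {dupes}")
    if (seen == 0).any():
        missing = [MUTATION_TYPES[i] for i in np.flatnonzero(seen == 0)]
        raise CatalogFormatError(f"missing mutation-type columns: {missing}")
    return np.asarray(idx)


def _as_int_counts(values: np.ndarray, context: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.number):
        raise CatalogFormatError(f"{context}: non-numeric mutation counts")
    as_float = arr.astype(float)
    if not np.isfinite(as_float).all():
        raise CatalogFormatError(f"{context}: non-finite mutation counts")
    rounded = np.rint(as_float)
    if not np.array_equal(rounded, as_float):
        bad = np.argwhere(rounded != as_float)[0]
        raise CatalogFormatError(
            f"{context}: non-integer count {as_float[tuple(bad)]!r} at row {bad[0]}, "
            f"column {bad[1]} — counts must be whole numbers"
        )
    if (rounded < 0).any():
        bad = np.argwhere(rounded < 0)[0]
        raise CatalogFormatError(f"{context}: negative count at row {bad[0]}, column {bad[1]}")
    return rounded.astype(np.int64)


def _check_duplicate_header(path) -> None:
    # pandas silently mangles duplicate column names, so inspect the raw header
    with open(path) as fh:
        tokens = fh.readline().rstrip("\n").split("\t")
    dupes = sorted({t for t in tokens if tokens.count(t) > 1})
    if dupes:
        raise CatalogFormatError(f"{path}: duplicate header columns: {dupes}")


def read_catalog(path, dialect: str = "samples-as-rows", tumor_type_map=None) -> MutationCatalog:
    """Read a mutation catalog from TSV.

    Parameters
    ----------
    path
        Catalog file.
    dialect
        ``samples-as-rows`` (default) or ``samples-as-columns`` (COSMIC-matrix
        layout; requires ``tumor_type_map``).
    tumor_type_map
        For ``samples-as-columns``: path to a TSV with columns ``sample_id``
        and ``tumor_type``.
    """
    if dialect == "samples-as-rows":
        _check_duplicate_header(path)
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        required = {"sample_id", "tumor_type"}
        if not required.issubset(df.columns):
            raise CatalogFormatError(
                f"{path}: missing required columns {sorted(required - set(df.columns))}"
            )
        context_cols = [c for c in df.columns if c not in required]
        perm = _context_permutation(context_cols)
        raw = _as_int_counts(df[context_cols].to_numpy(), str(path))
        counts = np.empty_like(raw)
        counts[:, perm] = raw
        return MutationCatalog.from_samples(df["sample_id"], df["tumor_type"], counts)
    if dialect == "samples-as-columns":
        if tumor_type_map is None:
            raise CatalogFormatError(
                "samples-as-columns dialect requires a sample_id -> tumor_type mapping file"
            )
        _check_duplicate_header(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        perm = _context_permutation(df.index)
        raw = _as_int_counts(df.to_numpy().T, str(path))  # samples x contexts (file order)
        counts = np.empty_like(raw)
        counts[:, perm] = raw
        mapping = pd.read_csv(tumor_type_map, sep="\t", dtype=str)
        if not {"sample_id", "tumor_type"}.issubset(mapping.columns):
            raise CatalogFormatError(
                f"{tumor_type_map}: expected columns sample_id and tumor_type"
            )
        lookup = dict(zip(mapping["sample_id"], mapping["tumor_type"]))
        sample_ids = [str(c) for c in df.columns]
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise CatalogFormatError(f"samples without tumor-type mapping: {missing}")
        return MutationCatalog.from_samples(
            sample_ids, [lookup[s] for s in sample_ids], counts
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_catalog(catalog: MutationCatalog, path) -> None:
    """Write a catalog as samples-as-rows TSV with canonical column order.

    Output is deterministic: two writes of the same catalog are
    byte-identical.
    """
    if catalog.L < 1:
        raise ValueError("cannot write an empty catalog (no tumor types)")
    catalog.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_signature_set(path) -> SignatureSet:
    """Read a COSMIC-style signature file: 96 context rows x K signature columns.

    Each column must already sum to 1 within 1e-6; columns are then
    renormalized exactly.  Rows are remapped to canonical context order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise CatalogFormatError(f"{path}: no signature columns found")
    perm = _context_permutation(df.index)
    raw = df.to_numpy(dtype=float)
    if not np.isfinite(raw).all() or (raw < 0).any():
        raise CatalogFormatError(f"{path}: signature entries must be finite and non-negative")
    totals = raw.sum(axis=0)
    off = np.flatnonzero(np.abs(totals - 1.0) > 1e-6)
    if off.size:
        raise CatalogFormatError(
            f"{path}: signature columns {list(df.columns[off])} sum to "
            f"{totals[off]} — not probability distributions"
        )
    probs = np.empty_like(raw.T)  # (K, 96)
    probs[:, perm] = raw.T
    probs /= probs.sum(axis=1, keepdims=True)
    return SignatureSet(names=tuple(str(c) for c in df.columns), probs=probs)


def write_signature_set(signatures: SignatureSet, path) -> None:
    """Write a signature set in the COSMIC-style layout read back by
    :func:`read_signature_set` (round-trip exact to float repr)."""
    signatures.to_frame().to_csv(path, sep="\t", lineterminator="\n")


def read_activities(path) -> ActivityMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tumor_type": str})
    sig_cols = [c for c in df.columns if c not in ("sample_id", "tumor_type")]
    return ActivityMatrix(
        sample_ids=tuple(df["sample_id"]),
        tumor_types=tuple(df["tumor_type"]),
        signature_names=tuple(sig_cols),
        values=df[sig_cols].to_numpy(dtype=float),
    )


def write_activities(theta: ActivityMatrix, path) -> None:
    theta.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def filter_min_mutations(catalog: MutationCatalog, min_count: int) -> MutationCatalog:
    """Drop samples with fewer than ``min_count`` total mutations.

    Samples with exactly ``min_count`` mutations are retained.  Tumor types
    left without samples are dropped.  The number of removed samples is
    logged; an empty result is legal but logged as a warning.
    """
    if min_count < 0:
        raise ValueError("min_count must be non-negative")
    keep = catalog.n_mutations >= min_count
    removed = int((~keep).sum())
    if removed:
        logger.info(
            "filter_min_mutations: removed %d of %d samples with fewer than %d mutations",
            removed, catalog.n_samples, min_count,
        )
    if not keep.any():
        logger.warning(
            "filter_min_mutations: no samples retained at threshold %d", min_count
        )
        return MutationCatalog(
            tumor_types=(),
            sample_ids=(),
            type_index=np.zeros(0, dtype=int),
            counts=np.zeros((0, N_TYPES), dtype=np.int64),
        )
    labels = np.asarray(catalog.sample_tumor_types(), dtype=object)[keep]
    ids = np.asarray(catalog.sample_ids, dtype=object)[keep]
    return MutationCatalog.from_samples(ids, labels, catalog.counts[keep])
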