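"""Observed-data containers, prior configuration, and structural validation.

The observed layer of the model is a quadruple (T, P, A, mask):

* ``T`` — n x q matrix of log-scale transcript abundances (optional; the
  model can run from peptides and a mask alone),
* ``P`` — n x r matrix of log-scale peptide abundances,
* ``A`` — length-n vector of binary condition labels (optional),
* ``mask`` — q x r binary detectability mask; ``mask[j, k] = 1`` iff peptide
  k can derive from isoform j (written ``k ≺ j``).

Rows index samples, columns index isoforms (T, mask rows) or peptides
(P, mask columns).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ObservedDataset",
    "PriorConfig",
    "TruncationBounds",
    "ValidationReport",
    "compute_truncation_bounds",
    "truncation_bounds_all",
    "validate_dataset",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


def _as_2d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class ObservedDataset:
    """Aligned transcript, peptide, condition and detectability data.

    Parameters
    ----------
    P : ndarray (n, r)
        Log-scale peptide abundances.
    mask : ndarray (q, r)
        Binary compatibility mask between isoforms (rows) and peptides
        (columns).
    T : ndarray (n, q), optional
        Log-scale transcript abundances, one column per isoform. ``None``
        drops the transcript term from the model.
    A : ndarray (n,), optional
        Binary condition labels. ``None`` drops the condition effect.
    """

    P: np.ndarray
    mask: np.ndarray
    T: np.ndarray | None = None
    A: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    isoform_ids: list[str] = field(default_factory=list)
    peptide_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.P = _as_2d(self.P, "P")
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-dimensional")
        self.mask = (self.mask != 0).astype(np.uint8)
        if self.T is not None:
            self.T = _as_2d(self.T, "T")
        if self.A is not None:
            self.A = np.asarray(self.A, dtype=float).ravel()
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.n)]
        if not self.isoform_ids:
            self.isoform_ids = [f"iso{j}" for j in range(self.q)]
        if not self.peptide_ids:
            self.peptide_ids = [f"pep{k}" for k in range(self.r)]

    @property
    def n(self) -> int:
        return self.P.shape[0]

    @property
    def q(self) -> int:
        return self.mask.shape[0]

    @property
    def r(self) -> int:
        return self.P.shape[1]

    @classmethod
    def from_frames(
        cls,
        P: pd.DataFrame,
        mask: pd.DataFrame,
        T: pd.DataFrame | None = None,
        A: pd.Series | Sequence | None = None,
    ) -> "ObservedDataset":
        """Build a dataset from labelled DataFrames, aligning on their labels.

        ``P`` and ``T`` are samples x features with sample ids in the index;
        ``mask`` is isoforms x peptides. Peptide columns of ``P`` are aligned
        to mask columns, transcript columns of ``T`` to mask rows.
        """
        mask_df = mask
        P = P.loc[:, list(mask_df.columns)]
        if T is not None:
            T = T.loc[P.index, list(mask_df.index)]
        if A is not None:
            A = pd.Series(A, index=P.index) if not isinstance(A, pd.Series) else A.loc[P.index]
        return cls(
            P=P.to_numpy(float),
            mask=mask_df.to_numpy(),
            T=None if T is None else T.to_numpy(float),
            A=None if A is None else A.to_numpy(float),
            sample_ids=[str(s) for s in P.index],
            isoform_ids=[str(j) for j in mask_df.index],
            peptide_ids=[str(k) for k in mask_df.columns],
        )

    @classmethod
    def from_tsv(
        cls,
        peptides: str,
        mask: str,
        transcripts: str | None = None,
        condition: str | None = None,
    ) -> "ObservedDataset":
        """Read the standard TSV layout (first column ids, header feature ids)."""
        P = read_matrix_tsv(peptides)
        M = read_matrix_tsv(mask)
        T = read_matrix_tsv(transcripts) if transcripts else None
        A = None
        if condition:
            A = read_matrix_tsv(condition).iloc[:, 0]
        return cls.from_frames(P=P, mask=M, T=T, A=A)

    def subset(self, isoforms: np.ndarray, peptides: np.ndarray) -> "ObservedDataset":
        """Restrict to the given isoform/peptide index arrays (e.g. one block)."""
        return ObservedDataset(
            P=self.P[:, peptides],
            mask=self.mask[np.ix_(isoforms, peptides)],
            T=None if self.T is None else self.T[:, isoforms],
            A=self.A,
            sample_ids=list(self.sample_ids),
            isoform_ids=[self.isoform_ids[j] for j in isoforms],
            peptide_ids=[self.peptide_ids[k] for k in peptides],
        )


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


@dataclass
class PriorConfig:
    """Hyperparameters of the hierarchical prior.

    All four ``tau_*`` entries are prior *variances* (scalar, broadcast over
    isoforms, or one value per isoform):

    * ``tau_w`` — variance of the N(1, tau_w) prior on conversion weights W,
    * ``tau_d`` — variance of the N(0, tau_d) prior (or slab) on condition
      effects D,
    * ``tau_z`` — variance of the truncated-normal prior on detectability
      coefficients Z,
    * ``tau_i0`` — variance of the prior on per-isoform intercepts. The
      default is diffuse (100): the baseline is a location nuisance on an
      arbitrary log-intensity scale, and a tight zero-centered intercept
      prior would shrink it and leak the deficit into the condition effect.

    ``prior_family`` selects "normal" (default) or "spike_slab" for D, where
    ``theta`` is the prior inclusion probability of the slab. Peptide noise
    variances carry a conjugate Inverse-Gamma(noise_a0, noise_b0) prior.
    ``i0_mean`` allows externally supplied prior means for the intercept
    (e.g. average expression from another study); default 0.
    """

    tau_w: float | np.ndarray = 1.0
    tau_d: float | np.ndarray = 1.0
    tau_z: float | np.ndarray = 1.0
    tau_i0: float | np.ndarray = 100.0
    prior_family: str = "normal"
    theta: float | np.ndarray = 0.5
    noise_a0: float = 1.0
    noise_b0: float = 1.0
    i0_mean: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_w", "tau_d", "tau_z", "tau_i0"):
            val = np.asarray(getattr(self, name), dtype=float)
            if np.any(val <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.prior_family not in ("normal", "spike_slab"):
            raise ValueError(f"unknown prior_family {self.prior_family!r}")
        th = np.asarray(self.theta, dtype=float)
        if np.any(th <= 0) or np.any(th > 1):
            raise ValueError("theta must lie in (0, 1]")
        if self.noise_a0 <= 0 or self.noise_b0 <= 0:
            raise ValueError("noise hyperparameters must be positive")

    def broadcast(self, q: int) -> "PriorConfig":
        """Return a copy with per-isoform vectors of length q."""
        kw = {}
        for name in ("tau_w", "tau_d", "tau_z", "tau_i0", "theta", "i0_mean"):
            kw[name] = np.broadcast_to(np.asarray(getattr(self, name), float), (q,)).copy()
        return dataclasses.replace(self, **kw)

    def to_yaml(self, path) -> None:
        as_dict = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(as_dict, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PriorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class TruncationBounds:
    """Support [lower, upper] of the truncated-normal prior on one isoform's Z.

    Bounds are ratios of peptide column means, so 0 < lower <= 1 <= upper and
    lower = 1/upper.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= 1.0 + 1e-12 <= self.upper + 2e-12):
            raise ValueError(f"invalid truncation bounds ({self.lower}, {self.upper})")


class StructuralError(ValueError):
    """Mask/topology violation that makes the model undefined."""


def compute_truncation_bounds(P: np.ndarray, mask: np.ndarray, j: int) -> TruncationBounds:
    """Data-driven truncation bounds for isoform ``j``'s detectability prior.

    With column means ``m_k`` of the peptides compatible with isoform j,
    the lower bound is min(m)/max(m) and the upper bound its reciprocal, so
    that detectability coefficients keep latent abundances on the scale of
    the observed peptides.
    """
    P = np.asarray(P, float)
    support = np.flatnonzero(np.asarray(mask)[j] != 0)
    if support.size == 0:
        raise StructuralError(f"isoform {j} has no compatible peptide")
    means = P[:, support].mean(axis=0)
    if np.any(means <= 0):
        raise ValueError(
            f"isoform {j}: nonpositive peptide column mean; shift or rescale the "
            "peptide matrix to a positive working scale before computing bounds"
        )
    lo = float(means.min() / means.max())
    return TruncationBounds(lower=lo, upper=1.0 / lo)


def truncation_bounds_all(
    P: np.ndarray, mask: np.ndarray, policy: str = "data"
) -> np.ndarray:
    """Per-isoform (q, 2) bounds array under a policy.

    policy "data"     — strict ratio-of-means bounds; raises on nonpositive
                        column means.
    policy "data-abs" — ratio of absolute column means; coincides with
                        "data" whenever all means are positive, and stays
                        defined on signed working scales.
    """
    mask = np.asarray(mask)
    P = np.asarray(P, float)
    q = mask.shape[0]
    out = np.empty((q, 2))
    col_means = P.mean(axis=0)
    for j in range(q):
        if policy == "data":
            b = compute_truncation_bounds(P, mask, j)
            out[j] = (b.lower, b.upper)
            continue
        if policy != "data-abs":
            raise ValueError(f"unknown bounds policy {policy!r}")
        support = np.flatnonzero(mask[j] != 0)
        if support.size == 0:
            raise StructuralError(f"isoform {j} has no compatible peptide")
        means = np.abs(col_means[support])
        means = np.where(means < 1e-12, 1e-12, means)
        lo = float(means.min() / means.max())
        out[j] = (lo, 1.0 / lo)
    return out


@dataclass
class ValidationReport:
    """Collected structural violations; empty means the dataset is usable."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return "OK" if self.ok else "\n".join(self.violations)


def validate_dataset(data: ObservedDataset) -> ValidationReport:
    """Report dimension mismatches and mask/topology violations.

    Checks: aligned row counts of T, P and A; binary A; no isoform without a
    compatible peptide and no peptide without a compatible isoform; and the
    identifiability requirement that every connected block of the
    isoform-peptide graph has at least as many peptides as isoforms.
    """
    rep = ValidationReport()
    n, r, q = data.n, data.r, data.q
    if data.mask.shape[1] != r:
        rep.violations.append(
            f"mask has {data.mask.shape[1]} peptide columns but P has {r}"
        )
        return rep
    if data.T is not None:
        if data.T.shape[0] != n:
            rep.violations.append(f"T has {data.T.shape[0]} rows but P has {n}")
        if data.T.shape[1] != q:
            rep.violations.append(
                f"T has {data.T.shape[1]} columns but mask has {q} isoforms"
            )
    if data.A is not None:
        if data.A.shape[0] != n:
            rep.violations.append(f"A has length {data.A.shape[0]} but P has {n} rows")
        elif not np.all(np.isin(data.A, (0.0, 1.0))):
            rep.violations.append("A contains values other than 0 and 1")
    row_empty = np.flatnonzero(data.mask.sum(axis=1) == 0)
    for j in row_empty:
        rep.violations.append(f"isoform with no peptide: {data.isoform_ids[j]}")
    col_empty = np.flatnonzero(data.mask.sum(axis=0) == 0)
    for k in col_empty:
        rep.violations.append(f"peptide with no isoform: {data.peptide_ids[k]}")
    if row_empty.size == 0 and col_empty.size == 0:
        from .preprocess import decompose_blocks

        for blk in decompose_blocks(data.mask):
            if len(blk.isoforms) > len(blk.peptides):
                rep.violations.append(
                    f"q>r in block {blk.block_id}: {len(blk.isoforms)} isoforms, "
                    f"{len(blk.peptides)} peptides"
                )
    return rep
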