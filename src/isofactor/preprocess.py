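"""Normalization, isoform grouping, and block decomposition.

Isoforms whose mask rows are bit-identical are indistinguishable from peptide
data and are merged into isoform groups; the grouped mask then decomposes into
connected components (blocks) of the isoform-peptide bipartite graph, each of
which can be estimated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "IsoformGroup",
    "Block",
    "group_isoforms",
    "decompose_blocks",
    "normalize_peptides",
    "normalize_transcripts",
]


@dataclass(frozen=True)
class IsoformGroup:
    group_id: str
    members: tuple[str, ...]
    peptide_support: tuple[int, ...]
    gene_ids: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class Block:
    """One connected component of the isoform-peptide compatibility graph."""

    block_id: int
    isoforms: np.ndarray  # integer row indices into the mask
    peptides: np.ndarray  # integer column indices

    def to_manifest(self) -> dict:
        return {
            "block_id": self.block_id,
            "isoforms": [int(j) for j in self.isoforms],
            "peptides": [int(k) for k in self.peptides],
        }


def group_isoforms(
    mask: np.ndarray, isoform_ids: list[str] | None = None, sep: str = "+"
) -> tuple[np.ndarray, list[IsoformGroup]]:
    """Merge isoforms with identical peptide support into groups.

    Returns the grouped mask (one row per distinct support pattern, ordered by
    first appearance) and the group list. Group ids join the sorted member ids
    with ``sep``; singleton isoforms keep their own id.
    """
    mask = (np.asarray(mask) != 0).astype(np.uint8)
    q = mask.shape[0]
    if isoform_ids is None:
        isoform_ids = [f"iso{j}" for j in range(q)]
    by_pattern: dict[bytes, list[int]] = {}
    order: list[bytes] = []
    for j in range(q):
        key = mask[j].tobytes()
        if key not in by_pattern:
            by_pattern[key] = []
            order.append(key)
        by_pattern[key].append(j)
    if not order:
        return np.zeros((0, mask.shape[1]), dtype=np.uint8), []
    rows, groups = [], []
    for key in order:
        members = by_pattern[key]
        rows.append(mask[members[0]])
        ids = sorted(isoform_ids[j] for j in members)
        groups.append(
            IsoformGroup(
                group_id=sep.join(ids),
                members=tuple(ids),
                peptide_support=tuple(int(k) for k in np.flatnonzero(mask[members[0]])),
            )
        )
    return np.array(rows, dtype=np.uint8), groups


def decompose_blocks(mask: np.ndarray) -> list[Block]:
    """Split the mask into independent blocks (connected components).

    Blocks partition both the isoform and the peptide axis; no peptide in a
    block is compatible with an isoform outside it. Ordering is deterministic:
    blocks sorted by their smallest isoform index, and index arrays sorted
    within each block. Isolated isoforms or peptides (empty rows/columns) form
    their own degenerate blocks so the partition property always holds.
    """
    mask = np.asarray(mask)
    q, r = mask.shape
    g = nx.Graph()
    g.add_nodes_from(("i", j) for j in range(q))
    g.add_nodes_from(("p", k) for k in range(r))
    jj, kk = np.nonzero(mask)
    g.add_edges_from((("i", int(j)), ("p", int(k))) for j, k in zip(jj, kk))
    comps = []
    for comp in nx.connected_components(g):
        isoforms = np.array(sorted(j for kind, j in comp if kind == "i"), dtype=int)
        peptides = np.array(sorted(k for kind, k in comp if kind == "p"), dtype=int)
        key = isoforms[0] if isoforms.size else q + peptides[0]
        comps.append((key, isoforms, peptides))
    comps.sort(key=lambda t: t[0])
    return [
        Block(block_id=i, isoforms=iso, peptides=pep)
        for i, (_, iso, pep) in enumerate(comps)
    ]


def _design_matrix(covariates: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in factors:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == bool:
            dummies = pd.get_dummies(col.astype(str), prefix=name, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(float))
                names.append(str(c))
        else:
            cols.append(col.to_numpy(float))
            names.append(name)
    X = np.column_stack(cols)
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    aliased = []
    for idx in range(1, X.shape[1]):
        reduced = np.delete(X, idx, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            aliased.append(names[idx])
    raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def normalize_peptides(
    raw: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    plex_col: str = "plex",
    model_cols: tuple[str, ...] = ("diagnosis", "age", "pmi"),
    drop_missing: bool = False,
) -> pd.DataFrame:
    """Normalize raw peptide intensities to a batch-adjusted log2 scale.

    Steps: (1) scale every sample's intensities so each sample total equals
    the median per-sample total; (2) log2-transform; (3) fit, per peptide, an
    ordinary least-squares model on plex (TMT batch) plus the biological and
    technical covariates that must be retained (diagnosis, age, postmortem
    interval); (4) subtract only the fitted plex effects, so residual
    variation of biological interest is preserved.

    ``covariates`` is indexed by sample id. With no covariate table (or a
    single plex) steps 3-4 are the identity.
    """
    raw = raw.copy()
    if drop_missing:
        raw = raw.dropna(axis=1)
    if raw.isna().any().any():
        raise ValueError("missing peptide intensities; pass drop_missing=True to drop them")
    values = raw.to_numpy(float)
    if np.any(values <= 0):
        raise ValueError("nonpositive raw peptide intensity; cannot log-transform")
    totals = values.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("sample with nonpositive total intensity")
    scaled = values * (np.median(totals) / totals)[:, None]
    logged = np.log2(scaled)
    if covariates is None:
        return pd.DataFrame(logged, index=raw.index, columns=raw.columns)
    cov = covariates.loc[raw.index]
    if cov[plex_col].astype(str).nunique() <= 1:
        return pd.DataFrame(logged, index=raw.index, columns=raw.columns)
    present = [c for c in model_cols if c in cov.columns]
    X, names = _design_matrix(cov, [plex_col] + present)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, logged, rcond=None)
    plex_idx = [i for i, nm in enumerate(names) if nm.startswith(f"{plex_col}_")]
    adjusted = logged - X[:, plex_idx] @ beta[plex_idx]
    return pd.DataFrame(adjusted, index=raw.index, columns=raw.columns)


def normalize_transcripts(
    counts: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    technical_cols: tuple[str, ...] = (),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Counts-per-million on a log2 scale, optionally adjusting technical covariates.

    CPM = 1e6 * count / library size, then log2(CPM + pseudocount). When
    ``technical_cols`` are given, their (centered) OLS effects are subtracted
    from every transcript, leaving means intact.
    """
    values = counts.to_numpy(float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    libsize = values.sum(axis=1)
    if np.any(libsize <= 0):
        raise ValueError("sample with zero library size")
    logcpm = np.log2(1e6 * values / libsize[:, None] + pseudocount)
    if covariates is not None and technical_cols:
        cov = covariates.loc[counts.index]
        X, names = _design_matrix(cov, list(technical_cols))
        X[:, 1:] = X[:, 1:] - X[:, 1:].mean(axis=0)  # keep transcript means
        _check_full_rank(X, names)
        beta, *_ = np.linalg.lstsq(X, logcpm, rcond=None)
        logcpm = logcpm - X[:, 1:] @ beta[1:]
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)
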