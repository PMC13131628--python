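"""Posterior summarization and significance via the local false sign rate.

The local false sign rate (LFSR) of an effect is the smaller of the posterior
probabilities that the effect is >= 0 or <= 0; small values mean the sign of
the effect is confidently determined. It replaces p-value machinery: no
further multiple-testing adjustment is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "lfsr",
    "lfsr_matrix",
    "detect_differential",
    "consensus",
    "chain_stability_filter",
    "summarize_posterior",
    "DifferentialResult",
]


def lfsr(draws: np.ndarray) -> float:
    """Empirical local false sign rate of a scalar effect.

    min of the fractions of draws >= 0 and <= 0; draws exactly at zero count
    toward both tails (both inequalities are inclusive). Capped at 0.5, the
    no-sign-information value.
    """
    draws = np.asarray(draws, float).ravel()
    if draws.size == 0:
        raise ValueError("lfsr requires at least one draw")
    p_pos = np.mean(draws >= 0)
    p_neg = np.mean(draws <= 0)
    return float(min(p_pos, p_neg, 0.5))


def lfsr_matrix(draws: np.ndarray) -> np.ndarray:
    """Column-wise LFSR of an (S, q) draw matrix."""
    draws = np.asarray(draws, float)
    p_pos = np.mean(draws >= 0, axis=0)
    p_neg = np.mean(draws <= 0, axis=0)
    return np.minimum(np.minimum(p_pos, p_neg), 0.5)


def detect_differential(lfsr_values, ids=None, alpha: float = 0.05) -> set:
    """Isoforms called differentially abundant at LFSR <= alpha."""
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    vals = np.asarray(lfsr_values, float)
    if ids is None:
        ids = list(range(vals.size))
    return {ids[j] for j in np.flatnonzero(vals <= alpha)}


def consensus(per_chain_detections: list[set], gamma: int) -> tuple[set, pd.Series]:
    """Detection frequency across chains and the gamma-consensus set.

    ``gamma`` is the minimum agreement count (inclusive): an isoform enters
    the consensus set iff at least ``gamma`` chains detected it.
    """
    n_chains = len(per_chain_detections)
    if not 1 <= gamma <= max(n_chains, 1):
        raise ValueError(f"gamma must lie in 1..{n_chains}")
    counts: dict = {}
    for det in per_chain_detections:
        for iso in det:
            counts[iso] = counts.get(iso, 0) + 1
    freq = pd.Series(counts, dtype=int).sort_index()
    return set(freq.index[freq >= gamma]), freq


def chain_stability_filter(per_chain_means: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Keep isoforms whose mean abundance is stable across chains.

    ``per_chain_means`` is (chains, q): each entry is one chain's posterior
    mean abundance averaged over samples. An isoform is retained iff the
    sample variance of that quantity over chains falls below ``threshold``.
    """
    m = np.asarray(per_chain_means, float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("chain stability requires >= 2 chains")
    return m.var(axis=0, ddof=1) < threshold


def summarize_posterior(draws: np.ndarray, level: float = 0.95):
    """Mean, SD and equal-tailed credible interval of a draw vector."""
    draws = np.asarray(draws, float).ravel()
    if draws.size < 2:
        raise ValueError("need at least two draws to summarize")
    half = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [half, 1.0 - half])
    return float(draws.mean()), float(draws.std(ddof=1)), (float(lo), float(hi))


@dataclass
class DifferentialResult:
    """Per-isoform differential-abundance summary across chains."""

    table: pd.DataFrame  # isoform_id, post_mean_D, post_sd_D, lfsr, pip, detected, detection_count

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def differential_table(
    chains,
    isoform_ids: list[str],
    alpha: float = 0.05,
) -> DifferentialResult:
    """Build the standard results table from a list of chain draws.

    Point estimates pool draws over chains; the ``lfsr`` column is the
    pooled-draw LFSR while ``detection_count`` counts chains whose own LFSR
    falls at or below alpha (the default, per-chain convention).
    """
    pooled = np.vstack([c.D for c in chains])
    per_chain = np.stack([lfsr_matrix(c.D) for c in chains])
    pooled_lfsr = lfsr_matrix(pooled)
    counts = (per_chain <= alpha).sum(axis=0)
    pip = None
    if chains[0].gamma is not None:
        pip = np.vstack([c.gamma for c in chains]).mean(axis=0)
    tbl = pd.DataFrame(
        {
            "isoform_id": isoform_ids,
            "post_mean_D": pooled.mean(axis=0),
            "post_sd_D": pooled.std(axis=0, ddof=1),
            "lfsr": pooled_lfsr,
            "pip": pip if pip is not None else np.nan,
            "detected": pooled_lfsr <= alpha,
            "detection_count": counts,
        }
    )
    return DifferentialResult(tbl)
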