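"""Transcript-isoform correlation post-analysis.

Given posterior-mean isoform abundances and the matched transcript matrix,
this module computes per-pair Pearson correlations over samples, the exact
analytic null tail of the correlation coefficient, expected tail counts,
variance explained by an eGene (2 f (1-f) b^2 for allele frequency f and
slope b), mapping-ambiguity classification, and an OLS model predicting the
observed correlations from abundance-variation covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PairCorrelationTable",
    "pair_correlations",
    "classify_mapping",
    "null_tail_fraction",
    "expected_tail_count",
    "egene_variance_explained",
    "fit_correlation_model",
    "sample_control_pairs",
]


@dataclass
class PairCorrelationTable:
    table: pd.DataFrame  # isoform_id, r, mapping, tail

    def tail_counts(self) -> pd.Series:
        return self.table["tail"].value_counts()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_histogram(self, ax=None, bins: int = 60):
        """Histogram of pair correlations with the +-0.3 tail bounds marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.table["r"], bins=bins, color="steelblue", edgecolor="none")
        for x in (-0.3, 0.3):
            ax.axvline(x, color="firebrick", linestyle="--", linewidth=1)
        ax.set_xlabel("transcript-isoform Pearson r")
        ax.set_ylabel("pairs")
        return ax


def pair_correlations(
    I_hat: np.ndarray,
    T: np.ndarray,
    isoform_ids: list[str] | None = None,
    mapping: np.ndarray | None = None,
    threshold: float = 0.3,
) -> PairCorrelationTable:
    """Pearson correlation over samples for each matched (transcript, isoform) pair.

    Zero-variance columns give an undefined correlation; those pairs are
    dropped with a warning. Tail flags are strict: ``strong_positive`` iff
    r > threshold, ``strong_negative`` iff r < -threshold.
    """
    I_hat = np.asarray(I_hat, float)
    T = np.asarray(T, float)
    if I_hat.shape != T.shape:
        raise ValueError("I_hat and T must have matching shapes")
    n, q = I_hat.shape
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if isoform_ids is None:
        isoform_ids = [f"iso{j}" for j in range(q)]
    ic = I_hat - I_hat.mean(axis=0)
    tc = T - T.mean(axis=0)
    si = np.sqrt((ic**2).sum(axis=0))
    st = np.sqrt((tc**2).sum(axis=0))
    ok = (si > 0) & (st > 0)
    if not np.all(ok):
        dropped = [isoform_ids[j] for j in np.flatnonzero(~ok)]
        warnings.warn(f"dropping zero-variance pairs: {dropped}")
    r = np.full(q, np.nan)
    r[ok] = (ic[:, ok] * tc[:, ok]).sum(axis=0) / (si[ok] * st[ok])
    tail = np.where(r > threshold, "strong_positive", np.where(r < -threshold, "strong_negative", "neutral"))
    tbl = pd.DataFrame(
        {
            "isoform_id": isoform_ids,
            "r": r,
            "mapping": mapping if mapping is not None else "unknown",
            "tail": tail,
        }
    )
    return PairCorrelationTable(tbl[ok].reset_index(drop=True))


def classify_mapping(mask: np.ndarray) -> np.ndarray:
    """Label each isoform 'unique' or 'ambiguous' from the detectability mask.

    An isoform is ambiguous iff any of its compatible peptides is compatible
    with two or more isoforms.
    """
    mask = (np.asarray(mask) != 0).astype(int)
    shared_pep = mask.sum(axis=0) >= 2
    ambiguous = (mask[:, shared_pep].sum(axis=1) > 0) if shared_pep.any() else np.zeros(mask.shape[0], bool)
    return np.where(ambiguous, "ambiguous", "unique")


def null_tail_fraction(n: int, threshold: float) -> float:
    """P(|r| > threshold) for a sample correlation under zero true correlation.

    Uses the exact t-transform of the null density: t = r sqrt(n-2)/sqrt(1-r^2)
    follows a Student t with n-2 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    t = threshold * np.sqrt(n - 2) / np.sqrt(1.0 - threshold**2)
    return float(2.0 * stats.t.sf(t, df=n - 2))


def expected_tail_count(n_pairs: int, n: int, threshold: float) -> float:
    """Expected number of null pairs beyond the bound in each tail."""
    return n_pairs * null_tail_fraction(n, threshold) / 2.0


def egene_variance_explained(f: float, b: float) -> float:
    """Variance in expression explained by an eGene variant: 2 f (1-f) b^2."""
    f_arr = np.asarray(f, float)
    if np.any((f_arr < 0) | (f_arr > 1)):
        raise ValueError("allele frequency f must lie in [0, 1]")
    return 2.0 * f_arr * (1.0 - f_arr) * np.asarray(b, float) ** 2


def fit_correlation_model(outcome, predictors: pd.DataFrame):
    """OLS of observed pair correlations on abundance-variation predictors.

    Typical predictors: case-control mean difference of isoform and of
    transcript abundances, the age coefficient for each, and the eGene
    variance explained. Returns the fitted statsmodels results (coefficients,
    R^2, per-predictor t statistics). Complete rows only; collinear
    predictors raise with the aliased set named.
    """
    y = np.asarray(outcome, float)
    X = predictors.astype(float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if y.size < X.shape[1] + 1:
        raise ValueError("too few complete rows to fit the correlation model")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        aliased = []
        for col in X.columns:
            reduced = design.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(reduced) == rank:
                aliased.append(col)
        raise ValueError(f"collinear predictors: {aliased}")
    return sm.OLS(y, design).fit()


def sample_control_pairs(
    table: pd.DataFrame,
    n: int,
    rng: np.random.Generator,
    max_abs_r: float = 0.05,
) -> pd.DataFrame:
    """Seeded draw (without replacement) of near-zero-correlation control pairs."""
    pool = table[table["r"].abs() < max_abs_r]
    if len(pool) < n:
        raise ValueError(f"only {len(pool)} pairs with |r| < {max_abs_r}, need {n}")
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)
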