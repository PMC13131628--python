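"""Model and Results objects tying the pipeline together.

`IsoformAbundanceModel` holds the observed data (after optional isoform
grouping), the prior configuration, and the block decomposition; `fit()`
runs the multi-chain Gibbs sampler and returns an
`IsoformAbundanceResults` carrying posterior draws, effect estimates with
uncertainties, LFSR-based differential calls, chain-consensus diagnostics,
and the transcript-isoform correlation post-analysis.
"""

from __future__ import annotations

import hashlib
import json
import time

import numpy as np
import pandas as pd

from . import inference, postanalysis
from .data import (
    ObservedDataset,
    PriorConfig,
    truncation_bounds_all,
    validate_dataset,
)
from .preprocess import decompose_blocks, group_isoforms
from .sampler import ChainConfig, PosteriorDraws, run_chains

__all__ = ["IsoformAbundanceModel", "IsoformAbundanceResults"]


class IsoformAbundanceModel:
    """Bayesian supervised factor analysis of peptide abundances.

    Parameters
    ----------
    P : (n, r) array
        Log-scale peptide abundances.
    mask : (q, r) array
        Binary detectability mask (isoforms x peptides).
    T : (n, q) array, optional
        Log-scale transcript abundances; when absent the latent layer is
        I ~ N(I0 + A D, 1).
    A : (n,) array, optional
        Binary condition labels; when absent no differential effect is
        estimated.
    prior : PriorConfig, optional
        Hyperparameters; defaults are weakly informative unit variances.
    group : bool
        Merge isoforms with identical peptide support into groups (they are
        only jointly estimable). A grouped isoform's transcript column is the
        mean of its members'.
    bounds : str or (q, 2) array
        Truncation-bound policy for the detectability prior: "data" (strict
        ratio-of-column-means), "data-abs" (ratios of absolute means, defined
        on signed working scales), or explicit per-isoform bounds.
    """

    def __init__(
        self,
        P,
        mask,
        T=None,
        A=None,
        *,
        sample_ids=None,
        isoform_ids=None,
        peptide_ids=None,
        prior: PriorConfig | None = None,
        group: bool = True,
        bounds="data",
    ) -> None:
        raw = ObservedDataset(
            P=np.asarray(P, float),
            mask=np.asarray(mask),
            T=None if T is None else np.asarray(T, float),
            A=None if A is None else np.asarray(A, float),
            sample_ids=list(sample_ids) if sample_ids is not None else [],
            isoform_ids=list(isoform_ids) if isoform_ids is not None else [],
            peptide_ids=list(peptide_ids) if peptide_ids is not None else [],
        )
        self.groups = None
        if group:
            gmask, groups = group_isoforms(raw.mask, raw.isoform_ids)
            self.groups = groups
            gT = None
            if raw.T is not None:
                id_pos = {iso: j for j, iso in enumerate(raw.isoform_ids)}
                cols = [
                    raw.T[:, [id_pos[m] for m in g.members]].mean(axis=1) for g in groups
                ]
                gT = np.column_stack(cols)
            self.data = ObservedDataset(
                P=raw.P,
                mask=gmask,
                T=gT,
                A=raw.A,
                sample_ids=raw.sample_ids,
                isoform_ids=[g.group_id for g in groups],
                peptide_ids=raw.peptide_ids,
            )
        else:
            self.data = raw
        self.prior = (prior or PriorConfig()).broadcast(self.data.q)
        if isinstance(bounds, str):
            self.bounds_policy = bounds
            self.bounds = truncation_bounds_all(self.data.P, self.data.mask, policy=bounds)
        else:
            self.bounds_policy = "explicit"
            self.bounds = np.asarray(bounds, float).reshape(self.data.q, 2)
        self.blocks = decompose_blocks(self.data.mask)

    @classmethod
    def from_dataframes(cls, P, mask, T=None, A=None, **kwargs) -> "IsoformAbundanceModel":
        ds = ObservedDataset.from_frames(P=P, mask=mask, T=T, A=A)
        return cls(
            P=ds.P,
            mask=ds.mask,
            T=ds.T,
            A=ds.A,
            sample_ids=ds.sample_ids,
            isoform_ids=ds.isoform_ids,
            peptide_ids=ds.peptide_ids,
            **kwargs,
        )

    @classmethod
    def from_tsv(cls, peptides, mask, transcripts=None, condition=None, **kwargs):
        ds = ObservedDataset.from_tsv(peptides, mask, transcripts, condition)
        return cls(
            P=ds.P,
            mask=ds.mask,
            T=ds.T,
            A=ds.A,
            sample_ids=ds.sample_ids,
            isoform_ids=ds.isoform_ids,
            peptide_ids=ds.peptide_ids,
            **kwargs,
        )

    def validate(self):
        return validate_dataset(self.data)

    def fit(
        self,
        n_iter: int = 3000,
        burn_in: int = 2000,
        n_chains: int = 10,
        seed: int = 0,
        thinning: int = 1,
        store_I: str = "mean",
        strict: bool = True,
    ) -> "IsoformAbundanceResults":
        """Run the Gibbs sampler and summarize the posterior.

        ``strict`` aborts on any structural validation violation; with
        ``strict=False`` violations are attached to the results as warnings
        (identifiability violations degrade estimates but the sampler still
        runs, regularized by the priors).
        """
        report = self.validate()
        if strict and not report.ok:
            raise ValueError(f"dataset failed validation:\n{report}")
        cfg = ChainConfig(
            n_iter=n_iter, burn_in=burn_in, n_chains=n_chains, base_seed=seed, thinning=thinning
        )
        t0 = time.perf_counter()
        chains = run_chains(
            self.data,
            self.prior,
            cfg,
            bounds=self.bounds,
            blocks=self.blocks,
            store_I=store_I,
        )
        elapsed = time.perf_counter() - t0
        return IsoformAbundanceResults(
            self, chains, cfg, validation=report, elapsed_seconds=elapsed
        )


class IsoformAbundanceResults:
    """Posterior summaries and diagnostics of a fitted model."""

    def __init__(self, model, chains: list[PosteriorDraws], config: ChainConfig, validation=None, elapsed_seconds=0.0):
        self.model = model
        self.chains = chains
        self.config = config
        self.validation = validation
        self.elapsed_seconds = elapsed_seconds
        self._pooled_D = np.vstack([c.D for c in chains])

    # -- effect estimates --------------------------------------------------

    @property
    def d_mean(self) -> np.ndarray:
        """Posterior mean condition effect per isoform (draws pooled over chains)."""
        return self._pooled_D.mean(axis=0)

    @property
    def d_sd(self) -> np.ndarray:
        return self._pooled_D.std(axis=0, ddof=1)

    @property
    def w_mean(self) -> np.ndarray:
        return np.vstack([c.W for c in self.chains]).mean(axis=0)

    @property
    def lfsr_(self) -> np.ndarray:
        """Pooled-draw LFSR per isoform."""
        return inference.lfsr_matrix(self._pooled_D)

    @property
    def lfsr_by_chain(self) -> np.ndarray:
        """(chains, q) matrix of per-chain LFSRs."""
        return np.stack([inference.lfsr_matrix(c.D) for c in self.chains])

    @property
    def pip_(self) -> np.ndarray | None:
        """Posterior inclusion probabilities (spike-and-slab prior only)."""
        if self.chains[0].gamma is None:
            return None
        return np.vstack([c.gamma for c in self.chains]).mean(axis=0)

    @property
    def isoform_abundance(self) -> np.ndarray:
        """(n, q) posterior-mean latent isoform abundances, averaged over chains."""
        return np.mean([c.I_mean for c in self.chains], axis=0)

    @property
    def isoform_ids(self) -> list[str]:
        return self.model.data.isoform_ids

    # -- detection ---------------------------------------------------------

    def detect(self, alpha: float = 0.05) -> set:
        """Isoforms differential at pooled LFSR <= alpha."""
        return inference.detect_differential(self.lfsr_, self.isoform_ids, alpha)

    def detect_by_chain(self, alpha: float = 0.05) -> list[set]:
        return [
            inference.detect_differential(row, self.isoform_ids, alpha)
            for row in self.lfsr_by_chain
        ]

    def detection_count(self, alpha: float = 0.05) -> np.ndarray:
        return (self.lfsr_by_chain <= alpha).sum(axis=0)

    def consensus(self, gamma: int, alpha: float = 0.05):
        """Isoforms detected by at least ``gamma`` chains, plus the frequency table."""
        return inference.consensus(self.detect_by_chain(alpha), gamma)

    def stable_isoforms(self, threshold: float = 1.0) -> np.ndarray:
        """Chain-stability keep mask: variance over chains of the per-chain
        mean abundance (mean over samples) below ``threshold``."""
        per_chain = np.stack([c.I_mean.mean(axis=0) for c in self.chains])
        return inference.chain_stability_filter(per_chain, threshold)

    # -- tables / output ---------------------------------------------------

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-isoform table: effect estimate, SD, LFSR, PIP, detection."""
        return inference.differential_table(self.chains, self.isoform_ids, alpha).table

    def pair_correlations(self, threshold: float = 0.3, stability_threshold: float | None = None):
        """Transcript-isoform correlation table from the fitted abundances."""
        if self.model.data.T is None:
            raise ValueError("pair correlations require transcript data")
        keep = np.ones(self.model.data.q, bool)
        if stability_threshold is not None and len(self.chains) >= 2:
            keep = self.stable_isoforms(stability_threshold)
        mapping = postanalysis.classify_mapping(self.model.data.mask)
        return postanalysis.pair_correlations(
            self.isoform_abundance[:, keep],
            self.model.data.T[:, keep],
            [i for i, k in zip(self.isoform_ids, keep) if k],
            mapping=mapping[keep],
            threshold=threshold,
        )

    def manifest(self) -> dict:
        cfg = {
            "n_iter": self.config.n_iter,
            "burn_in": self.config.burn_in,
            "n_chains": self.config.n_chains,
            "base_seed": self.config.base_seed,
            "thinning": self.config.thinning,
            "bounds_policy": self.model.bounds_policy,
            "prior_family": self.model.prior.prior_family,
        }
        digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()
        return {
            "config": cfg,
            "config_hash": digest,
            "seeds": [c.seed for c in self.chains],
            "n_blocks": len(self.model.blocks),
            "elapsed_seconds": round(self.elapsed_seconds, 3),
            "per_chain_draws": [c.n_draws for c in self.chains],
        }

    def save(self, outdir, alpha: float = 0.05) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.summary(alpha).to_csv(outdir / "differential.tsv", sep="\t", index=False)
        pd.DataFrame(
            self.isoform_abundance,
            index=self.model.data.sample_ids,
            columns=self.isoform_ids,
        ).to_csv(outdir / "isoform_abundance.tsv", sep="\t")
        for chain in self.chains:
            chain.save(outdir / "draws")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))

    def plot_detection_frequency(self, alpha: float = 0.05, ax=None):
        """Bar chart of how many isoforms hit each cross-chain detection count."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        counts = self.detection_count(alpha)
        levels = np.arange(len(self.chains) + 1)
        ax.bar(levels, [(counts == c).sum() for c in levels], color="slategray")
        ax.set_xlabel(f"chains detecting the isoform (LFSR <= {alpha})")
        ax.set_ylabel("isoforms")
        return ax

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        q = self.model.data.q
        return (
            f"<IsoformAbundanceResults: {q} isoforms, {len(self.chains)} chains, "
            f"{self.chains[0].n_draws} draws/chain>"
        )
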