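"""Bayesian colocalization of a GWAS and an eQTL signal in a region.

Per-variant evidence is the Wakefield approximate Bayes factor computed
from the effect estimate and its standard error under a normal prior on
the true effect.  With a single causal variant per trait assumed, the five
hypotheses (H0 no association, H1/H2 association with one trait only,
H3 two distinct causal variants, H4 one shared causal variant) have
posterior weights built from sums of per-variant (products of) Bayes
factors and the priors p1, p2, p12; all sums are done in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from cavspipe.gwas import wakefield_log_abf

__all__ = ["AbfTrack", "ColocResult", "coloc_abf", "colocalization_call"]

#: default prior effect standard deviations by trait type
PRIOR_SD = {"binary": 0.2, "quantitative": 0.15}


@dataclass
class AbfTrack:
    """Per-variant log approximate Bayes factors for one trait."""

    variant_ids: list[str]
    log_abf: np.ndarray
    trait_type: str = "quantitative"

    @classmethod
    def from_summary(
        cls,
        records: pd.DataFrame,
        trait_type: str,
        beta_col: str = "beta",
        se_col: str = "se",
        prior_sd: float | None = None,
    ) -> "AbfTrack":
        if prior_sd is None:
            prior_sd = PRIOR_SD[trait_type]
        labf = wakefield_log_abf(
            records[beta_col].to_numpy(dtype=float),
            records[se_col].to_numpy(dtype=float),
            prior_sd,
        )
        return cls(list(records["variant_id"]), labf, trait_type)


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    gene_id: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    p1: float
    p2: float
    p12: float

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def colocalized(self) -> bool:
        return colocalization_call(self)


def _logdiff(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b, -inf when the difference vanishes."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    track1: AbfTrack,
    track2: AbfTrack,
    gene_id: str = "",
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Five-hypothesis colocalization posterior from two ABF tracks.

    Tracks are intersected on variant id; an empty intersection is an
    error.  Unnormalized log weights: H0 = 0; H1 = log p1 + lse(l1);
    H2 = log p2 + lse(l2); H3 = log p1 p2 + log(sum_{i != j} e^{l1_i+l2_j});
    H4 = log p12 + lse(l1 + l2); normalized by log-sum-exp.
    """
    common = [v for v in track1.variant_ids if v in set(track2.variant_ids)]
    if not common:
        raise ValueError("tracks share no variants")
    l1 = pd.Series(track1.log_abf, index=track1.variant_ids).loc[common].to_numpy()
    l2 = pd.Series(track2.log_abf, index=track2.variant_ids).loc[common].to_numpy()
    lse1 = float(logsumexp(l1))
    lse2 = float(logsumexp(l2))
    lse12 = float(logsumexp(l1 + l2))
    lh = np.array(
        [
            0.0,
            np.log(p1) + lse1,
            np.log(p2) + lse2,
            np.log(p1) + np.log(p2) + _logdiff(lse1 + lse2, lse12),
            np.log(p12) + lse12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(
        gene_id=gene_id,
        pp0=float(pp[0]),
        pp1=float(pp[1]),
        pp2=float(pp[2]),
        pp3=float(pp[3]),
        pp4=float(pp[4]),
        n_variants=len(common),
        p1=p1,
        p2=p2,
        p12=p12,
    )


def colocalization_call(result: ColocResult, pp4_threshold: float = 0.75) -> bool:
    """Colocalized when PP4 strictly exceeds the threshold."""
    return bool(result.pp4 > pp4_threshold)
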