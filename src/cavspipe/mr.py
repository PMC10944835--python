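"""Two-sample Mendelian randomization of valve expression on disease risk.

Instruments are cis variants strongly associated with a gene's expression
(exposure p < 1e-4), LD-clumped at r² < 0.1 and individually strong
(F = (bx/bx_se)² > 15); genes need at least three surviving instruments.
Estimators: inverse-variance-weighted (fixed-effect) regression of outcome
effects on exposure effects through the origin, MR-Egger weighted least
squares with an intercept (directional-pleiotropy test), and the weighted
median of the per-instrument ratio estimates with a parametric-bootstrap
standard error.  Cochran's Q on the IVW fit screens out genes with
heterogeneous instruments (Q p < 0.01); candidates must pass FDR-adjusted
IVW and weighted-median significance with a non-significant Egger
intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["Instrument", "MrResult", "select_instruments", "mr_estimates", "gene_screen"]


@dataclass(frozen=True)
class Instrument:
    """One harmonized instrument: effects on exposure (expression SD per
    dose) and outcome (log-OR per dose), same effect allele."""

    variant_id: str
    bx: float
    bx_se: float
    by: float
    by_se: float

    @property
    def f_statistic(self) -> float:
        return (self.bx / self.bx_se) ** 2


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    ld_variant_ids: list[str] | None = None,
    p_max: float = 1e-4,
    r2_max: float = 0.1,
    min_instruments: int = 3,
    f_min: float = 15.0,
) -> list[Instrument] | None:
    """Instrument selection for one gene.

    ``exposure`` needs columns variant_id, slope, slope_se, p_nominal;
    ``outcome`` needs variant_id, beta, se (already harmonized to the same
    effect allele; rows absent from the outcome are dropped).  Greedy
    clumping by ascending exposure p keeps a variant only when its r² with
    every retained variant is below ``r2_max``.  Returns None (gene
    skipped) when fewer than ``min_instruments`` survive.
    """
    if isinstance(ld, pd.DataFrame):
        ld_ids, ld_mat = list(ld.index), ld.to_numpy()
    else:
        if ld_variant_ids is None:
            raise ValueError("ld_variant_ids required when ld is an array")
        ld_ids, ld_mat = list(ld_variant_ids), np.asarray(ld)
    pos = {v: i for i, v in enumerate(ld_ids)}

    cand = exposure[exposure["p_nominal"] < p_max].copy()
    cand["f_stat"] = (cand["slope"] / cand["slope_se"]) ** 2
    cand = cand[cand["f_stat"] > f_min]
    out = outcome.set_index("variant_id")
    cand = cand[cand["variant_id"].isin(out.index)]
    cand = cand.sort_values(["p_nominal", "variant_id"], kind="mergesort")

    kept: list[str] = []
    for vid in cand["variant_id"]:
        i = pos.get(vid)
        independent = all(
            i is None or pos.get(k) is None or ld_mat[i, pos[k]] < r2_max for k in kept
        )
        if independent:
            kept.append(vid)
    if len(kept) < min_instruments:
        return None
    cand = cand.set_index("variant_id")
    return [
        Instrument(
            variant_id=v,
            bx=float(cand.loc[v, "slope"]),
            bx_se=float(cand.loc[v, "slope_se"]),
            by=float(out.loc[v, "beta"]),
            by_se=float(out.loc[v, "se"]),
        )
        for v in kept
    ]


@dataclass
class MrResult:
    """All MR estimators and diagnostics for one gene."""

    gene_id: str
    n_instruments: int
    ivw_estimate: float
    ivw_se: float
    ivw_p: float
    # second-order weights 1/(by_se^2 + theta^2 bx_se^2): the correct CI
    # when exposure effects carry non-negligible measurement error
    ivw_delta_estimate: float
    ivw_delta_se: float
    ivw_delta_p: float
    egger_slope: float
    egger_slope_se: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_p: float
    wm_estimate: float
    wm_se: float
    wm_p: float
    q_stat: float
    q_p: float
    extra: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("IVW", self.ivw_estimate, self.ivw_se, self.ivw_p),
            ("Egger slope", self.egger_slope, self.egger_slope_se, np.nan),
            (
                "Egger intercept",
                self.egger_intercept,
                self.egger_intercept_se,
                self.egger_intercept_p,
            ),
            ("Weighted median", self.wm_estimate, self.wm_se, self.wm_p),
        ]
        df = pd.DataFrame(rows, columns=["estimator", "estimate", "se", "p"])
        df.attrs["q_stat"] = self.q_stat
        df.attrs["q_p"] = self.q_p
        return df


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (Bowden et al. construction)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5) - 1)
    return float(r[k] + (r[k + 1] - r[k]) * (0.5 - s[k]) / (s[k + 1] - s[k]))


def mr_estimates(
    instruments: list[Instrument],
    gene_id: str = "",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> MrResult:
    """IVW, Egger and weighted-median estimates from >= 3 instruments."""
    if len(instruments) < 3:
        raise ValueError("need at least 3 instruments")
    bx = np.array([i.bx for i in instruments])
    bx_se = np.array([i.bx_se for i in instruments])
    by = np.array([i.by for i in instruments])
    by_se = np.array([i.by_se for i in instruments])
    w = 1.0 / by_se**2
    k = len(bx)

    # IVW: weighted regression through the origin, fixed-effect SE
    ivw = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    ivw_se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    ivw_p = float(2.0 * stats.norm.sf(abs(ivw / ivw_se)))

    # one iteration of second-order weights: propagates exposure-side
    # measurement error into the weights and the standard error
    w2 = 1.0 / (by_se**2 + ivw**2 * bx_se**2)
    ivw2 = float(np.sum(w2 * bx * by) / np.sum(w2 * bx**2))
    ivw2_se = float(np.sqrt(1.0 / np.sum(w2 * bx**2)))
    ivw2_p = float(2.0 * stats.norm.sf(abs(ivw2 / ivw2_se)))

    # Cochran's Q on the IVW fit
    q = float(np.sum(w * (by - ivw * bx) ** 2))
    q_p = float(stats.chi2.sf(q, k - 1))

    # Egger: WLS with intercept; t-tests with k-2 df
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    egger_intercept, egger_slope = fit.params
    int_se, slope_se = fit.bse
    if int_se > 0:
        egger_intercept_p = float(2.0 * stats.t.sf(abs(egger_intercept / int_se), k - 2))
    else:
        egger_intercept_p = 1.0

    # Weighted median of ratio estimates, inverse-variance weights
    usable = bx != 0.0
    ratios = by[usable] / bx[usable]
    ratio_se = by_se[usable] / np.abs(bx[usable])
    wm_w = 1.0 / ratio_se**2
    wm = _weighted_median(ratios, wm_w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        bxb = rng.normal(bx[usable], bx_se[usable])
        byb = rng.normal(by[usable], by_se[usable])
        ok = bxb != 0.0
        if not ok.any():
            boots[b] = wm
            continue
        rb = byb[ok] / bxb[ok]
        sb = by_se[usable][ok] / np.abs(bxb[ok])
        boots[b] = _weighted_median(rb, 1.0 / sb**2)
    wm_se = float(boots.std(ddof=1))
    wm_p = float(2.0 * stats.norm.sf(abs(wm / wm_se))) if wm_se > 0 else (0.0 if wm != 0 else 1.0)

    return MrResult(
        gene_id=gene_id,
        n_instruments=k,
        ivw_estimate=ivw,
        ivw_se=ivw_se,
        ivw_p=ivw_p,
        ivw_delta_estimate=ivw2,
        ivw_delta_se=ivw2_se,
        ivw_delta_p=ivw2_p,
        egger_slope=float(egger_slope),
        egger_slope_se=float(slope_se),
        egger_intercept=float(egger_intercept),
        egger_intercept_se=float(int_se),
        egger_intercept_p=egger_intercept_p,
        wm_estimate=wm,
        wm_se=wm_se,
        wm_p=wm_p,
        q_stat=q,
        q_p=q_p,
    )


def gene_screen(
    results: list[MrResult] | pd.DataFrame,
    fdr: float = 0.05,
    q_alpha: float = 0.01,
    intercept_alpha: float = 0.05,
) -> pd.DataFrame:
    """Gene-level MR decision rule.

    Genes with heterogeneous instruments (Q p < ``q_alpha``) are removed
    before FDR adjustment; IVW and weighted-median p-values are BH-adjusted
    separately across the remaining genes; a candidate passes both at
    ``fdr`` with Egger intercept p > ``intercept_alpha``.  The unadjusted
    feature rule (IVW p < 0.05, WM p < 0.05 and Q p > 0.01) is also
    reported for the prioritization ledger.
    """
    if isinstance(results, list):
        df = pd.DataFrame([r.__dict__ for r in results]).drop(columns=["extra"], errors="ignore")
    else:
        df = results.copy()
    df["heterogeneous"] = df["q_p"] < q_alpha
    df["candidate"] = False
    df["ivw_q"] = np.nan
    df["wm_q"] = np.nan
    keep = ~df["heterogeneous"]
    if keep.any():
        rej_i, q_i, _, _ = multipletests(df.loc[keep, "ivw_p"], alpha=fdr, method="fdr_bh")
        rej_w, q_w, _, _ = multipletests(df.loc[keep, "wm_p"], alpha=fdr, method="fdr_bh")
        df.loc[keep, "ivw_q"] = q_i
        df.loc[keep, "wm_q"] = q_w
        df.loc[keep, "candidate"] = (
            rej_i & rej_w & (df.loc[keep, "egger_intercept_p"] > intercept_alpha)
        )
    df["mr_feature"] = (df["ivw_p"] < 0.05) & (df["wm_p"] < 0.05) & (df["q_p"] > q_alpha)
    return df
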