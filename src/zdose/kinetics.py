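"""Telegraph-model burst-kinetics inference from allele-resolved UMI counts.

At steady state of the two-state telegraph model (gene switches ON/OFF at
rates k_on/k_off, synthesises at rate k_syn while ON, mRNA degrades at rate
1), snapshot counts follow a Poisson mixture over a Beta-distributed ON
fraction:

    P(n) = integral_0^1 Pois(n; k_syn * x) * Beta(x; k_on, k_off) dx

The integral is evaluated by fixed-order Gauss-Jacobi quadrature with the
Beta(k_on, k_off) weight, accumulated in log space. Maximum-likelihood fits
start from a closed-form method-of-moments estimate with deterministic grid
fallbacks, optimised by bounded quasi-Newton in log10-parameter space.

Burst frequency is k_on and burst size k_syn/k_off, both in units of the
mRNA degradation rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, roots_jacobi
from scipy.stats import mannwhitneyu

from .types import ALLELES, TelegraphFit, TelegraphParams

log = logging.getLogger(__name__)

QUAD_ORDER = 64
#: log10 bounds for (k_on, k_off, k_syn)
BOUNDS_LOG10 = ((-3.0, 3.0), (-3.0, 3.0), (-2.0, 4.0))
MIN_CELLS = 50
LOG2 = np.log(2.0)


def _quad_nodes(k_on: float, k_off: float, order: int):
    """Gauss-Jacobi nodes/weights for the Beta(k_on, k_off) weight on [0, 1]."""
    t, w = roots_jacobi(order, k_off - 1.0, k_on - 1.0)
    x = 0.5 * (t + 1.0)
    log_w = np.log(w) + (1.0 - k_on - k_off) * LOG2 - betaln(k_on, k_off)
    return x, log_w


def beta_poisson_logpmf(
    n, params: TelegraphParams, order: int = QUAD_ORDER, _log_fact=None
) -> np.ndarray:
    """Log-probability of observing ``n`` mRNA copies under the telegraph model.

    Vectorised over ``n``. ``_log_fact`` may carry precomputed gammaln(n+1)
    to avoid recomputation inside optimisation loops.
    """
    k_on, k_off, k_syn = params
    arr = np.asarray([k_on, k_off, k_syn], dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"telegraph rates must be finite and > 0, got {params}")
    n = np.atleast_1d(np.asarray(n))
    if _log_fact is None:
        _log_fact = gammaln(n + 1.0)
    x, log_w = _quad_nodes(k_on, k_off, order)
    lam = np.maximum(k_syn * x, 1e-300)
    # log Pois(n; lam) per (count, node) + node log-weight
    m = np.outer(n, np.log(lam))
    m -= lam[None, :]
    m -= _log_fact[:, None]
    m += log_w[None, :]
    mx = m.max(axis=1)
    out = mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))
    if np.any(np.isnan(out)):
        raise FloatingPointError(f"NaN in beta-Poisson pmf at params {params}")
    return out


def beta_poisson_pmf(n, params: TelegraphParams, order: int = QUAD_ORDER) -> np.ndarray:
    """P(n) of the stationary telegraph (beta-Poisson) law; values in [0, 1].

    The k_syn -> 0 boundary degenerates to a point mass at zero and is
    handled explicitly.
    """
    k_on, k_off, k_syn = params
    if k_syn == 0:
        n = np.atleast_1d(np.asarray(n))
        return (n == 0).astype(float)
    p = np.exp(beta_poisson_logpmf(n, params, order=order))
    return np.clip(p, 0.0, 1.0)


def support_bound(params: TelegraphParams, tail: float = 1e-8) -> int:
    """Upper count N* with P(n > N*) < ``tail``: the 1 - tail Poisson quantile
    at the maximal rate k_syn (conditional rates never exceed k_syn)."""
    from scipy.stats import poisson

    return int(poisson.ppf(1.0 - tail, params.k_syn)) + 1


@dataclass
class MomentsResult:
    params: TelegraphParams | None
    ok: bool
    reason: str = ""


def moments_estimator(counts) -> MomentsResult:
    """Closed-form method-of-moments estimate from factorial moments.

    With f_k = E[n(n-1)...(n-k+1)] = k_syn^k * prod_j (k_on+j)/(k_on+k_off+j),
    the ratios r1 = f1, r2 = f2/f1, r3 = f3/f2 invert to k_on, k_off, k_syn.
    Fails (rather than returning spurious estimates) when the empirical
    moments are inconsistent with the model, e.g. sub-Poisson variance.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0 or np.all(x == 0):
        return MomentsResult(None, False, "all-zero or empty input")
    if np.var(x) <= 0:
        return MomentsResult(None, False, "zero variance")
    # identifiability gate: a dispersion index indistinguishable from 1
    # (Poisson) at ~3 sigma cannot pin down k_on/k_off
    phi = np.var(x) / np.mean(x)
    if phi - 1.0 < 3.0 * np.sqrt(2.0 / x.size):
        return MomentsResult(None, False, "dispersion indistinguishable from Poisson")
    f1 = x.mean()
    f2 = (x * (x - 1)).mean()
    f3 = (x * (x - 1) * (x - 2)).mean()
    if f1 <= 0 or f2 <= 0 or f3 <= 0:
        return MomentsResult(None, False, "non-positive factorial moment")
    r1, r2, r3 = f1, f2 / f1, f3 / f2
    denom_on = r1 * r2 - 2 * r1 * r3 + r2 * r3
    denom_syn = r1 - 2 * r2 + r3
    if denom_on == 0 or denom_syn == 0:
        return MomentsResult(None, False, "degenerate moment ratios")
    k_on = 2 * r1 * (r3 - r2) / denom_on
    k_off = 2 * (r3 - r2) * (r1 - r3) * (r2 - r1) / (denom_on * denom_syn)
    k_syn = (-r1 * r2 + 2 * r1 * r3 - r2 * r3) / denom_syn
    est = np.array([k_on, k_off, k_syn])
    if not np.all(np.isfinite(est)) or np.any(est <= 0):
        return MomentsResult(None, False, "inconsistent moments (estimates non-positive)")
    return MomentsResult(TelegraphParams(k_on, k_off, k_syn), True)


def _near_bounds(theta: np.ndarray, rel: float = 0.01) -> bool:
    """True when any parameter is within ``rel`` (multiplicatively) of a bound."""
    margin = np.log10(1.0 + rel)
    for val, (lo, hi) in zip(theta, BOUNDS_LOG10):
        if val <= lo + margin or val >= hi - margin:
            return True
    return False


def _grid_starts(counts: np.ndarray) -> list:
    """Three deterministic fallback starts spanning bursty-to-frequent regimes."""
    m = max(counts.mean(), 0.1)
    return [
        np.log10([0.3, 3.0, max(10.0 * m, 1.0)]),
        np.log10([1.0, 10.0, max(11.0 * m, 1.0)]),
        np.log10([0.05, 1.0, max(21.0 * m, 1.0)]),
    ]


def fit_telegraph(
    counts,
    gene_id: str = "",
    allele: str = "",
    min_cells: int = MIN_CELLS,
    order: int = QUAD_ORDER,
) -> TelegraphFit:
    """Maximum-likelihood telegraph fit for one gene-allele count vector.

    The moment start is optimised first; the deterministic grid starts are
    added only when it does not converge cleanly, and the best optimum is
    returned. The returned log-likelihood never falls below the value at the
    start point (the optimiser result is discarded if worse). Parameters
    within 1% of a box bound are flagged ``boundary``.
    """
    counts = np.asarray(counts)
    counts = counts[~pd.isna(counts)].astype(np.int64)
    n_used = counts.size
    if n_used < min_cells:
        return TelegraphFit(gene_id, allele, None, np.nan, n_used, "insufficient_cells")
    if np.all(counts == 0) or np.var(counts) == 0:
        # likelihood flat in k_on/k_off: unidentifiable
        return TelegraphFit(gene_id, allele, None, np.nan, n_used, "failed")

    uniq, mult = np.unique(counts, return_counts=True)
    log_fact = gammaln(uniq + 1.0)
    mult = mult.astype(float)

    def nll(theta: np.ndarray) -> float:
        p = TelegraphParams(*(10.0 ** theta))
        try:
            lp = beta_poisson_logpmf(uniq, p, order=order, _log_fact=log_fact)
        except FloatingPointError:
            return 1e12
        if not np.all(np.isfinite(lp)):
            return 1e12
        return -float(mult @ lp)

    starts = []
    mom = moments_estimator(counts)
    if mom.ok:
        t0 = np.clip(
            np.log10(np.asarray(mom.params)),
            [b[0] for b in BOUNDS_LOG10],
            [b[1] for b in BOUNDS_LOG10],
        )
        starts.append(t0)
    else:
        starts.extend(_grid_starts(counts))

    best_theta, best_nll, best_ok = None, np.inf, False
    tried_grid = not mom.ok
    while starts:
        x0 = starts.pop(0)
        nll0 = nll(x0)
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=BOUNDS_LOG10, options={"maxiter": 200}
        )
        theta, val = (res.x, res.fun) if res.fun <= nll0 else (x0, nll0)
        if val < best_nll:
            best_theta, best_nll, best_ok = theta, val, bool(res.success)
        clean = best_ok and best_nll < 1e11 and not _near_bounds(best_theta)
        if not clean and not tried_grid:
            starts.extend(_grid_starts(counts))
            tried_grid = True

    if best_theta is None or best_nll >= 1e11:
        return TelegraphFit(gene_id, allele, None, np.nan, n_used, "failed")
    params = TelegraphParams(*(10.0 ** best_theta))
    if _near_bounds(best_theta):
        status = "boundary"
    elif not best_ok:
        status = "failed"
    else:
        # unidentifiable Poisson corner (k_on, k_off -> large): when the fit
        # barely beats the one-parameter Poisson model the telegraph rates
        # are not pinned down and precise estimates would be spurious
        lam = max(float((uniq * mult).sum() / mult.sum()), 1e-12)
        ll_poisson = float(
            mult @ (uniq * np.log(lam) - lam - log_fact)
        )
        status = "boundary" if (-best_nll) - ll_poisson < 2.0 else "converged"
    return TelegraphFit(gene_id, allele, params, -best_nll, n_used, status)


def _normalise_counts(layer: pd.DataFrame, size_factors: pd.Series | None) -> pd.DataFrame:
    """Divide UMIs by per-cell size factors and round to the nearest integer."""
    if size_factors is None:
        return layer
    sf = size_factors.reindex(layer.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover all cells")
    return np.round(layer / sf).astype(np.int64)


def fit_all(
    matrix,
    annotation: pd.DataFrame,
    size_factors: pd.Series | None = None,
    expressed_genes=None,
    min_cells: int = MIN_CELLS,
    alleles=ALLELES,
    order: int = QUAD_ORDER,
) -> pd.DataFrame:
    """Fit every (gene, allele) layer of an allele-resolved UMI matrix.

    Counts are divided by per-cell spike size factors and rounded before
    fitting. ``expressed_genes`` restricts fitting to the expression mask.
    Returns a tidy table (gene, allele, rates, burst metrics, loglik, status).
    """
    genes = matrix.genes if expressed_genes is None else pd.Index(expressed_genes)
    rows = []
    for allele in alleles:
        if allele not in matrix.layers:
            continue
        layer = _normalise_counts(matrix[allele].loc[matrix.genes.intersection(genes)], size_factors)
        for gene in layer.index:
            fit = fit_telegraph(
                layer.loc[gene].to_numpy(), gene, allele, min_cells=min_cells, order=order
            )
            rows.append(
                {
                    "gene_id": gene,
                    "allele": allele,
                    "k_on": fit.params.k_on if fit.params else np.nan,
                    "k_off": fit.params.k_off if fit.params else np.nan,
                    "k_syn": fit.params.k_syn if fit.params else np.nan,
                    "burst_frequency": fit.burst_frequency,
                    "burst_size": fit.burst_size,
                    "loglik": fit.loglik,
                    "n_cells": fit.n_cells_used,
                    "status": fit.status,
                }
            )
    fits = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "allele", "k_on", "k_off", "k_syn",
            "burst_frequency", "burst_size", "loglik", "n_cells", "status",
        ],
    )
    if len(fits):
        log.info("fit_all status counts: %s", fits["status"].value_counts().to_dict())
    return fits


def relative_kinetics_log2(
    fits: pd.DataFrame,
    annotation: pd.DataFrame,
    metric: str = "burst_frequency",
    min_autosomal: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-gene log2 metric relative to the autosomal median, per allele.

    For each allele, rel(g) = log2(metric_g / median autosomal metric); the
    chrZ-vs-chrA contrast is a two-tailed Mann-Whitney U test with group
    medians and bootstrap percentile CIs. Alleles without converged Z fits
    are skipped.
    """
    if metric not in ("burst_frequency", "burst_size"):
        raise ValueError(f"unknown metric {metric!r}")
    from .dosage import percentile_ci

    chrom = annotation.set_index("gene_id")["chrom"]
    conv = fits[fits["status"] == "converged"].copy()
    conv["chrom"] = conv["gene_id"].map(chrom)
    out = {}
    rng = np.random.default_rng(seed)
    for allele, sub in conv.groupby("allele", sort=True):
        auto = sub[~sub["chrom"].isin(("Z", "W"))]
        zl = sub[sub["chrom"] == "Z"]
        if len(auto) < min_autosomal:
            log.info("allele %s: only %d converged autosomal fits, skipped", allele, len(auto))
            continue
        if len(zl) == 0:
            log.info("allele %s: no converged Z fits, test skipped", allele)
            continue
        med_auto = float(np.median(auto[metric]))
        rel = pd.Series(
            np.log2(sub[metric].to_numpy() / med_auto), index=sub["gene_id"], name=f"rel_{metric}"
        )
        rel_a = np.log2(auto[metric].to_numpy() / med_auto)
        rel_z = np.log2(zl[metric].to_numpy() / med_auto)
        mw = mannwhitneyu(rel_z, rel_a, alternative="two-sided")
        sub_seed = int(rng.integers(0, 2**31 - 1))

        def ci(values, s):
            if len(values) < 5:
                return (np.nan, np.nan)
            return percentile_ci(values, n_boot=n_boot, seed=s)

        out[allele] = {
            "rel": rel,
            "chroms": sub.set_index("gene_id")["chrom"],
            "median_z": float(np.median(rel_z)),
            "median_autosome": float(np.median(rel_a)),
            "ci_z": ci(rel_z, sub_seed),
            "ci_autosome": ci(rel_a, sub_seed + 1),
            "p_value": float(mw.pvalue),
            "n_z": int(len(rel_z)),
            "n_autosome": int(len(rel_a)),
        }
    return out


def calls_elevation(result: dict, alpha: float = 0.05) -> bool:
    """Whether a relative-kinetics contrast calls Z elevation for an allele:
    two-tailed p below ``alpha`` with the Z median above the autosomal one."""
    return result["p_value"] < alpha and result["median_z"] > 0


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False, float_format="%.10g")
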