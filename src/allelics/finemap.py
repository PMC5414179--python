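"""Case-control fine-mapping: QC filtering, score tests, conditional scans and LD.

The association machinery follows the standard GWAS recipe for a log-additive
genetic effect: a logistic null model containing only covariates (plus any
conditioning genotypes) is fitted, and each variant is tested with the 1-df
efficient score statistic

    U = g' (y - p),    V = g' W g - g' W X (X' W X)^{-1} X' W g,

with W = diag(p (1 - p)) at the null fit; U^2 / V is referred to chi-square
with one degree of freedom.  Conditional analysis appends the conditioning
variants' dosages to the covariate matrix and re-tests every other variant,
so signal collapse (proxies of a single causal variant losing significance)
and masking (a variant whose marginal effect is cancelled by a correlated
second signal) can both be read directly off the conditional p-values.

Linkage disequilibrium is computed from two-locus haplotype frequencies,
counted directly when phase is known and estimated by EM from unphased
genotypes otherwise:  D = pAB - pA pB,  r^2 = D^2 / (pA qA pB qB),
D' = |D| / Dmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import (
    AssociationResult,
    DegeneratePhenotypeError,
    GenotypeMatrix,
    LdPair,
    MonomorphicError,
)

__all__ = [
    "variant_qc_filter",
    "score_test",
    "association_scan",
    "ld_pair",
    "ld_from_haplotype_counts",
    "correlated_set",
    "NullFitError",
]

# QC defaults: imputed variants with minor-allele frequency below 1% or an
# imputation INFO score below 0.5 are excluded before association testing.
DEFAULT_MAF_MIN = 0.01
DEFAULT_INFO_MIN = 0.5


class NullFitError(RuntimeError):
    """Raised when the logistic null model fails to converge."""


# ---------------------------------------------------------------------------
# variant QC
# ---------------------------------------------------------------------------

def variant_qc_filter(
    variants: pd.DataFrame,
    maf_min: float = DEFAULT_MAF_MIN,
    info_min: float = DEFAULT_INFO_MIN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a variant table on MAF and imputation INFO score.

    A variant is retained iff ``maf >= maf_min`` and (INFO absent or
    ``info >= info_min``); both thresholds are inclusive.  Returns
    ``(retained, exclusion_log)`` where the log has columns ``id, reason``.
    """
    if len(variants) == 0:
        return variants.copy(), pd.DataFrame(columns=["id", "reason"])
    maf = variants["maf"].to_numpy(float)
    info = variants["info"].to_numpy(float) if "info" in variants else np.full(len(variants), np.nan)
    low_maf = maf < maf_min
    low_info = ~np.isnan(info) & (info < info_min)
    keep = ~(low_maf | low_info)
    reasons = []
    for i in np.flatnonzero(~keep):
        why = []
        if low_maf[i]:
            why.append(f"MAF {maf[i]:g} < {maf_min:g}")
        if low_info[i]:
            why.append(f"INFO {info[i]:g} < {info_min:g}")
        reasons.append({"id": variants["id"].iloc[i], "reason": "; ".join(why)})
    log = pd.DataFrame(reasons, columns=["id", "reason"])
    return variants.loc[keep].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# score test
# ---------------------------------------------------------------------------

def _as_design(X: Optional[np.ndarray], n: int) -> np.ndarray:
    """Covariate design matrix; defaults to an intercept column."""
    if X is None:
        return np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariate rows do not match phenotype length")
    # ensure an intercept-like column exists (constant column)
    if not np.any(np.ptp(X, axis=0) == 0):
        X = np.column_stack([np.ones(X.shape[0]), X])
    return X


def _fit_null(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fitted null probabilities for the covariate-only logistic model.

    Intercept-only designs have the closed-form MLE p = mean(y); anything
    richer is fitted by IRLS (statsmodels GLM, binomial family).
    """
    if X.shape[1] == 1 and np.ptp(X[:, 0]) == 0:
        return np.full(y.shape[0], y.mean())
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise NullFitError("logistic null model did not converge within 100 IRLS iterations")
    return np.asarray(res.fittedvalues)


def _score_core(g: np.ndarray, y: np.ndarray, X: np.ndarray, p_hat: np.ndarray) -> tuple[float, float]:
    """Efficient score U and variance V for one genotype column."""
    w = p_hat * (1.0 - p_hat)
    resid = y - p_hat
    U = float(g @ resid)
    XtWX = X.T @ (X * w[:, None])
    gWX = (g * w) @ X
    sol = np.linalg.solve(XtWX, gWX)
    V = float((g * g) @ w - gWX @ sol)
    return U, V


def _fit_alternative(g, y, X):
    """beta/SE for the genotype slope from the full logistic fit."""
    design = np.column_stack([X, g])
    model = sm.GLM(y, design, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=100, tol=1e-8)
    except Exception:
        return np.nan, np.nan, False
    beta = float(res.params[-1])
    se = float(res.bse[-1])
    # flag separation / non-convergence rather than reporting runaway estimates
    reliable = bool(res.converged) and np.isfinite(se) and se < 100.0 and abs(beta) < 50.0
    return beta, se, reliable


def score_test(
    g: np.ndarray,
    y: np.ndarray,
    X: Optional[np.ndarray] = None,
    variant_id: str = "variant",
    conditioned_on: tuple[str, ...] = (),
    fit_beta: bool = True,
) -> AssociationResult:
    """1-df score test of a log-additive genotype effect on case status.

    Rows with missing genotype, phenotype or covariates are dropped pairwise.
    The effect estimate (log OR) and its SE come from the full alternative
    fit when ``fit_beta`` is true; the p-value always comes from the score
    statistic evaluated at the covariate-only null fit.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape[0] != y.shape[0]:
        raise ValueError("genotype and phenotype lengths differ")
    X = _as_design(X, y.shape[0])
    keep = ~(np.isnan(g) | np.isnan(y) | np.isnan(X).any(axis=1))
    g, y, X = g[keep], y[keep], X[keep]
    uy = np.unique(y)
    if not np.isin(uy, [0.0, 1.0]).all():
        raise ValueError("phenotype must be binary 0/1")
    if uy.size < 2:
        raise DegeneratePhenotypeError("phenotype has a single class")
    if np.ptp(g) == 0:
        raise MonomorphicError(f"variant {variant_id!r} is monomorphic in the tested samples")
    p_hat = _fit_null(y, X)
    U, V = _score_core(g, y, X, p_hat)
    stat = U * U / V
    p = float(stats.chi2.sf(stat, df=1))
    p = max(p, np.nextafter(0, 1))  # keep p in (0, 1]
    if fit_beta:
        beta, se, reliable = _fit_alternative(g, y, X)
    else:
        beta, se, reliable = np.nan, np.nan, False
    return AssociationResult(
        variant_id=variant_id,
        beta=beta,
        se=se,
        score_stat=float(stat),
        p_value=p,
        n=int(y.shape[0]),
        conditioned_on=tuple(conditioned_on),
        beta_reliable=reliable,
    )


def association_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    X: Optional[np.ndarray] = None,
    condition_on: Sequence[str] = (),
    fit_beta: bool = True,
) -> pd.DataFrame:
    """Score-test every variant, optionally conditioning on chosen variants.

    Conditioning variants' dosages are appended to the covariate matrix and
    the remaining variants are tested one by one; conditioning variants are
    reported with NaN statistics.  Returns a DataFrame with one row per
    variant (columns: id, beta, se, score_stat, p_value, n, conditioned_on).
    """
    y = np.asarray(y, dtype=float)
    condition_on = list(condition_on)
    for vid in condition_on:
        if vid not in G.variant_ids:
            raise KeyError(f"conditioning variant {vid!r} is not in the genotype matrix")
    base = _as_design(X, y.shape[0])
    if condition_on:
        cond_cols = np.column_stack([G.column(v) for v in condition_on])
        design = np.column_stack([base, cond_cols])
    else:
        design = base

    rows = []
    keep = ~(np.isnan(y) | np.isnan(design).any(axis=1))
    yk, Xk = y[keep], design[keep]
    uy = np.unique(yk)
    if uy.size < 2:
        raise DegeneratePhenotypeError("phenotype has a single class")
    p_hat = _fit_null(yk, Xk)
    cond = tuple(condition_on)
    for j, vid in enumerate(G.variant_ids):
        if vid in condition_on:
            rows.append(
                dict(id=vid, beta=np.nan, se=np.nan, score_stat=np.nan,
                     p_value=np.nan, n=int(yk.shape[0]), conditioned_on=cond)
            )
            continue
        g = G.genotypes[:, j]
        if np.isnan(g[keep]).any():
            # pairwise deletion for this variant only: refit on the subset
            res = score_test(g, y, design, variant_id=vid,
                             conditioned_on=cond, fit_beta=fit_beta)
        else:
            gk = g[keep]
            if np.ptp(gk) == 0:
                raise MonomorphicError(f"variant {vid!r} is monomorphic in the tested samples")
            U, V = _score_core(gk, yk, Xk, p_hat)
            stat = U * U / V
            p = max(float(stats.chi2.sf(stat, df=1)), np.nextafter(0, 1))
            beta, se, reliable = (_fit_alternative(gk, yk, Xk) if fit_beta
                                  else (np.nan, np.nan, False))
            res = AssociationResult(vid, beta, se, float(stat), p, int(yk.shape[0]),
                                    cond, reliable)
        rows.append(
            dict(id=res.variant_id, beta=res.beta, se=res.se, score_stat=res.score_stat,
                 p_value=res.p_value, n=res.n, conditioned_on=res.conditioned_on)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def _ld_from_freqs(pAB, pAb, paB, pab, vi, vj, phased) -> LdPair:
    pA = pAB + pAb
    pB = pAB + paB
    qA, qB = 1 - pA, 1 - pB
    if min(pA, qA) <= 0 or min(pB, qB) <= 0:
        raise MonomorphicError("LD undefined: a locus is monomorphic")
    D = pAB - pA * pB
    r2 = D * D / (pA * qA * pB * qB)
    if D > 0:
        dmax = min(pA * qB, qA * pB)
    elif D < 0:
        dmax = min(pA * pB, qA * qB)
    else:
        dmax = 1.0
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    return LdPair(vi, vj, float(min(r2, 1.0)), float(min(d_prime, 1.0)),
                  (float(pAB), float(pAb), float(paB), float(pab)), phased)


def ld_from_haplotype_counts(nAB: float, nAb: float, naB: float, nab: float,
                             variant_i: str = "i", variant_j: str = "j") -> LdPair:
    """LD from directly counted two-locus haplotypes (phase known)."""
    total = nAB + nAb + naB + nab
    if total <= 0:
        raise ValueError("haplotype counts sum to zero")
    return _ld_from_freqs(nAB / total, nAb / total, naB / total, nab / total,
                          variant_i, variant_j, phased=True)


def _em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray,
                        tol: float = 1e-10, max_iter: int = 1000):
    """Two-locus haplotype frequencies from unphased genotypes by EM.

    Starts from linkage-equilibrium frequencies; only the double
    heterozygote's phase is latent and is resolved by expected counts.
    """
    keep = ~(np.isnan(g1) | np.isnan(g2))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    n = g1.shape[0]
    counts = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            counts[a, b] = np.count_nonzero((g1 == a) & (g2 == b))
    pA = g1.mean() / 2.0
    pB = g2.mean() / 2.0
    if min(pA, 1 - pA) <= 0 or min(pB, 1 - pB) <= 0:
        raise MonomorphicError("LD undefined: a locus is monomorphic")
    # haplotypes indexed (AB, Ab, aB, ab); start at linkage equilibrium
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])

    # known haplotype contributions of each unambiguous genotype pair
    known = np.zeros(4)
    for a in range(3):
        for b in range(3):
            if (a, b) == (1, 1):
                continue
            c = counts[a, b]
            if c == 0:
                continue
            # each individual contributes two haplotypes; outside the double
            # heterozygote the phase is determined
            alleleA = {0: [0, 0], 1: [1, 0], 2: [1, 1]}[a]
            alleleB = {0: [0, 0], 1: [1, 0], 2: [1, 1]}[b]
            for ha, hb in zip(alleleA, alleleB):
                idx = (1 - ha) * 2 + (1 - hb)
                known[idx] += c
    n_dh = counts[1, 1]

    def loglik(f):
        ll = 0.0
        probs = {
            (0, 0): f[3] ** 2, (0, 1): 2 * f[3] * f[2], (0, 2): f[2] ** 2,
            (1, 0): 2 * f[3] * f[1], (2, 0): f[1] ** 2,
            (1, 2): 2 * f[2] * f[0], (2, 1): 2 * f[1] * f[0], (2, 2): f[0] ** 2,
            (1, 1): 2 * f[0] * f[3] + 2 * f[1] * f[2],
        }
        for (a, b), pr in probs.items():
            c = counts[a, b]
            if c:
                ll += c * np.log(max(pr, 1e-300))
        return ll

    prev = loglik(f)
    for _ in range(max_iter):
        # E-step: split double heterozygotes between cis (AB/ab) and trans (Ab/aB)
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        tot = cis + trans
        w_cis = 0.5 if tot == 0 else cis / tot
        new = known.copy().astype(float)
        new[0] += n_dh * w_cis
        new[3] += n_dh * w_cis
        new[1] += n_dh * (1 - w_cis)
        new[2] += n_dh * (1 - w_cis)
        f = new / (2.0 * n)
        cur = loglik(f)
        if abs(cur - prev) < tol:
            break
        prev = cur
    return f


def ld_pair(data, i, j, phased: bool = False) -> LdPair:
    """LD between two loci from phased haplotypes or unphased genotypes.

    ``data`` is a 0/1 haplotype array (haplotypes x loci) when ``phased``,
    else a :class:`GenotypeMatrix`; ``i``/``j`` are variant ids (or column
    indices for the phased array).
    """
    if phased:
        H = np.asarray(data, dtype=float)
        if not isinstance(i, (int, np.integer)) or not isinstance(j, (int, np.integer)):
            raise TypeError("phased LD takes integer column indices into the haplotype array")
        a, b = H[:, i], H[:, j]
        nAB = np.count_nonzero((a == 1) & (b == 1))
        nAb = np.count_nonzero((a == 1) & (b == 0))
        naB = np.count_nonzero((a == 0) & (b == 1))
        nab = np.count_nonzero((a == 0) & (b == 0))
        return ld_from_haplotype_counts(nAB, nAb, naB, nab, str(i), str(j))
    G: GenotypeMatrix = data
    g1, g2 = G.column(i), G.column(j)
    f = _em_haplotype_freqs(g1, g2)
    return _ld_from_freqs(f[0], f[1], f[2], f[3], i, j, phased=False)


def correlated_set(G: GenotypeMatrix, index_variant: str, r2_threshold: float = 0.6) -> list[str]:
    """Variants with r^2 strictly above threshold to the index, by position.

    The index variant itself is excluded.  r^2 is EM-estimated from the
    unphased genotypes.
    """
    idx = G.index_of(index_variant)  # raises KeyError if absent
    hits = []
    for j, vid in enumerate(G.variant_ids):
        if j == idx:
            continue
        try:
            pair = ld_pair(G, index_variant, vid)
        except MonomorphicError:
            continue
        if pair.r2 > r2_threshold:
            hits.append((int(G.variants["pos"].iloc[j]), vid))
    return [vid for _, vid in sorted(hits)]
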