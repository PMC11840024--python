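"""Minimal LD-score regression: SNP heritability and genetic correlation.

Works on panels whose LD is exchangeable within blocks, so the LD score
of SNP j has the closed form l_j = 1 + (block size - 1) * r**2.  The
univariate model regresses z^2 on l,

    E[z_j^2] = intercept + n * h2 * l_j / m,

and the bivariate model regresses the z-score product on l,

    E[z1_j * z2_j] = intercept + sqrt(n1 * n2) * gcov * l_j / m,

giving the genetic correlation rg = gcov / sqrt(h2_1 * h2_2).  Fits are
weighted least squares with heteroskedasticity weights evaluated at a
first-pass unweighted estimate and iterated once (two steps total);
standard errors come from a delete-one block jackknife over contiguous
SNP blocks.  Within a genetic-correlation fit all three regressions
share one set of weights so that identical input traits return rg = 1
exactly.

This estimator deliberately omits partitioned heritability, reference
LD-score files and sample-overlap correction (synthetic cohorts are
independent by construction); the intercepts remain free and should sit
near 1 (univariate) and 0 (bivariate) on well-calibrated input.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import LdBlocks

log = logging.getLogger(__name__)

N_JACKKNIFE = 200


def ld_scores_from_blocks(blocks: LdBlocks) -> np.ndarray:
    """Per-SNP LD score under the exchangeable-block model.

    l_j = 1 + (K_j - 1) * r^2 for a SNP in a block of size K_j; equal to
    the row sum of squared correlations over the block's (implicit)
    correlation matrix.
    """
    labels = np.asarray(blocks.labels)
    if np.any(labels < 0):
        raise ValueError("unknown (negative) block label")
    sizes = np.bincount(labels)
    if np.any(sizes[np.unique(labels)] == 0):
        raise ValueError("unknown block for a SNP")
    return 1.0 + (sizes[labels] - 1.0) * blocks.r ** 2


def _wls_sufficient(x, y, w, n_blocks):
    """Per-jackknife-block normal-equation pieces for y ~ 1 + x, weights w."""
    m = len(x)
    cuts = np.linspace(0, m, n_blocks + 1).astype(int)
    A = np.column_stack([np.ones(m), x])
    WA = A * w[:, None]
    # S_b = A_b' W_b A_b (2x2), b_b = A_b' W_b y_b, per block
    S_blocks = np.empty((n_blocks, 2, 2))
    b_blocks = np.empty((n_blocks, 2))
    for k in range(n_blocks):
        sl = slice(cuts[k], cuts[k + 1])
        S_blocks[k] = A[sl].T @ WA[sl]
        b_blocks[k] = WA[sl].T @ y[sl]
    return S_blocks, b_blocks


def _wls_fit(x, y, w):
    A = np.column_stack([np.ones(len(x)), x])
    S = (A * w[:, None]).T @ A
    b = (A * w[:, None]).T @ y
    return np.linalg.solve(S, b)  # (intercept, slope)


def _jackknife(S_blocks, b_blocks, transform):
    """Delete-one-block estimates of transform(intercept, slope)."""
    S = S_blocks.sum(axis=0)
    b = b_blocks.sum(axis=0)
    n_blocks = len(S_blocks)
    vals = np.empty(n_blocks)
    for k in range(n_blocks):
        coef = np.linalg.solve(S - S_blocks[k], b - b_blocks[k])
        vals[k] = transform(coef)
    mean = vals.mean()
    se = np.sqrt((n_blocks - 1) / n_blocks * ((vals - mean) ** 2).sum())
    return vals, se


@dataclass
class H2Result:
    h2: float
    h2_raw: float
    intercept: float
    se_h2: float
    se_intercept: float


def fit_h2(
    z: np.ndarray,
    n: float | np.ndarray,
    ld_scores: np.ndarray,
    m: int | None = None,
    n_jackknife: int = N_JACKKNIFE,
) -> H2Result:
    """Univariate LD-score regression of z^2 on the LD score.

    ``m`` is the number of SNPs the heritability is spread over (defaults
    to the panel size).  The point estimate is truncated to [0, 1]; the
    raw value is retained and logged.
    """
    z = np.asarray(z, dtype=float)
    l = np.asarray(ld_scores, dtype=float)
    m = len(z) if m is None else m
    if len(z) < n_jackknife:
        raise ValueError("fewer SNPs than jackknife blocks")
    if np.ptp(l) == 0:
        raise ValueError("degenerate LD score variance: slope undefined")
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), z.shape)
    x = n_arr * l / m
    y = z ** 2

    coef0 = _wls_fit(x, y, np.ones_like(x))
    h2_0 = float(np.clip(coef0[1], 0.0, 1.0))
    w = 1.0 / (np.maximum(l, 1.0) * 2.0 * (1.0 + n_arr * h2_0 * l / m) ** 2)
    coef = _wls_fit(x, y, w)

    S_blocks, b_blocks = _wls_sufficient(x, y, w, n_jackknife)
    _, se_h2 = _jackknife(S_blocks, b_blocks, lambda c: c[1])
    _, se_int = _jackknife(S_blocks, b_blocks, lambda c: c[0])
    h2_raw = float(coef[1])
    h2 = float(np.clip(h2_raw, 0.0, 1.0))
    if h2 != h2_raw:
        log.info("h2 estimate %.4g truncated to [0, 1]", h2_raw)
    return H2Result(h2=h2, h2_raw=h2_raw, intercept=float(coef[0]),
                    se_h2=float(se_h2), se_intercept=float(se_int))


@dataclass
class LdscResult:
    """Heritabilities, genetic covariance and correlation for a trait pair."""

    h2_1: float
    h2_2: float
    gcov: float
    rg: float | None
    se_h2_1: float
    se_h2_2: float
    se_gcov: float
    se_rg: float | None
    intercept_1: float
    intercept_2: float
    intercept_biv: float
    p_rg: float | None
    reason: str = ""

    def to_row(self) -> dict:
        return {
            "h2_1": self.h2_1, "se_h2_1": self.se_h2_1,
            "h2_2": self.h2_2, "se_h2_2": self.se_h2_2,
            "gcov": self.gcov, "se_gcov": self.se_gcov,
            "rg": np.nan if self.rg is None else self.rg,
            "se_rg": np.nan if self.se_rg is None else self.se_rg,
            "p_rg": np.nan if self.p_rg is None else self.p_rg,
            "intercept_1": self.intercept_1,
            "intercept_2": self.intercept_2,
            "intercept_biv": self.intercept_biv,
            "reason": self.reason,
        }


def fit_rg(
    z1: np.ndarray,
    z2: np.ndarray,
    n1: float,
    n2: float,
    ld_scores: np.ndarray,
    m: int | None = None,
    n_jackknife: int = N_JACKKNIFE,
) -> LdscResult:
    """Bivariate LD-score regression: genetic covariance and correlation.

    All three regressions (two univariate, one cross) are refit under a
    single shared weight vector derived from first-pass unweighted
    estimates; rg and its jackknife SE are computed from delete-one-block
    re-estimates of the full ratio.  If either heritability estimate is
    nonpositive the correlation is reported undefined with a reason.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(ld_scores, dtype=float)
    m = len(z1) if m is None else m
    if len(z1) != len(z2) or len(z1) != len(l):
        raise ValueError("misaligned inputs")
    if len(z1) < n_jackknife:
        raise ValueError("fewer SNPs than jackknife blocks")
    if np.ptp(l) == 0:
        raise ValueError("degenerate LD score variance: slope undefined")

    x1 = n1 * l / m
    x2 = n2 * l / m
    xc = np.sqrt(n1 * n2) * l / m

    ones = np.ones_like(l)
    h2_1_0 = float(np.clip(_wls_fit(x1, z1 ** 2, ones)[1], 0.0, 1.0))
    h2_2_0 = float(np.clip(_wls_fit(x2, z2 ** 2, ones)[1], 0.0, 1.0))
    gcov_0 = float(_wls_fit(xc, z1 * z2, ones)[1])
    w = 1.0 / (
        np.maximum(l, 1.0)
        * ((1.0 + n1 * h2_1_0 * l / m) * (1.0 + n2 * h2_2_0 * l / m)
           + (np.sqrt(n1 * n2) * gcov_0 * l / m) ** 2)
    )

    c1 = _wls_fit(x1, z1 ** 2, w)
    c2 = _wls_fit(x2, z2 ** 2, w)
    cc = _wls_fit(xc, z1 * z2, w)
    h2_1, h2_2, gcov = float(c1[1]), float(c2[1]), float(cc[1])

    S1, b1 = _wls_sufficient(x1, z1 ** 2, w, n_jackknife)
    S2, b2 = _wls_sufficient(x2, z2 ** 2, w, n_jackknife)
    Sc, bc = _wls_sufficient(xc, z1 * z2, w, n_jackknife)
    h2_1_jk, se_h2_1 = _jackknife(S1, b1, lambda c: c[1])
    h2_2_jk, se_h2_2 = _jackknife(S2, b2, lambda c: c[1])
    gcov_jk, se_gcov = _jackknife(Sc, bc, lambda c: c[1])

    base = dict(
        h2_1=float(np.clip(h2_1, 0.0, 1.0)), h2_2=float(np.clip(h2_2, 0.0, 1.0)),
        gcov=gcov, se_h2_1=float(se_h2_1), se_h2_2=float(se_h2_2),
        se_gcov=float(se_gcov), intercept_1=float(c1[0]),
        intercept_2=float(c2[0]), intercept_biv=float(cc[0]),
    )
    if h2_1 <= 0 or h2_2 <= 0:
        return LdscResult(rg=None, se_rg=None, p_rg=None,
                          reason="nonpositive heritability estimate", **base)

    rg = gcov / np.sqrt(h2_1 * h2_2)
    denom = np.sqrt(np.maximum(h2_1_jk * h2_2_jk, 1e-24))
    rg_jk = gcov_jk / denom
    n_b = len(rg_jk)
    se_rg = float(np.sqrt((n_b - 1) / n_b * ((rg_jk - rg_jk.mean()) ** 2).sum()))
    p_rg = float(2.0 * stats.norm.sf(abs(rg) / se_rg)) if se_rg > 0 else 0.0
    if abs(rg) > 1.0:
        log.warning("rg estimate %.3f outside [-1, 1] (estimation noise)", rg)
    return LdscResult(rg=float(rg), se_rg=se_rg, p_rg=p_rg, **base)
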