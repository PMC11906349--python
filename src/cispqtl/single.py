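"""Single-variant association and conditional-joint signal selection.

Protein levels are rank-inverse normalised, regressed on per-variant
dosages with covariates, and independent signals are selected by a
CoJo-style forward-backward procedure.  Because the LD reference equals the
discovery sample here, conditional steps are carried out by exact
individual-level residualisation rather than summary-statistic algebra, so
the joint estimates of any selected set coincide with a direct multiple
regression on the same dosages.

Extremely small P values are computed entirely in log space
(``log10p_from_t``), so a |t| of several hundred still yields a finite
log10 P.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

LOG10E = np.log10(np.e)


def rank_inverse_normalize(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-inverse normal transform: Phi^-1((r - c) / (n - 2c + 1)).

    Ties receive average ranks.  Raises on fewer than 3 non-missing values
    or on a constant vector (ranks carry no information for inference).
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanmax(x) == np.nanmin(x):
        raise ValueError("all values identical; ranks undefined for inference")
    out = np.full(x.shape, np.nan)
    r = stats.rankdata(x[ok], method="average")
    n = ok.sum()
    out[ok] = stats.norm.ppf((r - c) / (n - 2 * c + 1))
    return out


# ---------------------------------------------------------------------------
# log-space t-test P


def _log_betacf(a: float, b: float, x: float, max_iter: int = 500) -> float:
    """Continued fraction for the regularized incomplete beta (Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 3e-15:
            break
    return h


def log_t_sf(t: float, df: float) -> float:
    """Natural log of the one-sided Student-t survival function P(T > t).

    Exact in log space for arbitrarily large ``t``; for small |t| (where no
    underflow is possible) the direct evaluation is used.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    if not np.isfinite(t):
        return -np.inf if t > 0 else 0.0
    if t <= 0:
        return float(np.log(stats.t.sf(t, df)))
    a, b = df / 2.0, 0.5
    x = df / (df + t * t)
    if x >= (a + 1.0) / (a + b + 2.0):
        # moderate statistic; sf is O(1) and direct evaluation is safe
        return float(np.log(stats.t.sf(t, df)))
    log_front = (
        a * np.log(x)
        + b * np.log1p(-x)
        - np.log(a)
        - special.betaln(a, b)
    )
    return float(np.log(0.5) + log_front + np.log(_log_betacf(a, b, x)))


def log10p_from_t(
    beta: float,
    se: float,
    n: int,
    k_covariates: int = 0,
    df_mode: str = "n_minus_2",
) -> float:
    """Two-sided t-test log10 P, computed entirely in log space.

    ``df_mode='n_minus_2'`` uses df = N - 2 (the convention used when
    recomputing underflowed P values from beta and s.e. alone);
    ``'n_minus_k_minus_2'`` subtracts the covariate count as well.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if df_mode == "n_minus_2":
        df = n - 2
    elif df_mode == "n_minus_k_minus_2":
        df = n - k_covariates - 2
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    if df <= 0:
        raise ValueError("nonpositive degrees of freedom")
    t = abs(beta / se)
    return LOG10E * (log_t_sf(t, df) + np.log(2.0))


def _log10p_vec(t_abs: np.ndarray, df: float) -> np.ndarray:
    return np.array([LOG10E * (log_t_sf(float(t), df) + np.log(2.0))
                     for t in t_abs])


# ---------------------------------------------------------------------------
# covariate handling


def design_matrix(covariates: pd.DataFrame | np.ndarray | None, n: int) -> np.ndarray:
    """Intercept + covariates as a dense float design matrix."""
    if covariates is None:
        return np.ones((n, 1))
    X = (covariates.to_numpy(dtype=float)
         if isinstance(covariates, pd.DataFrame) else
         np.asarray(covariates, dtype=float))
    if X.ndim == 1:
        X = X[:, None]
    return np.column_stack([np.ones(len(X)), X])


def orthonormal_basis(X: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """QR basis of the column space; raises naming collinear columns."""
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    bad = np.flatnonzero(diag < 1e-9 * scale)
    if len(bad):
        labels = ([names[i] for i in bad] if names is not None
                  else [f"column {i}" for i in bad])
        raise ValueError(f"rank-deficient covariates: {', '.join(map(str, labels))}")
    return q


def residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project columns of ``M`` off the orthonormal basis ``Q``."""
    return M - Q @ (Q.T @ M)


# ---------------------------------------------------------------------------
# marginal scan


def single_variant_assoc(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    min_mac: int = 5,
    df_mode: str = "n_minus_k_minus_2",
) -> pd.DataFrame:
    """Per-variant OLS of (already normalised) y on dosage + covariates.

    Variants with MAC < ``min_mac`` are skipped.  Missing dosages must be
    imputed beforehand (see :func:`cispqtl.qc.mean_impute`).  Uses
    Frisch-Waugh projection: covariates are swept from y and all dosages
    once, then each variant needs a single pair of dot products.
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    X = design_matrix(covariates, n)
    names = (["intercept"] + list(covariates.columns)
             if isinstance(covariates, pd.DataFrame) else None)
    Q = orthonormal_basis(X, names)
    k = X.shape[1] - 1  # covariates excluding intercept

    alt = G.sum(axis=0)
    mac = np.minimum(alt, 2 * n - alt)
    maf = mac / (2 * n)
    testable = mac >= min_mac

    yr = residualize(y[:, None], Q)[:, 0]
    Gr = residualize(G, Q)
    gty = Gr.T @ yr
    gtg = (Gr * Gr).sum(axis=0)
    testable &= gtg > 1e-12

    df = n - k - 2
    idx = np.flatnonzero(testable)
    beta = gty[idx] / gtg[idx]
    rss = yr @ yr - beta * gty[idx]
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / gtg[idx])
    t = beta / se
    log10p = _log10p_vec(
        np.abs(t), (n - 2) if df_mode == "n_minus_2" else df
    )
    p = np.minimum(1.0, 2.0 * stats.t.sf(np.abs(t), df))

    out = pd.DataFrame(
        {
            "idx": idx,
            "n": n,
            "mac": mac[idx].astype(int),
            "maf": maf[idx],
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "log10p": log10p,
        }
    )
    if variants is not None:
        vcols = variants.reset_index(drop=True)
        front = {
            col: vcols[col].to_numpy()[idx]
            for col in ("vid", "chrom", "pos", "ref", "alt")
            if col in vcols.columns
        }
        out = pd.concat([pd.DataFrame(front), out], axis=1)
    return out.reset_index(drop=True)


def ld_r2(ga: np.ndarray, gb: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing values are pairwise-dropped; monomorphic input is an error.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    a, b = ga[ok], gb[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic variant in LD computation")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# conditional-joint selection


@dataclass
class JointSignalSet:
    """Independent signals retained by the forward-backward joint model."""

    table: pd.DataFrame  # vid?, idx, beta_marginal, beta_joint, se_joint,
    #                      p_joint, log10p_joint, mac, maf
    selected_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    n_forward_steps: int = 0

    @property
    def max_abs_beta_discrepancy(self) -> float:
        if len(self.table) == 0:
            return 0.0
        return float(
            np.max(np.abs(self.table["beta_marginal"] - self.table["beta_joint"]))
        )

    def __len__(self) -> int:
        return len(self.selected_idx)


def _joint_fit(Gs: np.ndarray, yr: np.ndarray, df: int):
    """OLS of covariate-residualised y on the selected dosage columns."""
    coef, _, rank, _ = np.linalg.lstsq(Gs, yr, rcond=None)
    resid = yr - Gs @ coef
    rss = float(resid @ resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.pinv(Gs.T @ Gs)
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return coef, se, t, p


def cojo_select(
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    variants: pd.DataFrame | None = None,
    p_threshold: float = 2.95e-10,
    min_mac: int = 5,
    r2_guard: float = 0.99,
    diff_freq: float = 0.2,
    max_iter: int = 100,
) -> JointSignalSet:
    """Forward-backward conditional-joint selection of independent signals.

    Forward: repeatedly add the variant with the smallest conditional P
    (given covariates and the current selected set) while it is below the
    threshold; ties broken by smaller P, then larger MAC, then position.
    Backward: refit the joint model and drop any selected variant whose
    joint P is at or above the threshold, until stable.  There is no
    variance-explained collinearity-ratio filter (it discards genuine
    large-effect signals when the LD panel is the discovery sample); a
    pairwise r^2 > ``r2_guard`` check against already-selected variants
    prevents singular joint fits instead.  ``diff_freq`` is accepted for
    interface compatibility; with an in-sample LD panel the allele
    frequencies cannot disagree, so it never triggers.
    """
    G = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    X = design_matrix(covariates, n)
    Q = orthonormal_basis(X)
    k = X.shape[1] - 1

    alt = G.sum(axis=0)
    mac = np.minimum(alt, 2 * n - alt)
    maf = mac / (2 * n)
    pos = (variants["pos"].to_numpy() if variants is not None
           and "pos" in variants.columns else np.arange(m))

    yr = residualize(y[:, None], Q)[:, 0]
    Gr = residualize(G, Q)
    gtg_marg = (Gr * Gr).sum(axis=0)
    candidate = (mac >= min_mac) & (gtg_marg > 1e-12)
    beta_marginal = np.where(gtg_marg > 0, (Gr.T @ yr) / np.maximum(gtg_marg, 1e-300), 0.0)

    selected: list[int] = []
    excluded = np.zeros(m, dtype=bool)
    n_forward = 0

    for _ in range(max_iter):
        changed = False
        # ---- forward step
        s = len(selected)
        if s:
            B = np.linalg.qr(Gr[:, selected])[0]
            y_res = yr - B @ (B.T @ yr)
            G_res = Gr - B @ (B.T @ Gr)
        else:
            y_res = yr
            G_res = Gr
        df = n - k - s - 2
        if df <= 0:
            break
        cand = candidate & ~excluded
        cand[selected] = False
        ci = np.flatnonzero(cand)
        if len(ci):
            gtg = (G_res[:, ci] ** 2).sum(axis=0)
            usable = gtg > 1e-10 * np.maximum(gtg_marg[ci], 1e-300)
            ci = ci[usable]
        if len(ci):
            gtg = (G_res[:, ci] ** 2).sum(axis=0)
            gty = G_res[:, ci].T @ y_res
            b = gty / gtg
            rss = y_res @ y_res - b * gty
            se = np.sqrt(np.maximum(rss, 0.0) / df / gtg)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, np.abs(b / se), 0.0)
            logp = stats.t.logsf(t, df) + np.log(2.0)
            order = np.lexsort((pos[ci], -mac[ci], logp))
            for oi in order:
                j = int(ci[oi])
                if logp[oi] >= np.log(p_threshold):
                    break
                collinear = any(
                    ld_r2(Gr[:, j], Gr[:, sj]) > r2_guard for sj in selected
                )
                if collinear:
                    excluded[j] = True
                    continue
                selected.append(j)
                n_forward += 1
                changed = True
                break
        # ---- backward step
        while len(selected) > 1:
            s = len(selected)
            dfj = n - k - s - 1
            if dfj <= 0:
                break
            _, _, _, pj = _joint_fit(Gr[:, selected], yr, dfj)
            worst = int(np.argmax(pj))
            if pj[worst] >= p_threshold:
                del selected[worst]
                changed = True
            else:
                break
        if not changed:
            break
    else:
        warnings.warn("cojo_select did not converge within max_iter")

    if selected and len(selected) == 1:
        dfj = n - k - 2
        coef, se, t, pj = _joint_fit(Gr[:, selected], yr, dfj)
        if pj[0] >= p_threshold:
            selected = []

    if not selected:
        cols = ["idx", "beta_marginal", "beta_joint", "se_joint",
                "t_joint", "p_joint", "log10p_joint", "mac", "maf"]
        if variants is not None and "vid" in variants.columns:
            cols = ["vid"] + cols
        return JointSignalSet(pd.DataFrame(columns=cols), np.empty(0, int),
                              n_forward)

    sel = np.array(sorted(selected), dtype=int)
    dfj = n - k - len(sel) - 1
    coef, se, t, pj = _joint_fit(Gr[:, sel], yr, dfj)
    log10p = _log10p_vec(np.abs(t), dfj)
    table = pd.DataFrame(
        {
            "idx": sel,
            "beta_marginal": beta_marginal[sel],
            "beta_joint": coef,
            "se_joint": se,
            "t_joint": t,
            "p_joint": pj,
            "log10p_joint": log10p,
            "mac": mac[sel].astype(int),
            "maf": maf[sel],
        }
    )
    if variants is not None and "vid" in variants.columns:
        table.insert(0, "vid", variants["vid"].to_numpy()[sel])
    return JointSignalSet(table, sel, n_forward)


def variance_explained(
    signals: JointSignalSet,
    dosages: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> float:
    """R^2 increment of the joint signal dosages over the covariate model."""
    if len(signals) == 0:
        return 0.0
    G = np.asarray(dosages, dtype=float)[:, signals.selected_idx]
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = design_matrix(covariates, n)
    Q = orthonormal_basis(X)
    yr = residualize(y[:, None], Q)[:, 0]
    Gr = residualize(G, Q)
    coef, _, _, _ = np.linalg.lstsq(Gr, yr, rcond=None)
    resid = yr - Gr @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    r2_full = 1.0 - float(resid @ resid) / tss
    r2_cov = 1.0 - float(yr @ yr) / tss
    return max(0.0, min(1.0, r2_full - r2_cov))
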