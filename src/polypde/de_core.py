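"""Negative-binomial differential expression between two library groups.

Model: counts k_ij ~ NB(mean s_j * q_i, variance mu + alpha_i * mu^2) with
per-library size factors s_j (median-of-ratios), per-transcript base mean
q_i, and per-transcript dispersion alpha_i estimated under a declared
condition grouping by one of two engines:

``conservative``
    method-of-moments raw dispersion, a fitted a1/q + a0 mean-dispersion
    trend, and final = max(raw, trend) — deliberately pessimistic, in the
    spirit of the more conservative of the two classic count-based DE
    packages.
``shrinkage``
    maximum a-posteriori dispersion: per-transcript NB log-likelihood
    (condition means profiled out by a plug-in estimate) plus a log-normal
    prior centred on the local raw-dispersion trend, weighted by
    ``prior_weight`` pseudo-transcripts.

Significance comes from the exact conditional NB test on the two group
sums, with Benjamini-Hochberg adjustment across tested transcripts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .tables import check_design_matches_counts, resolve_condition, validate_counts

ALPHA_MAX = 10.0
EXACT_TEST_CAP = 10_000  # above this total, switch to the normal approximation
ENGINES = ("conservative", "shrinkage")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    s_j = median over transcripts (restricted to rows positive in every
    library) of k_ij / geometric-mean_i.
    """
    validate_counts(counts)
    k = counts.to_numpy(dtype=float)
    if k.size == 0:
        raise ValueError("empty count table")
    positive = (k > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no transcript has positive counts in every library; "
            "median-of-ratios size factors are undefined "
            "(a pseudo-reference fallback is deliberately not applied)"
        )
    rows = k[positive]
    log_geomean = np.log(rows).mean(axis=1)
    ratios = rows / np.exp(log_geomean)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts / factors.reindex(counts.columns)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionFit:
    """Per-transcript dispersion estimates under one engine.

    ``table`` has columns ``base_mean``, ``raw_alpha``, ``fitted_alpha``
    (trend value at the transcript's base mean), ``final_alpha`` and
    ``tested``; ``trend`` holds the (a0, a1) coefficients of the
    alpha(q) = a1/q + a0 mean-dispersion curve.
    """

    table: pd.DataFrame
    trend: tuple[float, float]
    engine: str
    conditions: Mapping[str, str]

    def final_alpha(self) -> pd.Series:
        return self.table["final_alpha"]


def _fit_trend(q: np.ndarray, raw: np.ndarray) -> tuple[float, float]:
    """Fit alpha(q) = a1/q + a0 (a0, a1 >= 0) by iterated weighted NNLS.

    Weights 1/fitted^2 (gamma-style) so high-dispersion transcripts do not
    dominate. Zero raw values stay in the fit: the moment estimator is
    clipped at zero, and dropping those observations right-censors the
    sample exactly where it is noisiest (low expression), inflating the
    1/q term severalfold. Falls back to a flat trend at the mean raw
    dispersion.
    """
    mask = (raw >= 0) & (q > 0) & np.isfinite(raw)
    if mask.sum() < 2:
        warnings.warn("too few positive raw dispersions; using flat trend")
        level = float(np.nanmean(raw[np.isfinite(raw)])) if np.isfinite(raw).any() else 0.0
        return max(level, 0.0), 0.0
    x = np.column_stack([np.ones(mask.sum()), 1.0 / q[mask]])
    y = raw[mask]
    try:
        coef, _ = nnls(x, y)
        for _ in range(8):
            pred = np.clip(x @ coef, 1e-8, None)
            coef, _ = nnls(x / pred[:, None], y / pred)
        if not np.all(np.isfinite(coef)) or (coef <= 0).all():
            raise RuntimeError("degenerate trend fit")
    except Exception:
        warnings.warn("dispersion trend fit failed; using flat trend at mean raw value")
        return float(np.mean(y)), 0.0
    return float(coef[0]), float(coef[1])


def _condition_index(
    counts: pd.DataFrame, conditions: Mapping[str, str] | pd.Series
) -> dict[str, np.ndarray]:
    cond = pd.Series(dict(conditions) if not isinstance(conditions, pd.Series) else conditions)
    missing = [c for c in counts.columns if c not in cond.index]
    if missing:
        raise ValueError(f"libraries without a condition label: {missing}")
    groups: dict[str, list[int]] = {}
    for j, lib in enumerate(counts.columns):
        groups.setdefault(cond[lib], []).append(j)
    return {label: np.array(idx) for label, idx in groups.items()}


def _nb_logpmf_matrix(k: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Elementwise NB(mean mu, var mu + alpha mu^2) log-pmf; Poisson at alpha=0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha <= 0:
            ll = k * np.log(mu) - mu - gammaln(k + 1.0)
        else:
            r = 1.0 / alpha
            ll = (
                gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
                + r * np.log(r / (r + mu)) + k * np.log(mu / (r + mu))
            )
    return np.where(mu > 0, ll, np.where(k == 0, 0.0, -np.inf))


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: Mapping[str, str] | pd.Series,
    engine: str = "conservative",
    prior_weight: float = 10.0,
    trend_window: int = 500,
) -> DispersionFit:
    """Per-transcript dispersion under a condition grouping.

    Raw estimate (method of moments): with normalized counts r_ij = k_ij/s_j,
    base mean q_i and pooled within-condition variance w_i,

        raw_alpha_i = max(0, (w_i - z_i) / q_i^2),   z_i = q_i * mean_j(1/s_j)

    subtracting the Poisson (shot-noise) component z before scaling.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    k = counts.to_numpy(dtype=float)
    s = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("size factors must be positive and cover all libraries")
    r = k / s
    q = r.mean(axis=1)
    tested = q > 0

    groups = _condition_index(counts, conditions)
    ss = np.zeros(len(counts))
    dof = 0
    for idx in groups.values():
        if len(idx) >= 2:
            sub = r[:, idx]
            centered = sub - sub.mean(axis=1, keepdims=True)
            ss += (centered**2).sum(axis=1)
            dof += len(idx) - 1
    if dof == 0:
        raise ValueError("dispersion estimation needs a condition with >= 2 libraries")
    w = ss / dof
    z = q * np.mean(1.0 / s)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(tested, np.maximum(0.0, (w - z) / q**2), np.nan)

    a0, a1 = _fit_trend(q, np.where(tested, raw, np.nan))
    with np.errstate(divide="ignore"):
        fitted = np.where(tested, a0 + a1 / np.where(q > 0, q, np.nan), np.nan)

    if engine == "conservative":
        final = np.maximum(raw, fitted)
    else:
        final = _map_shrink(k, s, groups, q, raw, tested, prior_weight, trend_window)

    table = pd.DataFrame(
        {
            "base_mean": q,
            "raw_alpha": raw,
            "fitted_alpha": fitted,
            "final_alpha": final,
            "tested": tested,
        },
        index=counts.index,
    )
    cond_map = dict(conditions) if not isinstance(conditions, pd.Series) else conditions.to_dict()
    return DispersionFit(table=table, trend=(a0, a1), engine=engine, conditions=cond_map)


def _map_shrink(
    k: np.ndarray,
    s: np.ndarray,
    groups: dict[str, np.ndarray],
    q: np.ndarray,
    raw: np.ndarray,
    tested: np.ndarray,
    prior_weight: float,
    trend_window: int,
) -> np.ndarray:
    n = k.shape[0]
    # plug-in condition means (Poisson-profile MLE): mu_ij = s_j * sum k / sum s
    mu = np.zeros_like(k)
    for idx in groups.values():
        cond_mean = k[:, idx].sum(axis=1) / s[idx].sum()
        mu[:, idx] = cond_mean[:, None] * s[idx][None, :]

    # local prior centre: rolling mean of raw dispersion over the nearest
    # trend_window transcripts by base mean (mean, not median: the raw
    # moment estimator is right-skewed, so its median underestimates the
    # typical dispersion)
    raw_floor = np.where(np.isfinite(raw), np.maximum(raw, 1e-6), np.nan)
    order = np.argsort(q, kind="stable")
    rolled = (
        pd.Series(raw_floor[order])
        .rolling(trend_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    local = np.empty(n)
    local[order] = rolled
    local = np.where(np.isfinite(local), local, 1e-6)
    log_local = np.log(local)

    grid = np.logspace(-6, math.log10(ALPHA_MAX), 49)
    log_grid = np.log(grid)
    objective = np.full((len(grid), n), -np.inf)
    group_list = list(groups.values())
    for g, alpha in enumerate(grid):
        ll = _nb_logpmf_matrix(k, mu, alpha).sum(axis=1)
        # Cox-Reid adjustment: penalize the information spent estimating the
        # per-condition means, else dispersion is biased low
        cr = np.zeros(n)
        for idx in group_list:
            with np.errstate(divide="ignore"):
                info = (mu[:, idx] / (1.0 + alpha * mu[:, idx])).sum(axis=1)
                cr -= 0.5 * np.where(info > 0, np.log(info), 0.0)
        objective[g] = ll + cr - 0.5 * prior_weight * (log_grid[g] - log_local) ** 2

    best = objective.argmax(axis=0)
    # quadratic refinement on log alpha between grid neighbours
    log_best = log_grid[best]
    interior = (best > 0) & (best < len(grid) - 1)
    idx = np.where(interior)[0]
    if idx.size:
        b = best[idx]
        f0 = objective[b - 1, idx]
        f1 = objective[b, idx]
        f2 = objective[b + 1, idx]
        denom = f0 - 2 * f1 + f2
        ok = np.isfinite(denom) & (denom < 0)
        step = log_grid[1] - log_grid[0]
        shift = np.where(ok, 0.5 * (f0 - f2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        log_best[idx] = log_grid[best[idx]] + shift * step
    final = np.clip(np.exp(log_best), 0.0, ALPHA_MAX)
    return np.where(tested, final, np.nan)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

_TIE_LOG_TOL = 1e-10


def _log_nb_pmf_1d(x: np.ndarray, mu: float, alpha: float) -> np.ndarray:
    if mu <= 0:
        out = np.full(x.shape, -np.inf)
        out[x == 0] = 0.0
        return out
    if alpha <= 0:
        return x * math.log(mu) - mu - gammaln(x + 1.0)
    r = 1.0 / alpha
    return (
        gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
        + r * math.log(r / (r + mu)) + x * np.log(mu / (r + mu))
    )


def nb_exact_test(
    k_a: Sequence[float],
    k_b: Sequence[float],
    s_a: Sequence[float],
    s_b: Sequence[float],
    alpha: float,
    cap: int = EXACT_TEST_CAP,
) -> float:
    """Exact conditional NB test on the two group sums.

    With common concentration q_hat = K_S / (sum s_A + sum s_B), each group
    sum is modelled NB with mean mu_G = q_hat * sum_G(s) and variance equal
    to the sum of the member libraries' NB variances,

        V_G = sum_j (q_hat s_j + alpha q_hat^2 s_j^2),

    i.e. an effective sum dispersion alpha_G = alpha * sum(s^2) / sum(s)^2
    (the sum of n similar NB variables is relatively less overdispersed
    than each member). The p-value sums P(a)P(b) over all splits
    a + b = K_S whose joint probability does not exceed the observed one
    (ties included), normalized by the total. Returns NaN for K_S = 0
    (not tested). Above ``cap`` the sum is evaluated on a subsampled grid
    of splits (the split density is smooth at that scale, and the grid
    spacing cancels from the ratio); a Gaussian approximation at the mode
    was rejected because the split distribution is skewed and
    heavy-tailed, overstating tail p-values severalfold.
    """
    if alpha < 0 or not np.isfinite(alpha):
        raise ValueError("alpha must be finite and >= 0")
    ka = int(round(float(np.sum(k_a))))
    kb = int(round(float(np.sum(k_b))))
    total = ka + kb
    if total == 0:
        return float("nan")
    sa = float(np.sum(s_a))
    sb = float(np.sum(s_b))
    if sa <= 0 or sb <= 0:
        raise ValueError("size-factor totals must be positive")
    q_hat = total / (sa + sb)
    mu_a = q_hat * sa
    mu_b = q_hat * sb
    # effective dispersion of each group SUM (variance additivity)
    alpha_a = alpha * float(np.sum(np.square(s_a))) / sa**2
    alpha_b = alpha * float(np.sum(np.square(s_b))) / sb**2

    if total <= cap:
        a = np.arange(total + 1)
        lf = _log_nb_pmf_1d(a, mu_a, alpha_a) + _log_nb_pmf_1d(
            (total - a).astype(float), mu_b, alpha_b
        )
        l_obs = lf[ka]
        keep = lf <= l_obs + _TIE_LOG_TOL
        p = math.exp(logsumexp(lf[keep]) - logsumexp(lf))
        return min(max(p, 5e-324), 1.0)

    # subsampled-grid evaluation: the grid spacing cancels from the ratio
    step = (total + 1 + cap - 1) // cap
    a = np.arange(0, total + 1, step, dtype=float)
    lf = _log_nb_pmf_1d(a, mu_a, alpha_a) + _log_nb_pmf_1d(total - a, mu_b, alpha_b)
    l_obs = float(
        _log_nb_pmf_1d(np.array([float(ka)]), mu_a, alpha_a)[0]
        + _log_nb_pmf_1d(np.array([float(total - ka)]), mu_b, alpha_b)[0]
    )
    keep = lf <= l_obs + _TIE_LOG_TOL
    if not keep.any():
        # the observed split is likelier than every grid point; its own
        # mass still belongs in the numerator
        p = math.exp(l_obs - logsumexp(lf) - math.log(step))
    else:
        p = math.exp(logsumexp(lf[keep]) - logsumexp(lf))
    return min(max(p, 5e-324), 1.0)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up; NaN entries (not tested) are excluded from m."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        pm = p[mask]
        if (pm <= 0).any() or (pm > 1).any():
            raise ValueError("p-values must lie in (0, 1]")
        out[mask] = multipletests(pm, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# the full two-group analysis
# ---------------------------------------------------------------------------

def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    comparison: tuple[str, str],
    engine: str = "conservative",
    *,
    dispersion: DispersionFit | None = None,
    dispersion_conditions: Mapping[str, str] | None = None,
    group_a: Sequence[str] | None = None,
    group_b: Sequence[str] | None = None,
    transcripts: Sequence[str] | None = None,
    pseudocount: float = 1.0,
    exact_cap: int = EXACT_TEST_CAP,
) -> pd.DataFrame:
    """Two-group NB differential expression.

    ``comparison = (A, B)`` names the conditions; positive
    ``log2_fold_change`` means higher expression in the first-named
    condition. Group membership defaults to the design's polyp (or
    gonozooid-sex) labels and can be overridden with ``group_a`` /
    ``group_b`` — the adjustment workflow uses this to represent the
    gonozooid condition by its male libraries only. Dispersions are
    estimated once from ALL libraries under ``dispersion_conditions``
    (default: polyp type) and may be passed in pre-computed for reuse
    across pairwise comparisons. ``transcripts`` restricts the tested
    template pool.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}")
    validate_counts(counts)
    check_design_matches_counts(design, counts)
    name_a, name_b = comparison
    libs_a = list(group_a) if group_a is not None else resolve_condition(design, name_a)
    libs_b = list(group_b) if group_b is not None else resolve_condition(design, name_b)
    if not libs_a or not libs_b:
        raise ValueError("both comparison groups need at least one library")
    overlap = set(libs_a) & set(libs_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")

    factors = size_factors(counts)
    if dispersion is None:
        if dispersion_conditions is None:
            dispersion_conditions = dict(
                zip(design["library_id"], design["polyp"])
            )
        dispersion = estimate_dispersion(counts, factors, dispersion_conditions, engine)
    elif dispersion.engine != engine:
        raise ValueError(
            f"dispersion fit was computed with engine {dispersion.engine!r}, "
            f"requested {engine!r}"
        )

    if transcripts is not None:
        wanted = set(transcripts)
        sub = counts.loc[[t for t in counts.index if t in wanted]]
    else:
        sub = counts

    r = sub / factors
    ra = r[libs_a].to_numpy()
    rb = r[libs_b].to_numpy()
    ka = sub[libs_a].to_numpy(dtype=float)
    kb = sub[libs_b].to_numpy(dtype=float)
    sa = factors[libs_a].to_numpy()
    sb = factors[libs_b].to_numpy()

    base_mean = np.concatenate([ra, rb], axis=1).mean(axis=1)
    log2_fc = np.log2((ra.mean(axis=1) + pseudocount) / (rb.mean(axis=1) + pseudocount))

    alphas = dispersion.table["final_alpha"].reindex(sub.index).to_numpy()
    trend_a0 = dispersion.trend[0]

    total_a = ka.sum(axis=1)
    total_b = kb.sum(axis=1)
    tested = (total_a + total_b) > 0

    p = np.full(len(sub), np.nan)
    for i in np.flatnonzero(tested):
        alpha_i = alphas[i]
        if not np.isfinite(alpha_i):
            alpha_i = trend_a0  # transcript zero overall but non-zero here is impossible;
            # guard for externally supplied fits
        p[i] = nb_exact_test(
            ka[i], kb[i], sa, sb, float(alpha_i), cap=exact_cap
        )

    result = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": log2_fc,
            "p_value": p,
            "p_adj": bh_adjust(p),
            "tested": tested,
        },
        index=sub.index,
    )
    result.attrs["comparison"] = f"{name_a}_vs_{name_b}"
    result.attrs["engine"] = engine
    return result


def significant(de_table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Boolean mask of transcripts with p_adj < alpha (not-tested => False)."""
    padj = de_table["p_adj"]
    return (padj < alpha).fillna(False) & de_table["tested"]
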