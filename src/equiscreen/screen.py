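"""Design-response screening, ANOVA variance decomposition, moderated t.

Peaks whose variance cannot be predicted from the experimental design
(ripening stage, genotype, treatment, harvest chronology) have unclear
analytical precision; the screen retains only peaks whose overall linear
model is significant by F-test.  The variance decomposition attributes each
peak's total sum of squares to the design factors (sequential, type-I) on a
0-100 scale.  The moderated t-test shrinks per-peak variances toward a
common prior (empirical Bayes), stabilizing two-group comparisons across
thousands of peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import EquiscreenError, PeakTable, StudyDesign

DEFAULT_FACTORS = ("stage", "genotype", "treatment", "harvest_order")


@dataclass
class ScreenResult:
    """Per-peak overall-model F statistics from the design-response filter."""

    table: pd.DataFrame  # peak_id index; columns F, df_num, df_den, p, retained
    alpha: float

    @property
    def retained_peaks(self) -> list:
        return list(self.table.index[self.table["retained"]])

    @property
    def retained_fraction(self) -> float:
        return float(self.table["retained"].mean())


@dataclass
class VarianceDecomposition:
    """Per-peak factor sums of squares scaled so each peak totals 100."""

    scaled_ss: pd.DataFrame   # peaks x (factors..., residual), rows sum to 100
    p_values: pd.DataFrame    # peaks x factors
    significant: pd.DataFrame  # peaks x factors, bool at the 95th F percentile


@dataclass
class ModeratedTestResult:
    """Empirical-Bayes moderated two-sample t-tests."""

    table: pd.DataFrame  # peak_id index; mean_diff, t, p, p_adj, df_total
    d0: float            # prior degrees of freedom
    s0_sq: float         # prior variance


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

def _factor_blocks(design: StudyDesign, factors, interactions=()):
    """Build per-factor design-matrix blocks (treatment coding).

    ``harvest_order`` enters as a single centered numeric covariate; all
    other factors as 0/1 indicator columns dropping the first level.
    Factors with a single level are skipped.  Returns an ordered list of
    ``(name, DataFrame)`` blocks.
    """
    df = design.table
    blocks = []
    for fac in factors:
        if fac not in df.columns:
            raise EquiscreenError(f"unknown design factor {fac!r}")
        if fac == "harvest_order":
            col = df[fac].astype(float)
            if col.nunique() < 2:
                continue
            blocks.append((fac, pd.DataFrame({fac: col - col.mean()}, index=df.index)))
        else:
            levels = sorted(df[fac].astype(str).unique())
            if len(levels) < 2:
                continue
            dummies = pd.get_dummies(df[fac].astype(str), prefix=fac, dtype=float)
            blocks.append((fac, dummies[[f"{fac}_{lv}" for lv in levels[1:]]]))
    by_name = dict(blocks)
    for a, b in interactions:
        if a not in by_name or b not in by_name:
            raise EquiscreenError(
                f"interaction {a}:{b} requires both factors in the model "
                f"with >=2 levels")
        cols = {}
        for ca in by_name[a].columns:
            for cb in by_name[b].columns:
                cols[f"{ca}:{cb}"] = by_name[a][ca] * by_name[b][cb]
        blocks.append((f"{a}:{b}", pd.DataFrame(cols, index=df.index)))
    if not blocks:
        raise EquiscreenError("design has no factor with >=2 levels")
    return blocks


def _check_rank(blocks, index) -> None:
    """Raise naming aliased columns if the full design matrix is rank-deficient."""
    full = pd.concat([b for _, b in blocks], axis=1)
    x = np.column_stack([np.ones(len(index)), full.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    aliased = []
    kept = np.ones((len(index), 1))
    for name in full.columns:
        cand = np.column_stack([kept, full[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            aliased.append(name)
    raise EquiscreenError(f"design is rank-deficient; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# overall-model screen
# ---------------------------------------------------------------------------

def design_response_filter(
    table: PeakTable,
    design: StudyDesign,
    alpha: float = 0.05,
    factors=DEFAULT_FACTORS,
) -> ScreenResult:
    """Retain peaks whose abundance is predicted by the experimental design.

    Per peak, an ordinary-least-squares fit of abundance on additive
    first-order factor encodings is compared with the intercept-only model
    by overall F-test; the peak is retained iff p < ``alpha``.  Rows with a
    missing abundance are dropped per peak (complete case).  Constant peaks
    have an undefined F and are excluded with a warning.
    """
    design.check_matches(table)
    sub_design = StudyDesign(design.table.loc[table.sample_ids])
    blocks = _factor_blocks(sub_design, factors)
    _check_rank(blocks, sub_design.table.index)
    xfull = pd.concat([b for _, b in blocks], axis=1).to_numpy(dtype=float)
    y_all = table.data.to_numpy(dtype=float)

    rows = []
    n_constant = 0
    for j, peak in enumerate(table.peak_ids):
        y = y_all[:, j]
        obs = np.isfinite(y)
        n = int(obs.sum())
        x = np.column_stack([np.ones(n), xfull[obs]])
        rank = np.linalg.matrix_rank(x)
        df_num = rank - 1
        df_den = n - rank
        yo = y[obs]
        sst = float(np.sum((yo - yo.mean()) ** 2))
        if sst <= 1e-300 or df_den < 1 or df_num < 1:
            n_constant += 1
            rows.append({"peak_id": peak, "F": np.nan, "df_num": df_num,
                         "df_den": df_den, "p": np.nan, "retained": False})
            continue
        beta, *_ = np.linalg.lstsq(x, yo, rcond=None)
        sse = float(np.sum((yo - x @ beta) ** 2))
        f = ((sst - sse) / df_num) / (sse / df_den) if sse > 0 else np.inf
        p = float(stats.f.sf(f, df_num, df_den))
        rows.append({"peak_id": peak, "F": f, "df_num": df_num, "df_den": df_den,
                     "p": p, "retained": bool(p < alpha)})
    if n_constant:
        warnings.warn(f"design_response_filter: {n_constant} constant/degenerate "
                      f"peak(s) excluded (F undefined)", stacklevel=2)
    out = pd.DataFrame(rows).set_index("peak_id")
    return ScreenResult(out, alpha=alpha)


# ---------------------------------------------------------------------------
# sequential variance decomposition
# ---------------------------------------------------------------------------

def anova_decomposition(
    table: PeakTable,
    design: StudyDesign,
    factors=DEFAULT_FACTORS,
    interactions=(),
    alpha: float = 0.05,
) -> VarianceDecomposition:
    """Sequential (type-I) ANOVA sums of squares per peak, scaled to 100.

    Factors enter in the declared order (interaction blocks last); each
    factor's SS is the increase in explained SS when its columns join the
    model.  Per-factor F-tests use the residual mean square; a factor is
    flagged significant when its F exceeds the 95th percentile of the
    corresponding F distribution (p < ``alpha`` with the default 0.05).
    """
    design.check_matches(table)
    sub_design = StudyDesign(design.table.loc[table.sample_ids])
    blocks = _factor_blocks(sub_design, factors, interactions)
    _check_rank(blocks, sub_design.table.index)
    names = [n for n, _ in blocks]
    mats = [b.to_numpy(dtype=float) for _, b in blocks]
    y_all = table.data.to_numpy(dtype=float)

    ss_rows, p_rows, sig_rows = [], [], []
    for j, peak in enumerate(table.peak_ids):
        y = y_all[:, j]
        obs = np.isfinite(y)
        yo = y[obs]
        n = len(yo)
        yc = yo - yo.mean()
        sst = float(yc @ yc)
        x = np.ones((n, 1))
        explained = 0.0
        prev_rank = 1
        ss_f, df_f = {}, {}
        for name, mat in zip(names, mats):
            x = np.column_stack([x, mat[obs]])
            beta, *_ = np.linalg.lstsq(x, yo, rcond=None)
            sse = float(np.sum((yo - x @ beta) ** 2))
            rank = np.linalg.matrix_rank(x)
            new_explained = sst - sse
            ss_f[name] = max(new_explained - explained, 0.0)
            df_f[name] = rank - prev_rank
            explained = new_explained
            prev_rank = rank
        ss_res = max(sst - explained, 0.0)
        df_res = n - 1 - sum(df_f.values())
        scale = 100.0 / sst if sst > 0 else np.nan
        row_ss = {name: ss_f[name] * scale for name in names}
        row_ss["residual"] = ss_res * scale
        ps, sig = {}, {}
        for name in names:
            if df_f[name] >= 1 and df_res >= 1 and ss_res > 0:
                f = (ss_f[name] / df_f[name]) / (ss_res / df_res)
                ps[name] = float(stats.f.sf(f, df_f[name], df_res))
            else:
                ps[name] = np.nan
            sig[name] = bool(ps[name] < alpha) if np.isfinite(ps[name]) else False
        row_ss["peak_id"] = ps["peak_id"] = sig["peak_id"] = peak
        ss_rows.append(row_ss)
        p_rows.append(ps)
        sig_rows.append(sig)

    scaled = pd.DataFrame(ss_rows).set_index("peak_id")
    pvals = pd.DataFrame(p_rows).set_index("peak_id")
    sigs = pd.DataFrame(sig_rows).set_index("peak_id")
    return VarianceDecomposition(scaled_ss=scaled, p_values=pvals, significant=sigs)


# ---------------------------------------------------------------------------
# moderated t (empirical Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F distribution.

    Under the hierarchical model s2 ~ s0_sq * F(df, d0), the log variances
    have known mean and excess dispersion in terms of di/trigamma functions;
    matching them yields the prior degrees of freedom ``d0`` and prior
    variance ``s0_sq``.  Returns ``(d0, s0_sq)``; ``d0`` is NaN when the
    observed dispersion is no larger than expected under a single variance
    (no information to estimate a finite prior).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if len(s2) < 2:
        return np.nan, float(np.median(s2)) if len(s2) else np.nan
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1))
    excess = evar - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        return np.nan, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t(
    table: PeakTable,
    group_a: list,
    group_b: list,
    d0_override: float | None = None,
) -> ModeratedTestResult:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Per peak the pooled two-sample variance s2 (df = nA + nB - 2) is shrunk
    toward the prior: s~2 = (d0*s0_sq + df*s2) / (d0 + df), and
    t = (meanA - meanB) / (s~ * sqrt(1/nA + 1/nB)) on df + d0 degrees of
    freedom.  ``d0_override = 0`` reproduces the ordinary pooled t exactly.
    Benjamini-Hochberg adjusted p-values are reported alongside.
    """
    missing = (set(group_a) | set(group_b)) - set(table.sample_ids)
    if missing:
        raise EquiscreenError(f"unknown sample ids: {sorted(map(str, missing))}")
    a = table.data.loc[group_a].to_numpy(dtype=float)
    b = table.data.loc[group_b].to_numpy(dtype=float)

    def _stats(m):
        obs = np.isfinite(m)
        n = obs.sum(axis=0).astype(float)
        mean = np.where(n > 0, np.nansum(np.where(obs, m, 0.0), axis=0) / np.maximum(n, 1), np.nan)
        ss = np.nansum(np.where(obs, (m - mean) ** 2, 0.0), axis=0)
        return n, mean, ss

    na, mean_a, ss_a = _stats(a)
    nb, mean_b, ss_b = _stats(b)
    valid = (na >= 2) & (nb >= 2)
    df = na + nb - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (ss_a + ss_b) / df
    s2 = np.where(valid, s2, np.nan)

    if table.n_peaks < 10:
        warnings.warn("moderated_t: fewer than 10 peaks; hyperparameter "
                      "estimation is unstable", stacklevel=2)
    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = fit_variance_prior(s2, df)
        if not np.isfinite(s0_sq):
            s0_sq = float(np.nanmedian(s2))
    else:
        d0, s0_sq = fit_variance_prior(s2, df)
        if not np.isfinite(d0):
            warnings.warn("moderated_t: prior df estimate non-finite; falling "
                          "back to ordinary t (d0 = 0)", stacklevel=2)
            d0 = 0.0
            if not np.isfinite(s0_sq):
                s0_sq = float(np.nanmedian(s2))

    with np.errstate(invalid="ignore", divide="ignore"):
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        tstat = (mean_a - mean_b) / se
    df_total = df + d0
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.where(np.isfinite(tstat), p, np.nan)
    p_adj = _benjamini_hochberg(p)
    out = pd.DataFrame({
        "mean_diff": mean_a - mean_b, "s2": s2, "s2_post": s2_post,
        "t": tstat, "df_total": df_total, "p": p, "p_adj": p_adj,
    }, index=pd.Index(table.peak_ids, name="peak_id"))
    return ModeratedTestResult(out, d0=d0, s0_sq=s0_sq)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out
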