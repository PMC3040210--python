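"""Proof-of-safety (equivalence) analysis with panel-derived margins.

Substantial-equivalence logic inverts the usual hypothesis test: the null
hypothesis is *non*-similarity, and rejecting it is evidence that a
transgenic line's metabolite level lies within the range of accepted
variation.  Acceptable deviation is not an external limit but is derived
from a panel of traditional reference cultivars: for each peak (and ripening
stage) the cultivar furthest from the control defines the margin via the
maximum absolute bound of its 90% Welch confidence interval (symmetric
mode), or all cultivars' CI bounds jointly (asymmetric mode).  Safety of a
transgenic line is then declared per peak by two one-sided Welch t-tests
(TOST) against those margins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EquiscreenError, PeakTable, StudyDesign

logger = logging.getLogger(__name__)

DEFAULT_CI_LEVEL = 0.90
DEFAULT_ALPHA = 0.05


@dataclass
class SafetyMargin:
    """Equivalence bounds for one (peak, stage), derived from the panel."""

    peak_id: object
    stage: str
    margin_low: float
    margin_high: float
    defining_cultivar: str
    ci_level: float = DEFAULT_CI_LEVEL
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.mode not in ("symmetric", "asymmetric"):
            raise EquiscreenError(f"unknown margin mode {self.mode!r}")
        if not (np.isfinite(self.margin_low) and np.isfinite(self.margin_high)):
            raise EquiscreenError("margins must be finite")
        if self.margin_low > 0 or self.margin_high < 0:
            raise EquiscreenError("margins must bracket zero (margin_low <= 0 <= margin_high)")
        if self.mode == "symmetric" and not np.isclose(self.margin_low, -self.margin_high):
            raise EquiscreenError("symmetric mode requires margin_low == -margin_high")


@dataclass
class SafetyResult:
    """TOST outcome for one (peak, line, stage)."""

    peak_id: object
    line: str
    stage: str
    mean_diff: float
    p_lower: float
    p_upper: float
    p: float
    declared_safe: bool
    margin: SafetyMargin
    degenerate_variance: bool = False
    ks_p: float = np.nan


# ---------------------------------------------------------------------------
# Welch machinery
# ---------------------------------------------------------------------------

def welch_ci(a, b, level: float = DEFAULT_CI_LEVEL):
    """Welch CI for mean(a) - mean(b) with unequal variances.

    Returns ``(delta, lo, hi, se, df)``; the Welch-Satterthwaite degrees of
    freedom are used for the t quantile.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise EquiscreenError("welch_ci requires >=2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    delta = float(np.mean(a) - np.mean(b))
    se2 = va / na + vb / nb
    se = float(np.sqrt(se2))
    if se2 > 0:
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        tq = float(stats.t.ppf(0.5 + level / 2.0, df))
        half = tq * se
    else:
        df = float(na + nb - 2)
        half = 0.0
    return delta, delta - half, delta + half, se, float(df)


def estimate_margin(
    control: np.ndarray,
    references: dict[str, np.ndarray],
    peak_id=None,
    stage: str = "",
    level: float = DEFAULT_CI_LEVEL,
    mode: str = "symmetric",
    selection: str = "delta",
) -> SafetyMargin:
    """Derive equivalence margins from the reference-cultivar panel.

    Each cultivar's mean difference from the control gets a Welch CI at
    ``level``.  Symmetric mode: the cultivar furthest from the control
    (largest absolute mean difference by default; largest absolute CI bound
    with ``selection='ci'``) defines margin_high as the maximum absolute CI
    bound, and margin_low = -margin_high.  Asymmetric mode: margin_low /
    margin_high are the extreme lower/upper CI bounds over all cultivars
    (clipped to bracket zero, as equivalence bounds must).
    """
    usable = {}
    for cultivar, values in references.items():
        vals = np.asarray(values, dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) >= 2:
            usable[cultivar] = vals
    control = np.asarray(control, dtype=float)
    control = control[np.isfinite(control)]
    if len(control) < 2:
        raise EquiscreenError("margin undefined: control has <2 replicates")
    if not usable:
        raise EquiscreenError("margin undefined: no reference cultivar with >=2 replicates")

    cis = {c: welch_ci(v, control, level=level) for c, v in usable.items()}
    if mode == "symmetric":
        if selection == "delta":
            far = max(cis, key=lambda c: abs(cis[c][0]))
        elif selection == "ci":
            far = max(cis, key=lambda c: max(abs(cis[c][1]), abs(cis[c][2])))
        else:
            raise EquiscreenError(f"unknown selection rule {selection!r}")
        _, lo, hi, _, _ = cis[far]
        high = max(abs(lo), abs(hi))
        return SafetyMargin(peak_id, stage, -high, high, far, level, "symmetric")
    # asymmetric: envelope of all cultivars' CI bounds
    lo = min(ci[1] for ci in cis.values())
    hi = max(ci[2] for ci in cis.values())
    far = max(cis, key=lambda c: abs(cis[c][0]))
    return SafetyMargin(peak_id, stage, min(lo, 0.0), max(hi, 0.0), far, level, "asymmetric")


def tost_safety(
    gm: np.ndarray,
    control: np.ndarray,
    margin: SafetyMargin,
    alpha: float = DEFAULT_ALPHA,
) -> SafetyResult:
    """Two one-sided Welch t-tests of equivalence against the margins.

    The compound null (non-safety) is delta <= margin_low OR delta >=
    margin_high; each side is tested one-sided with Welch's unequal-variance
    t, and the reported p is the larger of the two.  Safety is declared iff
    p < ``alpha``.  With zero variance in both groups the outcome reduces to
    whether the observed difference lies strictly inside the margins (p set
    to 0 or 1, flagged degenerate).
    """
    gm = np.asarray(gm, dtype=float)
    control = np.asarray(control, dtype=float)
    gm, control = gm[np.isfinite(gm)], control[np.isfinite(control)]
    if len(gm) < 2 or len(control) < 2:
        raise EquiscreenError("tost_safety requires >=2 replicates per group")
    delta, _, _, se, df = welch_ci(gm, control, level=1 - 2 * alpha)
    degenerate = se == 0.0
    if degenerate:
        inside = margin.margin_low < delta < margin.margin_high
        p_lower = 0.0 if delta > margin.margin_low else 1.0
        p_upper = 0.0 if delta < margin.margin_high else 1.0
        p = 0.0 if inside else 1.0
    else:
        t_lower = (delta - margin.margin_low) / se   # H0: delta <= margin_low
        t_upper = (delta - margin.margin_high) / se  # H0: delta >= margin_high
        p_lower = float(stats.t.sf(t_lower, df))
        p_upper = float(stats.t.cdf(t_upper, df))
        p = max(p_lower, p_upper)
    return SafetyResult(margin.peak_id, "", margin.stage, delta, p_lower,
                        p_upper, p, bool(p < alpha), margin, degenerate)


def ks_normality(residuals: np.ndarray) -> float:
    """One-sample KS p-value of standardized residuals vs the standard normal.

    A diagnostic only; it never gates the TOST.  Requires >=3 residuals.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[np.isfinite(r)]
    if len(r) < 3:
        raise EquiscreenError("ks_normality requires >=3 residuals")
    sd = np.std(r, ddof=1)
    if sd == 0:
        return 0.0
    z = (r - np.mean(r)) / sd
    return float(stats.kstest(z, "norm").pvalue)


# ---------------------------------------------------------------------------
# study-level orchestration
# ---------------------------------------------------------------------------

def run_safety(
    table: PeakTable,
    design: StudyDesign,
    alpha: float = DEFAULT_ALPHA,
    ci_level: float = DEFAULT_CI_LEVEL,
    mode: str = "symmetric",
    peaks=None,
    lines=None,
    hypothetical_panel: bool = False,
    pool_stages: bool = False,
) -> pd.DataFrame:
    """Margins + TOST for every (peak, transgenic line, ripening stage).

    Margins are derived per stage by default (``pool_stages`` merges
    stages).  With ``hypothetical_panel`` each reference cultivar is also
    tested as if it were a transgenic line of unknown safety status, with
    margins re-derived from the remaining cultivars (leave-one-out), which
    benchmarks the procedure itself.  Peaks without a usable margin are
    flagged ``margin_defined = False`` and excluded from safe-fraction
    denominators downstream.
    """
    design.check_matches(table)
    peaks = list(table.peak_ids) if peaks is None else list(peaks)
    test_lines = list(design.transgenic_lines if lines is None else lines)
    if hypothetical_panel:
        test_lines = test_lines + design.reference_cultivars
    stages = ["pooled"] if pool_stages else design.stages
    control = design.control
    cultivars = design.reference_cultivars

    def _values(genotype, stage, peak):
        ids = design.samples_of(genotype, None if stage == "pooled" else stage)
        return table.data.loc[ids, peak].to_numpy(dtype=float)

    rows = []
    for stage in stages:
        for peak in peaks:
            ctrl_vals = _values(control, stage, peak)
            panel = {c: _values(c, stage, peak) for c in cultivars}
            for line in test_lines:
                ref_panel = {c: v for c, v in panel.items() if c != line}
                try:
                    margin = estimate_margin(ctrl_vals, ref_panel, peak_id=peak,
                                             stage=stage, level=ci_level, mode=mode)
                except EquiscreenError:
                    rows.append({"peak_id": peak, "line": line, "stage": stage,
                                 "margin_defined": False, "mean_diff": np.nan,
                                 "margin_low": np.nan, "margin_high": np.nan,
                                 "p_lower": np.nan, "p_upper": np.nan, "p": np.nan,
                                 "declared_safe": False, "degenerate_variance": False,
                                 "ks_p": np.nan, "defining_cultivar": None,
                                 "role": _role_of(design, line)})
                    continue
                gm_vals = _values(line, stage, peak)
                try:
                    res = tost_safety(gm_vals, ctrl_vals, margin, alpha=alpha)
                except EquiscreenError:
                    continue
                resid = np.concatenate([gm_vals - np.nanmean(gm_vals),
                                        ctrl_vals - np.nanmean(ctrl_vals)])
                try:
                    ks_p = ks_normality(resid)
                except EquiscreenError:
                    ks_p = np.nan
                rows.append({"peak_id": peak, "line": line, "stage": stage,
                             "margin_defined": True, "mean_diff": res.mean_diff,
                             "margin_low": margin.margin_low,
                             "margin_high": margin.margin_high,
                             "p_lower": res.p_lower, "p_upper": res.p_upper,
                             "p": res.p, "declared_safe": res.declared_safe,
                             "degenerate_variance": res.degenerate_variance,
                             "ks_p": ks_p, "defining_cultivar": margin.defining_cultivar,
                             "role": _role_of(design, line)})
    return pd.DataFrame(rows)


def _role_of(design: StudyDesign, genotype: str) -> str:
    return design.table.loc[design.table["genotype"] == genotype, "role"].iloc[0]


def safety_summary(results: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Safe fractions per (line, stage) and the inconclusive-peak listing.

    The safe fraction counts only peaks with a defined margin.  A peak is
    *inconclusive* when it fails the test for at least one line and stage;
    the listing reports its observed difference and margins for follow-up.
    """
    if results.empty:
        raise EquiscreenError("no safety results to summarize")
    defined = results[results["margin_defined"]]
    summary = (defined.groupby(["line", "stage"])
               .agg(n_peaks=("peak_id", "size"),
                    n_safe=("declared_safe", "sum"),
                    safe_fraction=("declared_safe", "mean"),
                    role=("role", "first"))
               .reset_index())
    incon = defined[~defined["declared_safe"]][
        ["peak_id", "line", "stage", "mean_diff", "margin_low", "margin_high",
         "p", "degenerate_variance", "ks_p"]].copy()
    incon["fold_change_log"] = incon["mean_diff"].abs()
    return summary, incon.sort_values(["peak_id", "line", "stage"]).reset_index(drop=True)
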