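"""Method-comparison statistics for paired angle measurements.

Agreement between two ways of obtaining the same angle (mathematically
calculated vs measured on screen, observer 1 vs observer 2, repeat 1 vs
repeat 2) is quantified with Lin's concordance correlation coefficient,
Bland–Altman bias with its 95% confidence interval and paired t-test, and
a 95% tolerance interval on the differences — the range expected to
contain a single future measurement's deviation with 95% probability.

The default tolerance interval is the two-sided normal-theory interval
with 95% coverage at 95% confidence, ``bias ± k(n)·SD`` with Howe's
approximation of the tolerance factor ``k``.  Plain ``±1.96·SD`` limits
and the single-future-observation prediction interval
``± t(0.975, n−1)·SD·√(1+1/n)`` are available as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementResult",
    "ErrorSummary",
    "lin_ccc",
    "tolerance_factor",
    "bland_altman",
    "absolute_error_summary",
    "validation_report",
    "landmark_proj_a_analysis",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Reference (gold standard) and test measurements of the same items."""

    reference: np.ndarray
    test: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        r = np.asarray(self.reference, dtype=float)
        t = np.asarray(self.test, dtype=float)
        if r.shape != t.shape or r.ndim != 1:
            raise ValueError("reference and test must be 1-D of equal length")
        if len(r) < 2:
            raise ValueError("need at least 2 paired measurements")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise ValueError("paired measurements must be finite")
        object.__setattr__(self, "reference", r)
        object.__setattr__(self, "test", t)

    @property
    def n(self) -> int:
        return len(self.reference)


def _pairs(reference, test=None) -> PairedMeasurements:
    if isinstance(reference, PairedMeasurements):
        return reference
    return PairedMeasurements(reference=reference, test=test)


def lin_ccc(reference, test=None, sample_moments: bool = False) -> float:
    """Lin's concordance correlation coefficient.

    rho_c = 2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2),
    penalising both dispersion and location shift.  Uses population (1/n)
    moments by default, the original formulation; set ``sample_moments``
    for the (1/(n-1)) variant (the two differ only through the bias term).
    """
    p = _pairs(reference, test)
    x, y = p.reference, p.test
    ddof = 1 if sample_moments else 0
    vx, vy = x.var(ddof=ddof), y.var(ddof=ddof)
    if vx == 0.0 and vy == 0.0:
        raise ValueError("concordance undefined: both sequences are constant")
    cxy = np.cov(x, y, ddof=ddof)[0, 1]
    return float(2 * cxy / (vx + vy + (x.mean() - y.mean()) ** 2))


def tolerance_factor(n: int, coverage: float = 0.95, confidence: float = 0.95,
                     method: str = "howe") -> float:
    """Multiplier k of the SD for a two-sided tolerance interval on n values.

    ``howe``: normal-theory (coverage, confidence) tolerance factor,
    k = z_{(1+P)/2} * sqrt((n-1)(1+1/n) / chi2_{1-conf, n-1}) (Howe 1969).
    ``plain``: the large-sample z_{(1+P)/2} (1.96 for 95%), confidence
    ignored.  ``prediction``: t_{(1+P)/2, n-1} * sqrt(1+1/n), the single
    future observation prediction factor.
    """
    if n < 2:
        raise ValueError("tolerance factor needs n >= 2")
    z = stats.norm.ppf((1 + coverage) / 2)
    if method == "plain":
        return float(z)
    if method == "prediction":
        return float(stats.t.ppf((1 + coverage) / 2, n - 1) * np.sqrt(1 + 1 / n))
    if method == "howe":
        chi2 = stats.chi2.ppf(1 - confidence, n - 1)
        return float(z * np.sqrt((n - 1) * (1 + 1 / n) / chi2))
    raise ValueError(f"unknown tolerance method {method!r}")


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between paired measurements (all angle fields in degrees)."""

    n: int
    r_squared: float
    rho_c: float
    bias: float
    bias_ci_low: float
    bias_ci_high: float
    tl_low: float
    tl_high: float
    p_value: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "r_squared", "rho_c", "bias", "bias_ci_low",
                 "bias_ci_high", "tl_low", "tl_high", "p_value")}


def bland_altman(reference, test=None, coverage: float = 0.95,
                 confidence: float = 0.95,
                 tolerance_method: str = "howe") -> AgreementResult:
    """Bland–Altman comparison of test against reference measurements.

    Differences are ``test - reference``; the bias is their mean with a
    95% confidence interval and a two-sided paired t-test against zero;
    the tolerance limits are ``bias ± k·SD(differences)`` with ``k`` from
    :func:`tolerance_factor`.  Zero-variance differences collapse the
    limits to the bias and flag the result degenerate (p undefined).
    """
    p = _pairs(reference, test)
    if p.n < 3:
        raise ValueError("Bland-Altman analysis needs n >= 3")
    d = p.test - p.reference
    n = p.n
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    rho_c = lin_ccc(p)
    r = np.corrcoef(p.reference, p.test)[0, 1]
    r2 = float(r * r) if np.isfinite(r) else float("nan")
    if sd == 0.0:
        warnings.warn("zero-variance differences: tolerance limits collapse "
                      "to the bias and p-value is undefined", UserWarning,
                      stacklevel=2)
        return AgreementResult(n=n, r_squared=r2, rho_c=rho_c, bias=bias,
                               bias_ci_low=bias, bias_ci_high=bias,
                               tl_low=bias, tl_high=bias,
                               p_value=float("nan"), degenerate=True)
    half_ci = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    k = tolerance_factor(n, coverage, confidence, tolerance_method)
    p_value = float(stats.ttest_1samp(d, 0.0).pvalue)
    return AgreementResult(n=n, r_squared=r2, rho_c=rho_c, bias=bias,
                           bias_ci_low=bias - half_ci, bias_ci_high=bias + half_ci,
                           tl_low=bias - k * sd, tl_high=bias + k * sd,
                           p_value=p_value)


@dataclass(frozen=True)
class ErrorSummary:
    """Mean +/- SD of absolute differences |test - reference| for one group."""

    group: str
    mean_abs: float
    sd_abs: float
    n: int


def absolute_error_summary(reference, test=None, groups=None,
                           population_sd: bool = False) -> list[ErrorSummary]:
    """Grouped mean and SD of the absolute test-reference differences.

    ``groups`` assigns one label per pair (a single pooled group when
    omitted).  SD is the sample standard deviation unless
    ``population_sd``; a singleton group reports SD 0.
    """
    p = _pairs(reference, test)
    err = np.abs(p.test - p.reference)
    if groups is None:
        groups = np.array(["all"] * p.n)
    groups = np.asarray(groups)
    if groups.shape != (p.n,):
        raise ValueError("groups must assign one label per pair")
    ddof = 0 if population_sd else 1
    out = []
    for g in dict.fromkeys(groups):          # preserve first-seen order
        e = err[groups == g]
        sd = float(e.std(ddof=ddof)) if len(e) > ddof else 0.0
        out.append(ErrorSummary(group=str(g), mean_abs=float(e.mean()),
                                sd_abs=sd, n=len(e)))
    return out


# --------------------------------------------------------------------------
# validation report over the packaged gold-vs-manual table

def _table_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        for j, fam in ((0, "ProjA"), (1, "ProjA"),
                       (2, "SafA"), (3, "SafA"), (4, "SafA"), (5, "SafA")):
            rows.append({"case": r.case_id, "implant": r.implant_id,
                         "source": r.source, "observer": r.observer,
                         "repeat": r.repeat, "family": fam,
                         "angle_index": j, "value": r.angles[j]})
    return pd.DataFrame(rows)


def validation_report(records, tolerance_method: str = "howe") -> dict:
    """Reproduce the validation-table comparisons from the measurement records.

    Returns ``{"concordance": DataFrame, "absolute_errors": DataFrame}``.
    The concordance frame holds, per angle family (ProjA with 2 angles per
    implant, SafA with 4), the gold-standard-vs-single-value comparison
    (n = 96 / 192), repeat 1 vs repeat 2 and observer 1 vs observer 2.
    The absolute-error frame is the observer x repeat grid of
    mean ± SD absolute deviations from the gold standard.
    """
    records = list(records)
    df = _table_frame(records)
    n_implants = df.groupby(["case", "implant"]).ngroups
    expected = {"ProjA": n_implants * 2, "SafA": n_implants * 4}
    key = ["case", "implant", "angle_index"]

    conc_rows, err_rows = [], []
    for fam in ("ProjA", "SafA"):
        sub = df[df["family"] == fam]
        gold = sub[sub["source"] == "gold_standard"].set_index(key)["value"]
        manual = sub[sub["source"] != "gold_standard"]
        if len(gold) != expected[fam]:
            raise ValueError(f"incomplete table: expected {expected[fam]} "
                             f"gold {fam} values, got {len(gold)}")
        # gold standard vs every single manual value
        ref = gold.loc[list(manual[key].itertuples(index=False, name=None))]
        res = bland_altman(ref.to_numpy(), manual["value"].to_numpy(),
                           tolerance_method=tolerance_method)
        conc_rows.append({"family": fam, "value_1": "GS",
                          "value_2": "single", **res.as_dict()})
        # repeat 1 vs repeat 2 (within observer), observer 1 vs 2 (within repeat)
        wide = manual.pivot_table(index=key + ["observer"], columns="repeat",
                                  values="value")
        res = bland_altman(wide[1].to_numpy(), wide[2].to_numpy(),
                           tolerance_method=tolerance_method)
        conc_rows.append({"family": fam, "value_1": "rep1",
                          "value_2": "rep2", **res.as_dict()})
        wide = manual.pivot_table(index=key + ["repeat"], columns="observer",
                                  values="value")
        res = bland_altman(wide[1].to_numpy(), wide[2].to_numpy(),
                           tolerance_method=tolerance_method)
        conc_rows.append({"family": fam, "value_1": "obs1",
                          "value_2": "obs2", **res.as_dict()})
        # absolute-error grid: observer x (repeat, both)
        for obs in (1, 2):
            for rep in (1, 2, "both"):
                m = manual[manual["observer"] == obs]
                if rep != "both":
                    m = m[m["repeat"] == rep]
                ref = gold.loc[list(m[key].itertuples(index=False, name=None))]
                (summary,) = absolute_error_summary(ref.to_numpy(),
                                                    m["value"].to_numpy())
                err_rows.append({"family": fam, "observer": obs,
                                 "repeat": rep, "mean_abs": summary.mean_abs,
                                 "sd_abs": summary.sd_abs, "n": summary.n})
    return {"concordance": pd.DataFrame(conc_rows),
            "absolute_errors": pd.DataFrame(err_rows)}


# --------------------------------------------------------------------------
# landmark-placement reproducibility (quadruple analysis)

_QUAD_COLS = ["obs1_rep1", "obs1_rep2", "obs2_rep1", "obs2_rep2"]


def landmark_proj_a_analysis(quadruples: pd.DataFrame,
                             tolerance_method: str = "howe") -> dict:
    """Reproducibility of projected angles across 4 landmark placements.

    ``quadruples`` has one row per (case, site, angle) item with the four
    recomputed angle values in columns ``obs1_rep1 .. obs2_rep2`` and
    optional ``plane`` / ``frame`` label columns for subgroup analyses.
    The per-item gold standard is the mean of the four values.  Items with
    any missing value are dropped with a warning.

    Returns ``{"concordance": DataFrame, "absolute_errors": DataFrame}``:
    agreement of single values, two-observer means and two-repeat means
    against the gold standard, observer-vs-observer and repeat-vs-repeat
    comparisons (overall and per subgroup), and the corresponding
    absolute-error summaries.
    """
    missing = [c for c in _QUAD_COLS if c not in quadruples.columns]
    if missing:
        raise ValueError(f"quadruple frame is missing columns {missing}")
    q = quadruples.copy()
    bad = q[_QUAD_COLS].isna().any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} items with missing values",
                      UserWarning, stacklevel=2)
        q = q[~bad]
    if len(q) < 3:
        raise ValueError("need at least 3 complete quadruple items")
    vals = q[_QUAD_COLS].to_numpy()
    gs = vals.mean(axis=1)
    mean_obs = np.column_stack([vals[:, [0, 2]].mean(axis=1),   # rep 1 across obs
                                vals[:, [1, 3]].mean(axis=1)])  # rep 2 across obs
    mean_rep = np.column_stack([vals[:, [0, 1]].mean(axis=1),   # obs 1 across reps
                                vals[:, [2, 3]].mean(axis=1)])  # obs 2 across reps

    def _ba(ref, test, v1, v2, subgroup="all"):
        res = bland_altman(np.asarray(ref, dtype=float),
                           np.asarray(test, dtype=float),
                           tolerance_method=tolerance_method)
        return {"value_1": v1, "value_2": v2, "subgroup": subgroup,
                **res.as_dict()}

    conc = [
        _ba(np.repeat(gs, 4), vals.ravel(), "GS", "single"),
        _ba(np.repeat(gs, 2), mean_obs.ravel(), "GS", "mean_2_observers"),
        _ba(np.repeat(gs, 2), mean_rep.ravel(), "GS", "mean_2_repeats"),
        _ba(np.concatenate([vals[:, 0], vals[:, 1]]),
            np.concatenate([vals[:, 2], vals[:, 3]]), "obs1", "obs2"),
        _ba(np.concatenate([vals[:, 0], vals[:, 2]]),
            np.concatenate([vals[:, 1], vals[:, 3]]), "rep1", "rep2"),
    ]
    for label_col in ("plane", "frame"):
        if label_col not in q.columns:
            continue
        for level, idx in q.groupby(label_col).groups.items():
            sel = q.index.get_indexer(idx)
            if len(sel) < 3:
                warnings.warn(f"subgroup {label_col}={level} has fewer than 3 "
                              "items; omitted", UserWarning, stacklevel=2)
                continue
            v = vals[sel]
            conc.append(_ba(np.concatenate([v[:, 0], v[:, 1]]),
                            np.concatenate([v[:, 2], v[:, 3]]),
                            "obs1", "obs2", subgroup=f"{label_col}={level}"))
            conc.append(_ba(np.concatenate([v[:, 0], v[:, 2]]),
                            np.concatenate([v[:, 1], v[:, 3]]),
                            "rep1", "rep2", subgroup=f"{label_col}={level}"))

    err_rows = []
    for name, ref, test in (
            ("single", np.repeat(gs, 4), vals.ravel()),
            ("obs1_single", np.repeat(gs, 2), vals[:, :2].ravel()),
            ("obs2_single", np.repeat(gs, 2), vals[:, 2:].ravel()),
            ("mean_2_observers", np.repeat(gs, 2), mean_obs.ravel()),
            ("mean_2_repeats", np.repeat(gs, 2), mean_rep.ravel())):
        (s,) = absolute_error_summary(ref, test)
        err_rows.append({"comparison": name, "mean_abs": s.mean_abs,
                         "sd_abs": s.sd_abs, "n": s.n})
    return {"concordance": pd.DataFrame(conc),
            "absolute_errors": pd.DataFrame(err_rows)}
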