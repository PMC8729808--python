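"""Diagnostic performance evaluation for single- and dual-marker MSP calls.

Covers the evaluation toolbox of the pipeline:

* sensitivity / specificity at fixed decision cutoffs,
* ROC analysis — AUC by the midrank (Mann–Whitney) estimator with ½ credit
  for ties, 95% CI by DeLong's method (bootstrap available behind a flag),
  and optimal cutoff by maximizing Youden's J = sensitivity + specificity − 1,
* the hypothesis tests used on methylation data: Fisher's exact test for
  subsite sensitivity contrasts, Mann–Whitney U for group-wise comparisons,
  Wilcoxon signed-rank for paired comparisons, and McNemar's test for paired
  marker-vs-marker calls,
* a marker-comparison report contrasting SDC2, TFPI2 and the SDC2/TFPI2 OR
  combination per comparison group, indicator (Ct or ML) and tumor location.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .data_model import Group, SampleRecord, TARGET_GENES, ValidationError, records_to_frame
from .marker_screen import round_half_up
from .msp_calls import CallConfig

logger = logging.getLogger("methpanel")

__all__ = [
    "RocResult",
    "sensitivity",
    "specificity",
    "roc",
    "fisher_exact",
    "mcnemar_test",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "ReportConfig",
    "MarkerComparisonReport",
    "marker_comparison_report",
]


# --------------------------------------------------------------------------
# Rates
# --------------------------------------------------------------------------

def _rate(
    calls: pd.Series,
    records: Iterable[SampleRecord],
    group: Group | str,
    want_positive: bool,
) -> float:
    meta = records_to_frame(records)
    group = Group(group).value
    ids = meta.index[meta["group"] == group]
    sub = calls.reindex(ids).dropna()
    if len(sub) == 0:
        raise ValidationError(f"no valid called samples in group {group!r}")
    hits = sub.astype(bool) if want_positive else ~sub.astype(bool)
    return 100.0 * float(hits.sum()) / float(len(sub))


def sensitivity(calls: pd.Series, records: Iterable[SampleRecord],
                case_group: Group | str = Group.CRC) -> float:
    """Percent methylation-positive among valid case samples."""
    return _rate(calls, records, case_group, want_positive=True)


def specificity(calls: pd.Series, records: Iterable[SampleRecord],
                control_group: Group | str = Group.normal) -> float:
    """Percent methylation-negative among valid control samples."""
    return _rate(calls, records, control_group, want_positive=False)


# --------------------------------------------------------------------------
# ROC / AUC / Youden
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """AUC with 95% CI and the Youden-optimal operating point.

    Sensitivity/specificity are percentages; ``optimal_cutoff`` is on the
    original score scale, with positivity meaning score ≤ cutoff under
    ``lower_score_is_positive`` orientation and score ≥ cutoff otherwise.
    """

    auc: float
    ci_low: float
    ci_high: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    orientation: str


def _midrank(x: np.ndarray) -> np.ndarray:
    # average ranks (1-based), ties sharing the mean rank
    return scipy.stats.rankdata(x, method="average")


def _delong_auc(cases: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance for scores oriented higher = case-like."""
    m, n = len(cases), len(controls)
    all_scores = np.concatenate([cases, controls])
    tz = _midrank(all_scores)
    tx = _midrank(cases)
    ty = _midrank(controls)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n           # structural components, cases
    v10 = 1.0 - (tz[m:] - ty) / m     # structural components, controls
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc(
    scores: Sequence[float] | pd.Series,
    labels: Sequence[bool] | pd.Series,
    orientation: str = "higher_score_is_positive",
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC analysis of one scalar score against binary case/control labels.

    AUC is the probability a random case outscores a random control (ties ½).
    The optimal cutoff maximizes Youden's J over all observed score values;
    ties in J are broken toward higher sensitivity, then toward the more
    permissive cutoff.  ``ci_method`` is ``"delong"`` (default) or
    ``"bootstrap"`` (percentile, ``n_boot`` seeded resamples).
    """
    if orientation not in ("higher_score_is_positive", "lower_score_is_positive"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValidationError("scores and labels differ in length")
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if y.all() or not y.any():
        raise ValidationError("roc: need both cases and controls")
    flip = orientation == "lower_score_is_positive"
    so = -s if flip else s
    cases, controls = so[y], so[~y]

    auc, var = _delong_auc(cases, controls)
    if ci_method == "delong":
        half = 1.959963984540054 * np.sqrt(var)
        ci_low, ci_high = max(0.0, auc - half), min(1.0, auc + half)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            rc = rng.choice(cases, size=len(cases), replace=True)
            rn = rng.choice(controls, size=len(controls), replace=True)
            reps[b] = _delong_auc(rc, rn)[0]
        ci_low, ci_high = (float(np.percentile(reps, 2.5)),
                           float(np.percentile(reps, 97.5)))
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    # Youden scan over observed thresholds (rule: oriented score >= t)
    thresholds = np.unique(so)
    best = None
    for t in thresholds:
        sens = float(np.mean(cases >= t))
        spec = float(np.mean(controls < t))
        j = sens + spec - 1.0
        # more permissive = lower oriented threshold
        key = (round(j, 12), round(sens, 12), -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    _, t_opt, sens, spec = best  # type: ignore[misc]
    cutoff = -t_opt if flip else t_opt
    return RocResult(
        auc=auc,
        ci_low=ci_low,
        ci_high=ci_high,
        optimal_cutoff=float(cutoff),
        sensitivity_at_cutoff=100.0 * sens,
        specificity_at_cutoff=100.0 * spec,
        orientation=orientation,
    )


# --------------------------------------------------------------------------
# Hypothesis tests
# --------------------------------------------------------------------------

def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2×2 table (conditional hypergeometric).

    A zero margin makes the table degenerate; p = 1 by convention, with a
    logged warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact expects a nonnegative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("fisher_exact: zero margin in %s; p = 1 by convention", t.tolist())
        return 1.0
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


def mcnemar_test(table: Sequence[Sequence[int]]) -> float:
    """Exact McNemar p for paired binary calls (2×2 agreement table)."""
    res = _sm_mcnemar(np.asarray(table, dtype=int), exact=True)
    return float(res.pvalue)


_EXACT_N = 25  # exact enumeration below this per-group size, normal approx above


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test for two independent groups.

    Exact enumeration for small tie-free samples (both n ≤ 25), otherwise the
    normal approximation with tie correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney_u: empty group")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= _EXACT_N and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired measurements.

    Exact for n ≤ 25 (no zero differences/ties permitting), else normal
    approximation.  All-zero differences are an error.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("wilcoxon_signed_rank: unequal lengths")
    d = x - y
    if np.all(d == 0):
        raise ValidationError("wilcoxon_signed_rank: all paired differences are zero")
    d_nz = d[d != 0]
    method = "exact" if len(d_nz) <= _EXACT_N else "approx"
    res = scipy.stats.wilcoxon(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# Marker comparison report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportConfig:
    """Layout and thresholds of the marker-comparison report."""

    call_config: CallConfig = CallConfig()
    decimals: int = 2
    ci_method: str = "delong"
    seed: int = 0
    comparisons: tuple[tuple[str, str], ...] = (
        ("CRC", "normal"),
        ("adenoma", "normal"),
        ("CRC", "adenoma"),
    )
    marker_sets: tuple[tuple[str, ...], ...] = (
        ("SDC2",),
        ("TFPI2",),
        ("SDC2", "TFPI2"),
    )


@dataclass
class MarkerComparisonReport:
    """Two tables: overall `summary` and per-location `by_location`.

    summary columns: group, indicator, markers, auc, ci_low, ci_high,
    cutoff, sens, spec (at the Youden cutoff), sens_fixed, spec_fixed (at
    the fixed Ct cutoffs; NA for the ML indicator).
    by_location columns (per case group): group, location, n,
    sens_<gene>..., sens_dual, p_fisher_dual_vs_<anchor>,
    p_mcnemar_dual_vs_<anchor>.
    """

    summary: pd.DataFrame
    by_location: pd.DataFrame

    def write(self, out_dir: str | Path, prefix: str = "performance") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summary.to_csv(out / f"{prefix}_summary.csv", index=False, na_rep="NA")
        self.by_location.to_csv(out / f"{prefix}_by_location.csv", index=False, na_rep="NA")


def _marker_columns(markers: tuple[str, ...], indicator: str,
                    report: pd.DataFrame, config: CallConfig) -> tuple[pd.Series, pd.Series]:
    """(score, fixed-cutoff call) series for a marker set and indicator."""
    if len(markers) == 1:
        g = markers[0]
        call = report[f"call_{g}"]
        if indicator == "Ct":
            score = report[f"ct_{g}"].where(
                report[f"ct_{g}"].notna(), config.no_amp_ct_for_scoring
            )
            score = score.where(report["valid"].astype(bool), np.nan)
        else:
            score = report[f"ml_{g}"]
    else:
        call = report["call_combined"]
        score = report["score_ct"] if indicator == "Ct" else report["score_ml"]
    return score, call


def marker_comparison_report(
    report: pd.DataFrame,
    records: Iterable[SampleRecord],
    config: ReportConfig = ReportConfig(),
) -> MarkerComparisonReport:
    """Contrast single- vs dual-marker performance on one called cohort.

    ``report`` is the per-sample table from :func:`methpanel.msp_calls.call_cohort`.
    Invalid samples are excluded from every denominator.  For each comparison
    group and indicator (Ct: lower = case-like; ML: higher = case-like) the
    summary carries ROC results and fixed-cutoff rates; the per-location table
    contrasts dual vs anchor (first marker-set gene) sensitivity with Fisher's
    exact test on the independent 2×2 of detected/missed × marker set, plus
    McNemar's test acknowledging that the two calls are paired on the same
    samples.
    """
    records = list(records)
    meta = records_to_frame(records)
    valid = report[report["valid"].astype(bool)]
    dec = config.decimals

    summary_rows = []
    for case_g, control_g in config.comparisons:
        ids = [s for s in valid.index
               if s in meta.index and meta.loc[s, "group"] in (case_g, control_g)]
        sub = valid.loc[ids]
        labels = meta.loc[ids, "group"] == case_g
        for indicator, orient in (("Ct", "lower_score_is_positive"),
                                  ("ML", "higher_score_is_positive")):
            for markers in config.marker_sets:
                score, call = _marker_columns(markers, indicator, sub,
                                              config.call_config)
                rr = roc(score, labels, orientation=orient,
                         ci_method=config.ci_method, seed=config.seed)
                row = {
                    "group": f"{case_g} vs {control_g}",
                    "indicator": indicator,
                    "markers": "/".join(markers),
                    "auc": round_half_up(rr.auc, 3),
                    "ci_low": round_half_up(rr.ci_low, 3),
                    "ci_high": round_half_up(rr.ci_high, 3),
                    "cutoff": rr.optimal_cutoff,
                    "sens": round_half_up(rr.sensitivity_at_cutoff, dec),
                    "spec": round_half_up(rr.specificity_at_cutoff, dec),
                    "sens_fixed": np.nan,
                    "spec_fixed": np.nan,
                }
                if indicator == "Ct":
                    row["sens_fixed"] = round_half_up(
                        sensitivity(call, records, case_g), dec)
                    row["spec_fixed"] = round_half_up(
                        specificity(call, records, control_g), dec)
                summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    # per-location sensitivities at the fixed Ct cutoffs, dual vs anchor
    anchor = config.marker_sets[0][0]
    dual_set = max(config.marker_sets, key=len)
    genes = [g for g in TARGET_GENES if f"call_{g}" in report.columns]
    loc_rows = []
    for case_g in {c for c, _ in config.comparisons} & {"CRC", "adenoma"}:
        case_ids = [s for s in valid.index
                    if s in meta.index and meta.loc[s, "group"] == case_g]
        sub = valid.loc[case_ids]
        locs = meta.loc[case_ids, "location"]
        for loc in list(pd.unique(locs)) + ["Total"]:
            sel = sub.index if loc == "Total" else sub.index[locs == loc]
            n = len(sel)
            if n == 0:
                continue
            row: dict[str, object] = {"group": case_g, "location": loc, "n": n}
            for g in genes:
                row[f"sens_{g}"] = round_half_up(
                    100.0 * float(sub.loc[sel, f"call_{g}"].astype(bool).mean()), dec)
            dual_calls = sub.loc[sel, "call_combined"].astype(bool)
            anchor_calls = sub.loc[sel, f"call_{anchor}"].astype(bool)
            row["sens_dual"] = round_half_up(100.0 * float(dual_calls.mean()), dec)
            fisher_tab = [
                [int(dual_calls.sum()), int((~dual_calls).sum())],
                [int(anchor_calls.sum()), int((~anchor_calls).sum())],
            ]
            row[f"p_fisher_dual_vs_{anchor}"] = fisher_exact(fisher_tab)
            mc = [
                [int((dual_calls & anchor_calls).sum()),
                 int((dual_calls & ~anchor_calls).sum())],
                [int((~dual_calls & anchor_calls).sum()),
                 int((~dual_calls & ~anchor_calls).sum())],
            ]
            row[f"p_mcnemar_dual_vs_{anchor}"] = mcnemar_test(mc)
            row["markers_dual"] = "/".join(dual_set)
            loc_rows.append(row)
    by_location = pd.DataFrame(loc_rows)
    return MarkerComparisonReport(summary=summary, by_location=by_location)
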