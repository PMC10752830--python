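"""Three-group comparison and ROC-based diagnostic discrimination.

Two layers live here.  Functional primitives mirror the study design:
one-way ANOVA with Bonferroni-corrected post hoc contrasts against a
reference group (Shapiro-Wilk / Levene reported descriptively), an empirical
ROC curve over midpoint thresholds, the Mann-Whitney pair-counting AUC with
its rank-sum p-value, and Youden-J cut-off selection.

On top sits a statsmodels-style model/results pair:
:class:`AirspaceDiagnostics` is built from per-case morphometry (a DataFrame
or a list of :class:`~lungmorph.morphometry.CaseSummary`), and ``fit()``
returns a :class:`DiagnosticReport` carrying per-parameter group comparisons
and ROC results, with ``summary()``, table exports and an ROC plot.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import CaseSummary, case_summaries_frame
from .reference import DIAGNOSTIC_PARAMETERS

PARAMETER_LABELS = {
    "mean_aas_um2": "Mean AAS (um2)",
    "mean_ratio_aas_cas_um2": "Mean AAS/CAS (um2)",
    "mean_pas_percent": "Mean PAS (%)",
    "mean_max_das_um": "Maximum DAS (um)",
    "mean_min_das_um": "Minimum DAS (um)",
    "total_cas": "Mean CAS (units)",
    "mean_cas_per_field": "Mean CAS per field (units)",
}


@dataclass
class PosthocContrast:
    group: str
    reference: str
    mean_difference: float
    p_raw: float
    p_adjusted: float
    flag: str  # "ns", "*", "**"


@dataclass
class GroupComparison:
    """ANOVA + post hoc summary for one morphometric parameter."""

    parameter: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    shapiro_p: dict[str, float]
    levene_p: float
    anova_f: float
    anova_p: float
    posthoc: list[PosthocContrast]
    degenerate: bool = False


@dataclass
class RocCurve:
    """Empirical ROC points ordered by ascending threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0

    def trapezoidal_auc(self) -> float:
        # thresholds ascend, so fpr is non-increasing along the point order;
        # integrating in threshold order keeps tied-fpr runs on the curve
        fpr = 1.0 - self.specificity
        return float(-np.trapezoid(self.sensitivity, fpr))


@dataclass
class RocResult:
    """ROC discrimination of one parameter (positive group vs pooled rest)."""

    parameter: str
    auc: float
    auc_p: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int
    curve: RocCurve | None = field(default=None, repr=False)


def _flag(p: float) -> str:
    if math.isnan(p):
        return "ns"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(
    values_by_group: dict[str, np.ndarray],
    reference_group: str,
    parameter: str = "",
    all_pairs: bool = False,
) -> GroupComparison:
    """One-way ANOVA with Bonferroni post hoc contrasts.

    Post hoc contrasts use the pooled within-group variance (ANOVA mean
    square error) with N - k degrees of freedom; by default each non-reference
    group is contrasted against the reference (m = k - 1 comparisons), with
    ``all_pairs=True`` every pair is compared (m = k(k-1)/2).  Normality and
    variance-homogeneity checks are reported, never used to gate the ANOVA.
    A zero-variance input yields a degenerate result with no significance.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("compare_groups requires at least two groups")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        if np.isnan(vals).any():
            raise ValueError(f"group {name!r} contains NaN values")

    means = {k: float(v.mean()) for k, v in groups.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in groups.items()}
    ns = {k: len(v) for k, v in groups.items()}
    shapiro = {}
    for k, v in groups.items():
        try:
            shapiro[k] = float(sps.shapiro(v).pvalue) if len(v) >= 3 else math.nan
        except ValueError:
            shapiro[k] = math.nan

    allv = np.concatenate(list(groups.values()))
    if np.ptp(allv) == 0:
        return GroupComparison(
            parameter=parameter,
            group_means=means,
            group_sds=sds,
            group_ns=ns,
            shapiro_p=shapiro,
            levene_p=math.nan,
            anova_f=math.nan,
            anova_p=math.nan,
            posthoc=[
                PosthocContrast(g, reference_group, 0.0, math.nan, math.nan, "ns")
                for g in groups
                if g != reference_group
            ],
            degenerate=True,
        )

    try:
        levene_p = float(sps.levene(*groups.values()).pvalue)
    except ValueError:
        levene_p = math.nan
    f_stat, f_p = sps.f_oneway(*groups.values())

    # pooled within-group variance for post hoc t contrasts
    k = len(groups)
    n_total = sum(ns.values())
    ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_w = n_total - k
    mse = ssw / df_w
    if all_pairs:
        names = list(groups)
        pairs = [
            (names[i], names[j])
            for i in range(len(names))
            for j in range(i + 1, len(names))
        ]
    else:
        pairs = [(g, reference_group) for g in groups if g != reference_group]
    m = len(pairs)
    posthoc = []
    for a, b in pairs:
        diff = means[a] - means[b]
        if mse == 0:
            p_raw = 0.0 if diff != 0 else 1.0
        else:
            se = math.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = diff / se
            p_raw = 2.0 * float(sps.t.sf(abs(t), df_w))
        p_adj = min(1.0, m * p_raw)
        posthoc.append(PosthocContrast(a, b, diff, p_raw, p_adj, _flag(p_adj)))

    return GroupComparison(
        parameter=parameter,
        group_means=means,
        group_sds=sds,
        group_ns=ns,
        shapiro_p=shapiro,
        levene_p=levene_p,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        posthoc=posthoc,
    )


def _descriptive_comparison(
    values_by_group: dict[str, np.ndarray], reference_group: str, parameter: str
) -> GroupComparison:
    """Means/SDs only, no tests — used when a group has fewer than 2 cases."""
    means = {k: float(np.mean(v)) for k, v in values_by_group.items()}
    sds = {
        k: (float(np.std(v, ddof=1)) if len(v) > 1 else math.nan)
        for k, v in values_by_group.items()
    }
    return GroupComparison(
        parameter=parameter,
        group_means=means,
        group_sds=sds,
        group_ns={k: len(v) for k, v in values_by_group.items()},
        shapiro_p={k: math.nan for k in values_by_group},
        levene_p=math.nan,
        anova_f=math.nan,
        anova_p=math.nan,
        posthoc=[
            PosthocContrast(
                g,
                reference_group,
                means[g] - means.get(reference_group, math.nan),
                math.nan,
                math.nan,
                "ns",
            )
            for g in values_by_group
            if g != reference_group
        ],
        degenerate=True,
    )


def roc_curve(case_values: np.ndarray, control_values: np.ndarray) -> RocCurve:
    """Empirical ROC with higher marker values indicating the positive class.

    Thresholds are the midpoints between adjacent distinct pooled values plus
    -inf/+inf sentinels; sensitivity is the fraction of cases strictly above
    the threshold and specificity the fraction of controls at or below it.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both arms need at least one value")
    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if len(pooled) > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def auc(
    case_values: np.ndarray, control_values: np.ndarray
) -> tuple[float, float]:
    """Pair-counting (Mann-Whitney) AUC with ties counted 1/2, plus p vs 0.5.

    The p-value comes from the two-sided rank-sum test: exact null
    distribution when the arms are tie-free and n_cases*n_controls <= 1e6,
    otherwise the tie-corrected normal approximation.
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both arms need at least one value")
    n1, n0 = len(cases), len(controls)
    ranks = sps.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc_value = float(u / (n1 * n0))
    pooled = np.concatenate([cases, controls])
    has_ties = len(np.unique(pooled)) < len(pooled)
    # exact null only for small tie-free problems (the study scale is 6 vs
    # 12); the exact recursion is numerically unusable near 1e6 pairs
    method = "exact" if (n1 * n0 <= 10_000 and not has_ties) else "asymptotic"
    p = float(
        sps.mannwhitneyu(cases, controls, alternative="two-sided", method=method).pvalue
    )
    return auc_value, p


def choose_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Cut-off maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold.  Returns (cutoff, sensitivity, specificity).
    """
    if len(curve.thresholds) == 0:
        raise ValueError("ROC curve has no points")
    j = curve.youden()
    best = None
    for i in range(len(curve.thresholds)):
        key = (j[i], curve.sensitivity[i], -curve.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return (
        float(curve.thresholds[i]),
        float(curve.sensitivity[i]),
        float(curve.specificity[i]),
    )


# ---------------------------------------------------------------------------
# model / results layer
# ---------------------------------------------------------------------------


class AirspaceDiagnostics:
    """Diagnostic model over per-case air-space morphometry.

    Parameters
    ----------
    data:
        DataFrame with one row per case, a ``group`` column (or
        ``group_col``) and one column per morphometric parameter.
    parameters:
        Parameter columns to analyse (default: the five diagnostic
        parameters AAS, AAS/CAS, PAS, MaxDAS, MinDAS).
    reference_group:
        Group the post hoc contrasts are taken against.
    positive_group:
        Group treated as ROC-positive; all remaining groups are pooled as
        controls.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        parameters: tuple[str, ...] | None = None,
        group_col: str = "group",
        reference_group: str = "drowning",
        positive_group: str = "pbt",
        bonferroni_all_pairs: bool = False,
    ) -> None:
        if group_col not in data.columns:
            raise ValueError(f"missing group column {group_col!r}")
        self.data = data.copy()
        self.group_col = group_col
        groups = list(dict.fromkeys(data[group_col]))
        if positive_group not in groups:
            raise ValueError(f"positive group {positive_group!r} not in data")
        if len(groups) < 2:
            raise ValueError("at least two groups required")
        if reference_group not in groups:
            # two-group data without the canonical reference: fall back to
            # the first non-positive group
            reference_group = next(g for g in groups if g != positive_group)
        self.groups = groups
        self.reference_group = reference_group
        self.positive_group = positive_group
        self.bonferroni_all_pairs = bonferroni_all_pairs
        if parameters is None:
            parameters = tuple(
                p for p in DIAGNOSTIC_PARAMETERS if p in data.columns
            )
        missing = [p for p in parameters if p not in data.columns]
        if missing:
            raise ValueError(f"missing parameter columns: {missing}")
        self.parameters = tuple(parameters)

    @classmethod
    def from_case_summaries(
        cls, summaries: list[CaseSummary], **kwargs
    ) -> "AirspaceDiagnostics":
        return cls(case_summaries_frame(summaries), **kwargs)

    def fit(self) -> "DiagnosticReport":
        comparisons: dict[str, GroupComparison] = {}
        rocs: dict[str, RocResult] = {}
        for param in self.parameters:
            by_group = {
                g: self.data.loc[self.data[self.group_col] == g, param].to_numpy()
                for g in self.groups
            }
            if min(len(v) for v in by_group.values()) < 2:
                # micro-cohorts (single case per group) still get a
                # descriptive table; inference needs >=2 cases per group
                comparisons[param] = _descriptive_comparison(
                    by_group, self.reference_group, param
                )
            else:
                comparisons[param] = compare_groups(
                    by_group,
                    self.reference_group,
                    parameter=param,
                    all_pairs=self.bonferroni_all_pairs,
                )
            cases = by_group[self.positive_group]
            controls = np.concatenate(
                [by_group[g] for g in self.groups if g != self.positive_group]
            )
            curve = roc_curve(cases, controls)
            auc_value, auc_p = auc(cases, controls)
            cutoff, sens, spec = choose_cutoff(curve)
            rocs[param] = RocResult(
                parameter=param,
                auc=auc_value,
                auc_p=auc_p,
                cutoff=cutoff,
                sensitivity=sens,
                specificity=spec,
                n_cases=len(cases),
                n_controls=len(controls),
                curve=curve,
            )
        return DiagnosticReport(
            model=self, group_comparisons=comparisons, roc_results=rocs
        )


class DiagnosticReport:
    """Fitted results: per-parameter group comparisons and ROC rows."""

    def __init__(
        self,
        model: AirspaceDiagnostics,
        group_comparisons: dict[str, GroupComparison],
        roc_results: dict[str, RocResult],
    ) -> None:
        self.model = model
        self.group_comparisons = group_comparisons
        self.roc_results = roc_results
        self.pooling_note = (
            "single control group; pooled controls coincide with it"
            if len(model.groups) == 2
            else ""
        )

    # -- tables -------------------------------------------------------------

    def table_group_comparisons(self) -> pd.DataFrame:
        """Parameter x group mean (sd) table with significance flags."""
        rows = []
        for param, comp in self.group_comparisons.items():
            row: dict[str, object] = {
                "parameter": PARAMETER_LABELS.get(param, param)
            }
            flags = {c.group: c.flag for c in comp.posthoc}
            for g in self.model.groups:
                cell = f"{comp.group_means[g]:.2f} ({comp.group_sds[g]:.2f})"
                if flags.get(g, "ns") != "ns":
                    cell += f" {flags[g]}"
                row[g] = cell
            row["anova_F"] = comp.anova_f
            row["anova_p"] = comp.anova_p
            rows.append(row)
        return pd.DataFrame(rows)

    def table_roc(self) -> pd.DataFrame:
        """Parameter, AUC, cut-off, sensitivity, specificity table."""
        rows = []
        for param, r in self.roc_results.items():
            rows.append(
                {
                    "parameter": PARAMETER_LABELS.get(param, param),
                    "auc": r.auc,
                    "auc_p": r.auc_p,
                    "auc_flag": _flag(r.auc_p),
                    "cutoff": r.cutoff,
                    "sensitivity_percent": 100.0 * r.sensitivity,
                    "specificity_percent": 100.0 * r.specificity,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Air-space morphometry diagnostic report",
            "=" * 55,
            f"groups: {', '.join(self.model.groups)}"
            f" (reference: {self.model.reference_group},"
            f" positive: {self.model.positive_group})",
        ]
        if self.pooling_note:
            lines.append(f"note: {self.pooling_note}")
        lines.append("")
        lines.append("Group comparison (ANOVA + Bonferroni post hoc)")
        lines.append(self.table_group_comparisons().to_string(index=False))
        lines.append("")
        lines.append(
            f"ROC: {self.model.positive_group} vs pooled other groups"
        )
        lines.append(
            self.table_roc()
            .drop(columns=["n_cases", "n_controls"])
            .to_string(index=False)
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out: dict = {
            "groups": list(self.model.groups),
            "reference_group": self.model.reference_group,
            "positive_group": self.model.positive_group,
            "parameters": {},
        }
        if self.pooling_note:
            out["note"] = self.pooling_note
        for param in self.group_comparisons:
            comp = self.group_comparisons[param]
            r = self.roc_results[param]
            out["parameters"][param] = {
                "group_means": comp.group_means,
                "group_sds": comp.group_sds,
                "group_ns": comp.group_ns,
                "shapiro_p": comp.shapiro_p,
                "levene_p": comp.levene_p,
                "anova_f": comp.anova_f,
                "anova_p": comp.anova_p,
                "degenerate": comp.degenerate,
                "posthoc": [
                    {
                        "group": c.group,
                        "reference": c.reference,
                        "mean_difference": c.mean_difference,
                        "p_raw": c.p_raw,
                        "p_adjusted": c.p_adjusted,
                        "flag": c.flag,
                    }
                    for c in comp.posthoc
                ],
                "roc": {
                    "auc": r.auc,
                    "auc_p": r.auc_p,
                    "cutoff": r.cutoff,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "n_cases": r.n_cases,
                    "n_controls": r.n_controls,
                },
            }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def plot_roc(self, ax=None):
        """Plot the per-parameter ROC curves (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for param, r in self.roc_results.items():
            if r.curve is None:
                continue
            fpr = 1.0 - r.curve.specificity
            order = np.argsort(fpr, kind="stable")
            ax.plot(
                fpr[order],
                r.curve.sensitivity[order],
                label=f"{PARAMETER_LABELS.get(param, param)} (AUC {r.auc:.3f})",
            )
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(fontsize=7)
        return ax


def diagnostic_report(
    case_summaries: list[CaseSummary],
    positive_group: str = "pbt",
    reference_group: str = "drowning",
    parameters: tuple[str, ...] | None = None,
    bonferroni_all_pairs: bool = False,
) -> DiagnosticReport:
    """Fit the diagnostic model directly from case summaries."""
    model = AirspaceDiagnostics.from_case_summaries(
        case_summaries,
        parameters=parameters,
        reference_group=reference_group,
        positive_group=positive_group,
        bonferroni_all_pairs=bonferroni_all_pairs,
    )
    return model.fit()
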