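"""Cohort scoring: accuracy fractions, agreement statistics, report tables.

Scores a cohort of PC datasets against their static-phantom reference:
per-method net-flow accuracy, triage-classification success, regurgitation
reclassification, plus the paired-categorical statistics (McNemar, weighted
kappa) used to compare correction methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .background import (
    ConcomitantModel,
    linear_correction,
    phantom_correction,
)
from .core import AlgoParams, plane_coordinates
from .failure import TriageLabel
from .flow import (
    Vessel,
    VesselContour,
    accuracy_flag,
    compute_flow,
    judge_classification,
    phantom_qc,
)
from .pipeline import run_npccor
from .simulate import CohortDataset

__all__ = [
    "mcnemar_test",
    "weighted_kappa",
    "evaluate_cohort",
    "classification_report",
    "GRADE_ORDER",
]

GRADE_ORDER = ("none", "mild", "moderate", "severe")


def mcnemar_test(discordant_b: int, discordant_c: int) -> float:
    """McNemar's test p-value from the two discordant-pair counts.

    Exact binomial for small discordant totals (b + c < 25), continuity-
    corrected chi-square otherwise; p = 1 when there are no discordant
    pairs.
    """
    b, c = int(discordant_b), int(discordant_c)
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    if n < 25:
        res = sps.binomtest(min(b, c), n, 0.5, alternative="two-sided")
        return float(min(res.pvalue, 1.0))
    chi2 = (abs(b - c) - 1) ** 2 / n
    return float(sps.chi2.sf(chi2, df=1))


def weighted_kappa(matrix: np.ndarray, weights: str = "linear"
                   ) -> tuple[float, tuple[float, float]]:
    """Weighted Cohen's kappa with an asymptotic 95% CI.

    ``matrix[i, j]`` counts (reference grade i, method grade j) over K
    ordered categories.  Disagreement weights are |i-j|/(K-1) (linear) or
    its square (quadratic); kappa = 1 - sum(w*O)/sum(w*E) with E from the
    marginal products.  The CI uses the Fleiss-Cohen-Everitt large-sample
    variance.
    """
    O = np.asarray(matrix, dtype=float)
    if O.ndim != 2 or O.shape[0] != O.shape[1]:
        raise ValueError("confusion matrix must be square")
    n = O.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    k = O.shape[0]
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    d = np.abs(i - j) / (k - 1)
    w_dis = d if weights == "linear" else d**2 if weights == "quadratic" \
        else None
    if w_dis is None:
        raise ValueError("weights must be 'linear' or 'quadratic'")

    p = O / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    e = np.outer(row, col)
    denom = float((w_dis * e).sum())
    if denom == 0:
        warnings.warn("degenerate marginals; kappa undefined", stacklevel=2)
        return float("nan"), (float("nan"), float("nan"))
    kappa = 1.0 - float((w_dis * p).sum()) / denom

    # variance on the agreement-weight scale (v = 1 - w_dis)
    v = 1.0 - w_dis
    po_w = float((v * p).sum())
    pe_w = float((v * e).sum())
    v_row = (v * col[None, :]).sum(axis=1)   # row-conditional expected weight
    v_col = (v * row[:, None]).sum(axis=0)
    term = (v - (v_row[:, None] + v_col[None, :]) * (1 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe_w * (1 - kappa)) ** 2) \
        / (n * (1 - pe_w) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    return kappa, (kappa - 1.96 * se, kappa + 1.96 * se)


# ---------------------------------------------------------------------------
# cohort evaluation

_METHODS = ("none", "linear", "npccor")


def _grade_index(grade) -> int:
    return GRADE_ORDER.index(str(getattr(grade, "value", grade)))


def evaluate_cohort(cohort: list[CohortDataset],
                    params: AlgoParams | None = None,
                    model: ConcomitantModel | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Score every dataset of a synthetic cohort against phantom correction.

    Returns a long-format table (one row per dataset x method) and a summary
    dict: per-method accurate fractions and error medians, accuracy after
    automatic triage, per-class classification success, and regurgitation
    reclassification counts with weighted kappa.

    Datasets failing the static-phantom QC agreement check are excluded from
    the summary (their rows are kept, flagged ``qc_pass=False``).
    """
    params = params or AlgoParams()
    model = model or ConcomitantModel()
    rows = []
    for idx, ds in enumerate(cohort):
        res = run_npccor(ds.in_vivo, params, model)
        contour = VesselContour(ds.truth.vessel_mask)
        reference = phantom_correction(ds.in_vivo, ds.phantom)
        qc_roi = res.masks.union_mask if res.masks.n_static > 0 \
            else ds.truth.static_mask
        qc_pass = phantom_qc(ds.in_vivo, ds.phantom, qc_roi, params) \
            if qc_roi.any() else False

        flow_ref = compute_flow(reference, contour)
        coords = plane_coordinates(ds.in_vivo.geometry)
        variants = {"none": ds.in_vivo, "npccor": res.corrected}
        if res.masks.n_static >= 5:
            variants["linear"], _ = linear_correction(ds.in_vivo, res.masks,
                                                      coords)
        else:
            variants["linear"] = ds.in_vivo

        mean_ref = reference.velocity.mean(axis=0)
        flows = {}
        for method, series in variants.items():
            fl = compute_flow(series, contour)
            flows[method] = fl
            dv = float(np.mean(np.abs(
                series.velocity.mean(axis=0)[contour.mask]
                - mean_ref[contour.mask])))
            rel = abs(fl.net_volume - flow_ref.net_volume) \
                / abs(flow_ref.net_volume) * 100.0 \
                if flow_ref.net_volume != 0 else float("nan")
            rows.append({
                "dataset": idx,
                "scenario": ds.scenario,
                "scanner": ds.scanner,
                "method": method,
                "net_volume": fl.net_volume,
                "net_reference": flow_ref.net_volume,
                "abs_net_diff_pct": rel,
                "abs_velocity_diff": dv,
                "accurate": bool(rel <= params.accuracy_threshold * 100.0)
                if np.isfinite(rel) else False,
                "grade": fl.grade.value if fl.grade else None,
                "grade_reference": flow_ref.grade.value if flow_ref.grade
                else None,
                "label": res.label.value,
                "qc_pass": qc_pass,
            })
        success = judge_classification(
            res.label, flows["npccor"].net_volume, flows["none"].net_volume,
            flow_ref.net_volume, params) if flow_ref.net_volume != 0 else False
        for r in rows[-len(variants):]:
            r["classification_success"] = success

    table = pd.DataFrame(rows)
    summary = _summarise(table, params)
    return table, summary


def _summarise(table: pd.DataFrame, params: AlgoParams) -> dict:
    inc = table[table["qc_pass"]]
    summary: dict = {"n_datasets": int(table["dataset"].nunique()),
                     "n_included": int(inc["dataset"].nunique()),
                     "methods": {}}
    per_ds = inc[inc["method"] == "none"].set_index("dataset")

    for method in _METHODS:
        sub = inc[inc["method"] == method]
        summary["methods"][method] = {
            "accurate_fraction": float(sub["accurate"].mean()) if len(sub)
            else float("nan"),
            "median_abs_net_diff_pct": float(sub["abs_net_diff_pct"].median()),
            "iqr_abs_net_diff_pct": [
                float(sub["abs_net_diff_pct"].quantile(0.25)),
                float(sub["abs_net_diff_pct"].quantile(0.75))],
            "median_abs_velocity_diff": float(sub["abs_velocity_diff"].median()),
            "reclassified_ge1": int((sub["grade"] != sub["grade_reference"]).sum()),
        }

    # accuracy after automatic triage: drop perform-rescan, substitute the
    # uncorrected series where the triage selected it
    npc = inc[inc["method"] == "npccor"].set_index("dataset")
    unc = inc[inc["method"] == "none"].set_index("dataset")
    kept = npc[npc["label"] != TriageLabel.PERFORM_RESCAN.value]
    selected_acc = []
    selected_grades = []
    for ds_id, row in kept.iterrows():
        src = unc.loc[ds_id] if row["label"] == TriageLabel.USE_UNCORRECTED.value \
            else row
        selected_acc.append(bool(src["accurate"]))
        selected_grades.append((src["grade_reference"], src["grade"]))
    summary["triage"] = {
        "n_after_triage": int(len(kept)),
        "n_rescan": int((npc["label"] == TriageLabel.PERFORM_RESCAN.value).sum()),
        "accurate_fraction_after_triage": float(np.mean(selected_acc))
        if selected_acc else float("nan"),
        "reclassified_ge1_after_triage": int(sum(
            1 for ref, got in selected_grades if ref != got)),
    }

    # per-class classification success
    cls = {}
    for label in TriageLabel:
        sub = npc[npc["label"] == label.value]
        cls[label.value] = {
            "n": int(len(sub)),
            "success_fraction": float(sub["classification_success"].mean())
            if len(sub) else None,
        }
    summary["classification"] = cls

    # regurgitation agreement (reference grades vs per-method grades)
    kappas = {}
    for method in _METHODS:
        sub = inc[inc["method"] == method].dropna(subset=["grade",
                                                          "grade_reference"])
        if len(sub) == 0:
            continue
        mat = np.zeros((4, 4))
        for ref, got in zip(sub["grade_reference"], sub["grade"]):
            mat[_grade_index(ref), _grade_index(got)] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kap, ci = weighted_kappa(mat)
        kappas[method] = {"kappa": kap, "ci95": list(ci)}
    summary["weighted_kappa"] = kappas
    return summary


def classification_report(labels: list[str], successes: list[bool]) -> dict:
    """Per-class triage success table with a K-proportions chi-square test.

    Empty classes report ``success_fraction=None`` (undefined, not zero).
    """
    labels = [TriageLabel(lab).value for lab in labels]
    out: dict = {"per_class": {}, "overall": {}}
    counts = []
    for label in TriageLabel:
        idx = [i for i, lab in enumerate(labels) if lab == label.value]
        n = len(idx)
        s = sum(bool(successes[i]) for i in idx)
        out["per_class"][label.value] = {
            "n": n, "n_success": s,
            "success_fraction": s / n if n else None,
        }
        if n:
            counts.append([s, n - s])
    n_total = len(labels)
    s_total = sum(bool(s) for s in successes)
    out["overall"] = {"n": n_total, "n_success": s_total,
                      "success_fraction": s_total / n_total if n_total else None}
    if len(counts) >= 2 and np.asarray(counts).sum() > 0:
        arr = np.asarray(counts)
        if (arr.sum(axis=0) > 0).all():
            chi2, p, *_ = sps.chi2_contingency(arr)
            out["chi_square_p"] = float(p)
    return out
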