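"""Model/Results surface tying the analysis together.

:class:`BlinkMRIDiagnosis` is built from a per-patient table of the two
asymmetry indices (recovery-cycle AI at a chosen ISI, MRI AI) plus group
labels; ``fit()`` returns a :class:`BlinkMRIDiagnosisResults` carrying ROC
curves, Youden cutoffs, sensitivity/specificity with exact 95% CIs, the
two-marker combination (sequential rule and logistic score, side by side),
the age-adjusted logistic association, and group-comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diagnostics as dx
from . import group_stats as gs
from .asymmetry import PRIMARY_ISI
from .cohort import CohortDataset
from .errors import DataError


class BlinkMRIDiagnosis:
    """Diagnostic-accuracy model of PD-vs-CBS discrimination by asymmetry.

    Parameters
    ----------
    data : DataFrame
        One row per patient with columns ``group`` ("PD"/"CBS"),
        ``ai_r2brrc_<isi>``, ``ai_mri`` and optionally ``age`` plus further
        demographics.
    isi : int
        ISI (ms) whose recovery-cycle AI is the classification feature.
    r2brrc_cutoff, mri_cutoff : float, optional
        Fixed cutoffs; when omitted, the Youden-optimal cutoffs estimated
        from the data are used (as in the source analysis).

    Examples
    --------
    >>> from neuroasym import fixture_cohort, BlinkMRIDiagnosis
    >>> res = BlinkMRIDiagnosis.from_cohort(fixture_cohort()).fit()
    >>> round(res.metrics_r2brrc.sensitivity, 3)
    0.857
    """

    def __init__(self, data: pd.DataFrame, isi: int = PRIMARY_ISI,
                 r2brrc_cutoff: float | None = None, mri_cutoff: float | None = None):
        col = f"ai_r2brrc_{isi}"
        for c in ("group", col, "ai_mri"):
            if c not in data.columns:
                raise DataError(f"data lacks required column {c!r}")
        if set(data["group"]) != {"PD", "CBS"}:
            raise DataError("data must contain both PD and CBS patients")
        self.data = data.reset_index(drop=True)
        self.isi = isi
        self.r2brrc_cutoff = r2brrc_cutoff
        self.mri_cutoff = mri_cutoff

    @classmethod
    def from_cohort(cls, cohort: CohortDataset, isi: int = PRIMARY_ISI, **kwargs):
        return cls(cohort.to_frame(), isi=isi, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, isi: int = PRIMARY_ISI, **kwargs):
        return cls(df, isi=isi, **kwargs)

    def fit(self) -> "BlinkMRIDiagnosisResults":
        d = self.data
        ai_r2 = d[f"ai_r2brrc_{self.isi}"].to_numpy(float)
        ai_mri = d["ai_mri"].to_numpy(float)
        groups = d["group"].to_numpy()

        # PD is positive for the recovery-cycle AI, CBS for the MRI AI.
        roc_r2 = dx.empirical_roc(ai_r2, groups, positive_label="PD", direction="greater")
        roc_mri = dx.empirical_roc(ai_mri, groups, positive_label="CBS", direction="greater")
        cut_r2 = self.r2brrc_cutoff if self.r2brrc_cutoff is not None else roc_r2.youden_cutoff
        cut_mri = self.mri_cutoff if self.mri_cutoff is not None else roc_mri.youden_cutoff
        m_r2 = dx.evaluate_rule(ai_r2, groups, cut_r2, "greater", "PD")
        m_mri = dx.evaluate_rule(ai_mri, groups, cut_mri, "greater", "CBS")

        combined = {}
        for mode in ("sequential_rule", "logistic_score"):
            rule = dx.CombinedRule(r2brrc_cutoff=cut_r2, mri_cutoff=cut_mri, mode=mode)
            cres = dx.combined_classify(ai_r2, ai_mri, groups, rule)
            roc_c = dx.empirical_roc(cres.score, groups, positive_label="PD",
                                     direction="greater")
            y_pd = groups == "PD"
            pred_pd = cres.predicted == "PD"
            bm = dx.BinaryMetrics(
                tp=int(np.sum(pred_pd & y_pd)), fn=int(np.sum(~pred_pd & y_pd)),
                tn=int(np.sum(~pred_pd & ~y_pd)), fp=int(np.sum(pred_pd & ~y_pd)),
            )
            combined[mode] = {"result": cres, "roc": roc_c, "metrics": bm}

        logistic = None
        if "age" in d.columns:
            logistic = gs.fit_logistic_adjusted(groups, ai_r2, d["age"].to_numpy(float))

        continuous = [c for c in ("age", "disease_duration", "updrs_me", "hy_stage")
                      if c in d.columns]
        continuous += [f"ai_r2brrc_{self.isi}", "ai_mri"]
        categorical = [(c, lvl) for c, lvl in (("sex", "M"), ("mas_side", "right"))
                       if c in d.columns]
        comparison = gs.compare_groups(d, "group", continuous, categorical)

        return BlinkMRIDiagnosisResults(
            model=self, roc_r2brrc=roc_r2, roc_mri=roc_mri,
            r2brrc_cutoff=float(cut_r2), mri_cutoff=float(cut_mri),
            metrics_r2brrc=m_r2, metrics_mri=m_mri, combined=combined,
            logistic_age_adjusted=logistic, comparison=comparison,
        )


@dataclass
class BlinkMRIDiagnosisResults:
    """Fitted diagnostic-accuracy results; see :meth:`summary`."""

    model: BlinkMRIDiagnosis
    roc_r2brrc: dx.ROCResult
    roc_mri: dx.ROCResult
    r2brrc_cutoff: float
    mri_cutoff: float
    metrics_r2brrc: dx.BinaryMetrics
    metrics_mri: dx.BinaryMetrics
    combined: dict
    logistic_age_adjusted: gs.LogisticReport | None = None
    comparison: pd.DataFrame | None = None
    _extra: dict = field(default_factory=dict)

    @property
    def combined_logistic(self):
        return self.combined["logistic_score"]

    @property
    def combined_sequential(self):
        return self.combined["sequential_rule"]

    def metrics_frame(self) -> pd.DataFrame:
        """Headline accuracy numbers as a tidy table (percent scale)."""
        def row(name, roc, bm, cutoff):
            return {
                "marker": name, "auc": roc.auc, "cutoff": cutoff,
                "sensitivity_pct": 100 * bm.sensitivity,
                "sens_ci_low_pct": 100 * bm.sens_ci[0],
                "sens_ci_high_pct": 100 * bm.sens_ci[1],
                "specificity_pct": 100 * bm.specificity,
                "spec_ci_low_pct": 100 * bm.spec_ci[0],
                "spec_ci_high_pct": 100 * bm.spec_ci[1],
            }
        rows = [
            row(f"ai_r2brrc_{self.model.isi} (PD+)", self.roc_r2brrc,
                self.metrics_r2brrc, self.r2brrc_cutoff),
            row("ai_mri (CBS+)", self.roc_mri, self.metrics_mri, self.mri_cutoff),
        ]
        for mode, parts in self.combined.items():
            rows.append(row(f"combined:{mode}", parts["roc"], parts["metrics"], np.nan))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Blink-reflex / MRI asymmetry diagnosis (PD vs CBS)",
                 "=" * 52,
                 f"n = {len(self.model.data)} "
                 f"(PD {int((self.model.data['group'] == 'PD').sum())}, "
                 f"CBS {int((self.model.data['group'] == 'CBS').sum())}); "
                 f"classification ISI = {self.model.isi} ms",
                 ""]
        mf = self.metrics_frame().copy()
        with pd.option_context("display.float_format", lambda v: f"{v:0.3f}"):
            lines.append(mf.to_string(index=False))
        if self.logistic_age_adjusted is not None:
            lg = self.logistic_age_adjusted
            lines.append("")
            if lg.separation or lg.quasi_separation:
                lines.append("Age-adjusted logistic fit: (quasi-)complete separation "
                             "detected; Wald statistics unreliable.")
            else:
                lines.append("Age-adjusted logistic fit (diagnosis ~ AI + age):")
                tab = pd.DataFrame({"coef": lg.params, "se": lg.bse, "p": lg.p_values})
                lines.append(tab.to_string(float_format=lambda v: f"{v:0.3f}"))
        return "\n".join(lines)

    def plot_roc(self, path=None, ax=None):
        """ROC curves of both single markers and the logistic combination."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for label, roc in [
            (f"AI recovery cycle (ISI {self.model.isi}), AUC={self.roc_r2brrc.auc:0.2f}",
             self.roc_r2brrc),
            (f"AI MRI, AUC={self.roc_mri.auc:0.2f}", self.roc_mri),
            (f"combined (logistic), AUC={self.combined_logistic['roc'].auc:0.2f}",
             self.combined_logistic["roc"]),
        ]:
            ax.plot(roc.fpr, roc.tpr, marker="o", ms=3, label=label)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=120, metadata={"Software": None})
            plt.close(ax.figure)
        return ax
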