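"""Four-metric DTI quality screen with Tukey-fence outlier flagging.

Per subject:

1. mean streamline count over that subject's present edges,
2. mean FA over present edges,
3. mean cohort prevalence of the subject's present edges
   (low when the subject has "odd" connections nobody else has),
4. mean cohort prevalence of the subject's *absent* node pairs
   (high when the subject misses commonly found connections).

Edge prevalence is the fraction of cohort subjects in which an edge survives
binarization; it is a presence/absence concept, so metrics 3-4 operate on the
thresholded graphs while metrics 1-2 read the raw counts/FA.  A subject is an
outlier if any metric falls strictly below Q1 - 1.5*IQR or strictly above
Q3 + 1.5*IQR, with quartiles interpolated linearly (the "type 7" convention)
across the pooled cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import DEFAULT_MIN_STREAMLINES, StructuralConnectome, binarize

__all__ = ["QCReport", "compute_qc_metrics", "iqr_outlier_flags", "run_qc"]

METRICS = (
    "mean_streamlines",
    "mean_fa",
    "prevalence_present",
    "prevalence_absent",
)

TUKEY_K = 1.5


@dataclass
class QCReport:
    """Per-subject QC metric values, per-metric fences, and outlier flags.

    ``values`` has one row per subject and one column per metric (NaN where
    a metric is undefined, e.g. an edgeless subject).  ``fences`` maps each
    metric to (Q1, Q2, Q3, IQR, lower fence, upper fence) once flags have
    been computed.  High ``prevalence_absent`` is the suspicious direction;
    for the other three metrics both tails are suspicious and the fences
    handle the directionality symmetrically.
    """

    values: pd.DataFrame
    fences: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: pd.DataFrame | None = None

    @property
    def outlier(self) -> pd.Series:
        """Overall per-subject flag: outlying on >= 1 metric or undefined."""
        if self.flags is None:
            raise RuntimeError("flags not computed; call iqr_outlier_flags first")
        return self.flags.any(axis=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        if self.flags is not None:
            for m in METRICS:
                out[f"flag_{m}"] = self.flags[m]
            out["outlier"] = self.outlier
        return out

    def write(self, table_path: str | Path, fences_path: str | Path) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index_label="subject_id")
        Path(fences_path).write_text(json.dumps(self.fences, indent=2))


def compute_qc_metrics(
    cohort: list[StructuralConnectome],
    min_streamlines: int = DEFAULT_MIN_STREAMLINES,
) -> QCReport:
    """Compute the four QC metrics for every subject of a cohort.

    Prevalence is estimated across the *full* cohort passed in, so the
    values of one subject depend on everyone else — QC is a cohort-level
    screen, not a per-file check.
    """
    if len(cohort) < 2:
        raise ValueError("edge prevalence requires a cohort of >= 2 subjects")
    n = cohort[0].n_nodes
    for sc in cohort:
        if sc.n_nodes != n:
            raise ValueError(f"{sc.subject_id}: node count {sc.n_nodes} != {n}")

    adjs = np.stack([binarize(sc, min_streamlines).A for sc in cohort])
    prevalence = adjs.mean(axis=0)  # fraction of subjects carrying each edge
    offdiag = ~np.eye(n, dtype=bool)

    rows = {}
    for sc, A in zip(cohort, adjs):
        present = (A > 0) & offdiag
        absent = (A == 0) & offdiag
        if present.any():
            m1 = sc.streamline_counts[present].mean()
            m2 = sc.fa_weights[present].mean()
            m3 = prevalence[present].mean()
        else:  # edgeless subject: metrics undefined, flagged downstream
            m1 = m2 = m3 = np.nan
        m4 = prevalence[absent].mean() if absent.any() else np.nan
        rows[sc.subject_id] = (m1, m2, m3, m4)

    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(METRICS))
    values.index.name = "subject_id"
    return QCReport(values=values)


def iqr_outlier_flags(report: QCReport, k: float = TUKEY_K) -> QCReport:
    """Populate Tukey-fence flags on a computed QC report (in place).

    Fences are Q1 - k*IQR and Q3 + k*IQR per metric, quartiles by linear
    interpolation over the pooled sample; flagging is strict (< lower or
    > upper).  A subject with an undefined metric is flagged on that metric.
    """
    flags = pd.DataFrame(False, index=report.values.index, columns=list(METRICS))
    for m in METRICS:
        v = report.values[m]
        finite = v.dropna()
        q1, q2, q3 = np.percentile(finite, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        report.fences[m] = {
            "Q1": float(q1), "Q2": float(q2), "Q3": float(q3),
            "IQR": float(iqr), "lower": float(lo), "upper": float(hi),
        }
        flags[m] = (v < lo) | (v > hi) | v.isna()
    report.flags = flags
    return report


def run_qc(
    cohort: list[StructuralConnectome],
    min_streamlines: int = DEFAULT_MIN_STREAMLINES,
) -> QCReport:
    """Metrics plus fences in one call."""
    return iqr_outlier_flags(compute_qc_metrics(cohort, min_streamlines))
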