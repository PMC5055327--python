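"""The 50-case WHO grade 2/3 glioma cohort and its headline statistics.

The package ships the published per-case table — demographics, diagnosis,
WHO grade, IDH1 status, the two blinded radiologist readings (lesion
heterogeneity: homo/hetero; border: vague/well defined) and the three
computed image metrics (T2WI entropy in bits, Edge mean, Edge median) — as
a plain TSV fixture guarded by a checksum. ``reproduce_paper_stats`` reruns
every published comparison from it:

* pooled t-tests: entropy ~ heterogeneity, edge_mean ~ border,
  edge_median ~ border, entropy ~ IDH1, plus the two null findings
  (edge_mean ~ IDH1, edge_median ~ IDH1);
* ROC analyses: entropy ~ heterogeneity, edge_mean ~ border,
  edge_median ~ border, entropy ~ IDH1.

Direction conventions make the published differences positive:
(hetero - homo), (well defined - vague), (mutant - wild type); the same
class is "positive" in each ROC, with higher metric predicting it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataIntegrityError
from .stats import ROCResult, TTestResult, roc_auc, two_sample_ttest

__all__ = [
    "CohortRecord",
    "StatReport",
    "load_cohort",
    "cohort_dataframe",
    "reproduce_paper_stats",
]

_FIXTURE = "cohort.tsv"
_FIXTURE_SHA256 = "05d4aecfff8093a41822097320db97cd8c3947cd64a4e6aae6cd4dee7dabdf14"

N_CASES = 50
N_GRADE2 = 22
N_GRADE3 = 28

TTEST_COMPARISONS = (
    ("entropy~heterogeneity", "entropy", "heterogeneity_label", "hetero"),
    ("edge_mean~border", "edge_mean", "border_label", "well defined"),
    ("edge_median~border", "edge_median", "border_label", "well defined"),
    ("entropy~idh", "entropy", "idh_status", "mt"),
    ("edge_mean~idh", "edge_mean", "idh_status", "mt"),
    ("edge_median~idh", "edge_median", "idh_status", "mt"),
)
ROC_COMPARISONS = (
    ("entropy~heterogeneity", "entropy", "heterogeneity_label", "hetero"),
    ("edge_mean~border", "edge_mean", "border_label", "well defined"),
    ("edge_median~border", "edge_median", "border_label", "well defined"),
    ("entropy~idh", "entropy", "idh_status", "mt"),
)
# exploratory comparisons published as negative results
NULL_FINDINGS = ("edge_mean~idh", "edge_median~idh")


@dataclass(frozen=True)
class CohortRecord:
    case_id: int
    age: int
    sex: str  # M / F
    diagnosis: str  # DA/GG/OA/OL/AA/AO/AOA
    grade: int  # WHO grade 2 or 3
    idh_status: str  # wt / mt
    heterogeneity_label: str  # homo / hetero (blinded radiologist)
    border_label: str  # vague / well defined (blinded radiologist)
    entropy: float  # T2WI Shannon entropy, bits
    edge_mean: float
    edge_median: float


@dataclass(frozen=True)
class StatReport:
    """All cohort comparisons, keyed by '<metric>~<grouping>'."""

    ttests: Mapping[str, TTestResult]
    rocs: Mapping[str, ROCResult]

    def to_records(self) -> list[dict]:
        """Flatten to one row per analysis (t-tests first, then ROCs)."""
        rows = []
        for name, t in self.ttests.items():
            rows.append(
                {
                    "analysis": name,
                    "kind": "ttest",
                    "n1": t.n1,
                    "n2": t.n2,
                    "estimate": t.mean_difference,
                    "ci95_low": t.ci95[0],
                    "ci95_high": t.ci95[1],
                    "statistic": t.t_statistic,
                    "p": t.p_two_sided,
                    "significant": t.significant,
                }
            )
        for name, r in self.rocs.items():
            rows.append(
                {
                    "analysis": name,
                    "kind": "roc",
                    "n1": r.n_positive,
                    "n2": r.n_negative,
                    "estimate": r.auc,
                    "ci95_low": r.ci95[0],
                    "ci95_high": r.ci95[1],
                    "statistic": r.se,
                    "p": r.p_vs_half,
                    "significant": r.significant,
                }
            )
        return rows

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())


def _fixture_text() -> str:
    text = resources.files("t2texture").joinpath(f"data/{_FIXTURE}").read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise DataIntegrityError(
            f"cohort fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    return text


def cohort_dataframe() -> pd.DataFrame:
    """The cohort table as a DataFrame (checksum-verified)."""
    from io import StringIO

    frame = pd.read_csv(StringIO(_fixture_text()), sep="\t")
    if len(frame) != N_CASES:
        raise DataIntegrityError(f"expected {N_CASES} cases, found {len(frame)}")
    grade_counts = frame["grade"].value_counts().to_dict()
    if grade_counts.get(2) != N_GRADE2 or grade_counts.get(3) != N_GRADE3:
        raise DataIntegrityError(f"unexpected WHO grade counts: {grade_counts}")
    return frame


def load_cohort() -> list[CohortRecord]:
    """All 50 published cases as typed records."""
    frame = cohort_dataframe()
    return [CohortRecord(**row) for row in frame.to_dict(orient="records")]


def reproduce_paper_stats(records: Iterable[CohortRecord] | None = None) -> StatReport:
    """Re-run every published cohort comparison.

    Accepts the record list (order-insensitive) or, by default, loads the
    packaged cohort.
    """
    if records is None:
        frame = cohort_dataframe()
    else:
        frame = pd.DataFrame([vars(r) for r in records])
        if len(frame) != N_CASES:
            raise DataIntegrityError(f"expected {N_CASES} cases, found {len(frame)}")

    ttests = {}
    for name, metric, label, positive in TTEST_COMPARISONS:
        in_group = frame[label] == positive
        ttests[name] = two_sample_ttest(
            frame.loc[in_group, metric], frame.loc[~in_group, metric]
        )
    rocs = {}
    for name, metric, label, positive in ROC_COMPARISONS:
        rocs[name] = roc_auc(frame[metric], frame[label] == positive)
    return StatReport(ttests=ttests, rocs=rocs)
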