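"""Cohort-level aggregation of patient switch profiles.

Two views of the same profiles:

* a cohort summary of per-term *occurrence* — a term counts once per
  patient per direction regardless of how many SNPs support it — with the
  percentage difference pct_disease − pct_healthy classifying each term as
  overall gained (> 0), lost (< 0) or both (= 0 with occurrences on both
  sides);
* a patient × (feature, direction) count matrix for clustering, where the
  value is the number of the patient's active SNPs supporting that
  direction, plus a per-column standardized copy (zero-variance columns
  excluded from scaling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .switches import PatientSwitchProfile

log = logging.getLogger(__name__)


def summarize_cohort(profiles: Sequence[PatientSwitchProfile]) -> pd.DataFrame:
    """Per-term gain/loss occurrence percentages over a cohort.

    A patient counts toward pct_disease for a term when the term's state is
    gained or both, and toward pct_healthy when lost or both. Terms absent
    from every profile are omitted. Columns: term, pct_disease,
    pct_healthy, pct_diff, classification.
    """
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    terms = sorted({t for p in profiles for t in p.term_states})
    rows = []
    for term in terms:
        dis = sum(1 for p in profiles if p.term_states.get(term) in ("gained", "both"))
        hea = sum(1 for p in profiles if p.term_states.get(term) in ("lost", "both"))
        pct_d, pct_h = 100.0 * dis / n, 100.0 * hea / n
        diff = pct_d - pct_h
        if diff > 0:
            cls = "gained"
        elif diff < 0:
            cls = "lost"
        elif dis > 0:  # equal nonzero occurrence on both sides
            cls = "both"
        else:
            cls = "none"
        rows.append((term, pct_d, pct_h, diff, cls))
    return pd.DataFrame(
        rows, columns=["term", "pct_disease", "pct_healthy", "pct_diff",
                       "classification"],
    )


@dataclass
class FeatureMatrix:
    """Patient × (feature, direction) SNP-support counts plus a scaled copy."""

    counts: pd.DataFrame          # integer counts, columns "<feature>|<direction>"
    scaled: pd.DataFrame          # standardized, zero-variance columns dropped
    dropped_columns: list[str] = field(default_factory=list)


def build_feature_matrix(
    profiles: Sequence[PatientSwitchProfile],
    feature_kind: str = "GO",
) -> FeatureMatrix:
    """Count, per patient, the active SNPs supporting each gained/lost
    feature (GO term or TF). Column order is sorted, hence deterministic."""
    if not profiles:
        raise ValueError("no profiles")
    if feature_kind not in ("GO", "TF"):
        raise ValueError("feature_kind must be GO or TF")
    attr = "term_support" if feature_kind == "GO" else "tf_support"
    columns = sorted({
        f"{feat}|{direction}"
        for p in profiles for (feat, direction) in getattr(p, attr)
    })
    index = [p.patient_id for p in profiles]
    mat = np.zeros((len(profiles), len(columns)), dtype=int)
    col_idx = {c: j for j, c in enumerate(columns)}
    for i, p in enumerate(profiles):
        for (feat, direction), rsids in getattr(p, attr).items():
            mat[i, col_idx[f"{feat}|{direction}"]] = len(rsids)
    counts = pd.DataFrame(mat, index=index, columns=columns)
    variances = counts.var(axis=0, ddof=0)
    dropped = [c for c in columns if variances[c] == 0]
    if dropped:
        log.info("excluding %d zero-variance column(s) from scaling: %s",
                 len(dropped), dropped[:10])
    keep = counts.drop(columns=dropped)
    scaled = (keep - keep.mean()) / keep.std(ddof=0) if len(keep.columns) else keep
    return FeatureMatrix(counts=counts, scaled=scaled, dropped_columns=dropped)
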