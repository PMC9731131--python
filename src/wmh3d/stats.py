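"""One-way ANOVA across clusters with Bonferroni-style pairwise reporting.

Raw pairwise p-values are reported alongside the Bonferroni significance
thresholds ``alpha / n_pairs`` (and a stricter ``alpha_high / n_pairs``),
mirroring how multiple-comparison results are usually tabulated in this
literature; Bonferroni-adjusted p-values are included for convenience.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "anova_by_cluster"]


@dataclass
class AnovaResult:
    F: float
    p: float
    groups: list
    pairwise: pd.DataFrame
    bonferroni_threshold: float
    bonferroni_threshold_high: float
    excluded: list


def anova_by_cluster(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = 0.05,
    alpha_high: float = 0.01,
) -> AnovaResult:
    """One-way ANOVA of ``values`` across cluster labels plus all pairwise
    two-group F tests.  Groups with fewer than 2 members are excluded."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, excluded, samples = [], [], []
    for g in np.unique(groups):
        v = values[groups == g]
        if v.size < 2:
            excluded.append(g)
            continue
        labels.append(g)
        samples.append(v)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups with >= 2 members")
    f, p = sps.f_oneway(*samples)
    pairs = list(combinations(range(len(labels)), 2))
    thr = alpha / len(pairs)
    thr_high = alpha_high / len(pairs)
    rows = []
    for i, j in pairs:
        fij, pij = sps.f_oneway(samples[i], samples[j])
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "F": float(fij),
                "p": float(pij),
                "p_bonferroni": float(min(pij * len(pairs), 1.0)),
                "significant": pij < thr,
                "highly_significant": pij < thr_high,
            }
        )
    return AnovaResult(
        F=float(f),
        p=float(p),
        groups=labels,
        pairwise=pd.DataFrame(rows),
        bonferroni_threshold=thr,
        bonferroni_threshold_high=thr_high,
        excluded=excluded,
    )
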