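"""Technical repeatability from split-lysate subsample pairs.

Each split sample is one lysate partitioned into two subsamples that are
amplified and sequenced independently. A mutation called in both
subsamples is a concordant true positive; a call in only one subsample is
a false positive if no other sample of the flower supports it, and a
false negative (in the subsample lacking it) if the flower does. The
qualitative summary is the concordance rate over all (mutation, pair)
comparisons; the quantitative summary is an orthogonal (Deming)
regression of the paired VAF estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "find_split_pairs",
    "classify_calls",
    "concordance_rate",
    "deming_fit",
    "split_qc_summary",
]

MATCH, FALSE_POSITIVE, FALSE_NEGATIVE, EXCLUDED = (
    "match", "false_positive", "false_negative", "excluded",
)


def find_split_pairs(metadata: pd.DataFrame) -> dict[str, tuple[str, str]]:
    """Map split-group id -> (subsample a, subsample b) from the metadata
    ``split_group`` / ``subsample`` columns."""
    pairs = {}
    split = metadata[metadata["split_group"].notna()]
    for group, rows in split.groupby("split_group"):
        subs = rows.sort_values("subsample")
        if len(subs) != 2:
            raise ValueError(f"split group {group!r} has {len(subs)} subsamples, need 2")
        pairs[group] = (subs.index[0], subs.index[1])
    return pairs


def classify_calls(
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
    pairs: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Label every (mutation, split pair) comparison.

    ``presence`` is the 1/0/NaN presence matrix over all samples of the
    flower. Both subsamples present or both absent -> match. Present in
    exactly one: false positive when the mutation is seen nowhere else in
    the flower, false negative otherwise. Comparisons where either
    subsample is missing (no coverage) are excluded from the denominator.
    """
    if pairs is None:
        pairs = find_split_pairs(metadata)
    rows = []
    for group, (a, b) in pairs.items():
        flower = metadata.loc[a, "flower"]
        flower_samples = metadata.index[
            (metadata["flower"] == flower) & (~metadata.index.isin([a, b]))
        ]
        others = presence[[s for s in flower_samples if s in presence.columns]]
        for mut in presence.index:
            ca, cb = presence.loc[mut, a], presence.loc[mut, b]
            if np.isnan(ca) or np.isnan(cb):
                label = EXCLUDED
            elif ca == cb:
                label = MATCH
            else:
                supported = bool((others.loc[mut] == 1.0).any())
                label = FALSE_NEGATIVE if supported else FALSE_POSITIVE
            rows.append(dict(mutation=mut, pair=group, a=a, b=b, label=label))
    return pd.DataFrame(rows)


def concordance_rate(labels) -> dict:
    """Percent of comparisons that match, with the count arithmetic.

    Accepts the frame from :func:`classify_calls` or raw (matches, total)
    counts. The denominator is mutations x pairs minus excluded
    comparisons.
    """
    if isinstance(labels, tuple):
        matches, total = labels
    else:
        counted = labels[labels["label"] != EXCLUDED]
        matches = int((counted["label"] == MATCH).sum())
        total = len(counted)
    if total == 0:
        raise ValueError("no scorable comparisons")
    return {
        "matches": int(matches),
        "total": int(total),
        "concordance_pct": 100.0 * matches / total,
    }


@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float
    r_squared_pct: float
    p_value: float
    n: int


def deming_fit(x, y, error_ratio: float = 1.0) -> DemingFit:
    """Orthogonal (Deming) regression of paired VAF estimates.

    Fits the line minimising perpendicular residuals under an assumed
    error-variance ratio ``delta = var(err_y)/var(err_x)`` (1 by default:
    both subsamples measured the same way). Closed form:

        slope = (syy - delta*sxx + sqrt((syy - delta*sxx)^2 + 4*delta*sxy^2))
                / (2*sxy)

    ``r_squared_pct`` is 100 * (Pearson r)^2 and the p-value comes from
    the Pearson correlation test, matching how such fits are usually
    annotated; the orthogonal-residual alternative is a caller-side
    choice of reporting, not of the fitted line.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 paired values, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: orthogonal fit undefined")
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    d = error_ratio
    if sxy == 0:
        raise ValueError("zero covariance: orthogonal fit undefined")
    slope = (syy - d * sxx + np.sqrt((syy - d * sxx) ** 2 + 4 * d * sxy**2)) / (
        2 * sxy
    )
    intercept = y.mean() - slope * x.mean()
    r, p = stats.pearsonr(x, y)
    return DemingFit(
        slope=float(slope), intercept=float(intercept),
        r_squared_pct=float(100.0 * r * r), p_value=float(p), n=n,
    )


def split_qc_summary(
    vaf: pd.DataFrame,
    presence: pd.DataFrame,
    metadata: pd.DataFrame,
) -> dict:
    """Qualitative + quantitative repeatability for all split pairs.

    Returns the classification frame, the concordance arithmetic, and a
    combined Deming fit of subsample-a versus subsample-b VAFs pooled over
    all (mutation, pair) observations with coverage in both subsamples.
    """
    pairs = find_split_pairs(metadata)
    if not pairs:
        raise ValueError("metadata defines no split pairs")
    labels = classify_calls(presence, metadata, pairs)
    xs, ys = [], []
    for group, (a, b) in pairs.items():
        va, vb = vaf[a], vaf[b]
        keep = va.notna() & vb.notna()
        xs.append(va[keep].to_numpy())
        ys.append(vb[keep].to_numpy())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    fit = deming_fit(x, y) if np.ptp(x) > 0 and np.ptp(y) > 0 else None
    return {
        "labels": labels,
        "concordance": concordance_rate(labels),
        "deming": fit,
        "n_pairs": len(pairs),
        "n_mutations": int(presence.shape[0]),
    }
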