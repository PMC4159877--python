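"""Correlation screening of descriptors against activity.

Candidate descriptors are screened one at a time by Pearson correlation
with the experimental activity; two-sided p-values come from the exact
t-transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom.  No
multiple-testing correction is applied across the descriptor grid (each
result carries a ``note`` field so users can adjust externally).
Because electronegativity and chemical potential are exact negatives of
each other (chi = -mu), one of any such perfectly collinear pair is
redundant and can be eliminated before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "ConstantInputError",
    "pearson",
    "screen_descriptors",
    "eliminate_collinear",
    "correlation_report",
]


class ConstantInputError(ValueError):
    """Correlation is undefined for a zero-variance vector."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one descriptor column with activity."""

    descriptor_id: str
    r: float
    p: float
    n: int
    stars: str = ""
    note: str = ""

    @property
    def failed(self) -> bool:
        return bool(self.note) and np.isnan(self.r)


def pearson(x: Sequence[float], y: Sequence[float], descriptor_id: str = "") -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value.

    Requires equal-length vectors of at least 3 points, neither constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"length mismatch: x has shape {x.shape}, y has shape {y.shape}"
        )
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(
            "correlation undefined for a constant vector"
        )
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        descriptor_id=descriptor_id,
        r=float(res.statistic),
        p=float(res.pvalue),
        n=int(x.size),
    )


def screen_descriptors(
    features: pd.DataFrame,
    activity: Sequence[float],
    alpha_strict: float = 0.01,
    alpha_loose: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate every feature column with activity and annotate significance.

    Star levels: ``**`` for p < ``alpha_strict``, ``*`` for p <
    ``alpha_loose``.  Columns where the correlation is undefined (e.g.
    constant) are reported with ``r = nan`` and the error message in
    ``note`` instead of aborting the scan.  Results keep column order;
    sort by ``abs(res.r)`` for a strength ranking.
    """
    if not alpha_strict < alpha_loose:
        raise ValueError(
            f"alpha_strict ({alpha_strict}) must be below alpha_loose ({alpha_loose})"
        )
    y = np.asarray(activity, dtype=float)
    out: list[CorrelationResult] = []
    for col in features.columns:
        try:
            res = pearson(features[col].to_numpy(), y, descriptor_id=str(col))
        except (ConstantInputError, ValueError) as exc:
            out.append(
                CorrelationResult(
                    descriptor_id=str(col), r=float("nan"), p=float("nan"),
                    n=int(y.size), note=str(exc),
                )
            )
            continue
        stars = "**" if res.p < alpha_strict else ("*" if res.p < alpha_loose else "")
        out.append(
            CorrelationResult(
                descriptor_id=res.descriptor_id, r=res.r, p=res.p, n=res.n,
                stars=stars,
            )
        )
    return out


def eliminate_collinear(
    selected: Sequence[str],
    features: pd.DataFrame,
    r2_threshold: float = 1.0,
) -> list[str]:
    """Greedily drop descriptors pairwise-collinear with an earlier pick.

    ``selected`` is assumed ranked (strongest first); a later descriptor
    is removed when its squared Pearson correlation with any survivor
    reaches ``r2_threshold``.  At the default threshold of 1 only exact
    duplicates and negations (such as chemical potential given
    electronegativity) are removed.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    kept: list[str] = []
    # tiny slack so exact negations hit an r2 of 1 despite float rounding
    eps = 1e-12
    for name in selected:
        x = features[name].to_numpy(dtype=float)
        redundant = False
        for prev in kept:
            r = np.corrcoef(features[prev].to_numpy(dtype=float), x)[0, 1]
            if r * r >= r2_threshold - eps:
                redundant = True
                break
        if not redundant:
            kept.append(name)
    return kept


def correlation_report(results: Sequence[CorrelationResult]) -> str:
    """Plain-text screening report, one descriptor per row."""
    lines = [f"{'descriptor':<16} {'r':>8} {'p':>10} {'n':>4}  sig"]
    for res in results:
        if res.failed:
            lines.append(f"{res.descriptor_id:<16} {'--':>8} {'--':>10} {res.n:>4}  [{res.note}]")
        else:
            lines.append(
                f"{res.descriptor_id:<16} {res.r:>8.3f} {res.p:>10.4g} {res.n:>4}  {res.stars}"
            )
    lines.append("")
    lines.append("*, ** : p below the loose / strict significance level")
    lines.append("note: p-values are not adjusted for multiple comparisons")
    return "\n".join(lines)
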