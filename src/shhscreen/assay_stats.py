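"""Statistics for the secondary differentiation and viability assays.

The osteoblast-differentiation readout (alkaline-phosphatase absorbance) is
median-centered per plate exactly like the luciferase ratios, then each
cDNA is compared to the control by a Kruskal-Wallis test followed by Dunn's
post-hoc z (tie-corrected, two-sided normal p).  The unadjusted p-values
are corrected by the two-stage linear step-up false-discovery-rate
procedure of Benjamini, Krieger and Yekutieli (BKY), and viability time
courses are summarized by trapezoidal area under the curve.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssayError
from .plate_screen import median_center

logger = logging.getLogger(__name__)


def normalize_assay_plate(values: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Median-center single-channel absorbance per plate.

    Same contract as the luciferase plate centering: each plate's values are
    divided by the plate median; a zero or non-finite median raises an error
    naming the plate.  Expects a long-format frame with ``plate`` and
    ``value`` columns; adds a ``normalized`` column.
    """
    return median_center(values, value_col=value_col)


def kw_dunn_vs_control(
    groups: Mapping[str, Sequence[float]] | pd.DataFrame,
    control: str,
    value_col: str = "normalized",
) -> pd.DataFrame:
    """Kruskal-Wallis test with Dunn's post-hoc comparisons versus control.

    The global tie-corrected H statistic is computed over all groups; each
    cDNA is then compared to the control on the pooled ranks:

        z = (Rbar_control - Rbar_cdna) /
            sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_c + 1/n_i) )

    with T = sum(t^3 - t) over tie groups, and a two-sided p from the
    standard normal.  p-values are emitted unadjusted; FDR control is
    applied downstream.  Because only ranks enter, any strictly monotone
    transform of the values leaves every p unchanged.

    Parameters
    ----------
    groups : mapping or DataFrame
        Either ``{cdna: values}`` or a long DataFrame with ``cdna`` and
        value columns.
    control : str
        Group to compare everything against.

    Returns
    -------
    DataFrame indexed by cdna (control excluded) with columns ``n``,
    ``mean_rank``, ``dunn_z``, ``p``, plus attrs ``kw_h`` and ``kw_p``.
    """
    if isinstance(groups, pd.DataFrame):
        groups = {k: g[value_col].to_numpy(dtype=float) for k, g in groups.groupby("cdna")}
    else:
        groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if control not in groups:
        raise AssayError(f"control group '{control}' not present")
    if len(groups) < 2:
        raise AssayError("need at least two groups")
    for k, v in groups.items():
        if len(v) < 2:
            raise AssayError(f"group '{k}' has fewer than 2 observations")
        if not np.isfinite(v).all():
            raise AssayError(f"group '{k}' contains non-finite values")

    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    if np.all(pooled == pooled[0]):
        raise AssayError("all observations tied across all groups; H undefined")
    kw_h, kw_p = stats.kruskal(*[groups[k] for k in names])

    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for k in names:
        n_k = len(groups[k])
        mean_ranks[k] = float(ranks[offset:offset + n_k].mean())
        sizes[k] = n_k
        offset += n_k

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term

    records = []
    n_c = sizes[control]
    for k in names:
        if k == control:
            continue
        se = np.sqrt(var_unit * (1.0 / n_c + 1.0 / sizes[k]))
        z = (mean_ranks[control] - mean_ranks[k]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        records.append({"cdna": k, "n": sizes[k], "mean_rank": mean_ranks[k],
                        "dunn_z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(records).set_index("cdna")
    out.attrs["kw_h"] = float(kw_h)
    out.attrs["kw_p"] = float(kw_p)
    out.attrs["control_mean_rank"] = mean_ranks[control]
    return out


# ---------------------------------------------------------------------------
# two-stage FDR (Benjamini-Krieger-Yekutieli)
# ---------------------------------------------------------------------------

def _bh_n_rejections(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear step-up (BH) procedure at
    ``level`` on ascending-sorted p-values."""
    m = len(p_sorted)
    crit = level * np.arange(1, m + 1) / m
    below = np.nonzero(p_sorted <= crit)[0]
    return 0 if below.size == 0 else int(below[-1]) + 1


def bky_reject(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Boolean rejection vector of the BKY two-stage step-up procedure.

    Stage 1 runs the linear step-up procedure at the adjusted level
    alpha' = alpha/(1+alpha) to estimate the number of true nulls
    m0 = m - r1; stage 2 reruns the step-up at level alpha' * m / m0.
    r1 = 0 rejects nothing, r1 = m rejects everything.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise AssayError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise AssayError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    alpha1 = alpha / (1.0 + alpha)
    r1 = _bh_n_rejections(p_sorted, alpha1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    r2 = _bh_n_rejections(p_sorted, alpha1 * m / (m - r1))
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject


def bky_fdr(pvalues, alpha: float = 0.1, q_tol: float = 1e-6) -> pd.DataFrame:
    """Two-stage BKY FDR control with q-values.

    ``significant`` is the exact two-stage rejection decision at ``alpha``.
    The q-value of each p is the smallest level at which the two-stage
    procedure rejects it, found by bisection to ``q_tol`` and made monotone
    non-decreasing in p.  Only threshold behavior of q is load-bearing
    downstream (calls at q < 0.1 or q < 0.05).

    Accepts a sequence of p-values or a Series; returns a DataFrame with
    columns ``p``, ``q``, ``significant`` (index preserved for Series
    input).
    """
    index = pvalues.index if isinstance(pvalues, pd.Series) else None
    p = np.asarray(pvalues, dtype=float)
    significant = bky_reject(p, alpha)

    q = np.ones(p.size)
    for i in range(p.size):
        lo, hi = 0.0, 1.0
        # rejection is monotone in alpha in practice; bisect the smallest
        # level at which p[i] enters the rejection set
        if not bky_reject(p, 1.0 - q_tol)[i]:
            q[i] = 1.0
            continue
        while hi - lo > q_tol:
            mid = 0.5 * (lo + hi)
            if bky_reject(p, mid)[i]:
                hi = mid
            else:
                lo = mid
        q[i] = hi
    # enforce monotonicity in p
    order = np.argsort(p, kind="stable")
    q_sorted = np.maximum.accumulate(q[order])
    q[order] = q_sorted
    out = pd.DataFrame({"p": p, "q": q, "significant": significant})
    if index is not None:
        out.index = index
    return out


def viability_auc(timepoints: Sequence[float], values: Sequence[float]) -> float:
    """Trapezoidal area under a viability time course.

    Points are sorted by time first; duplicate timepoints raise an error.
    Requires at least two timepoints.
    """
    t = np.asarray(timepoints, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise AssayError("timepoints and values must have equal length")
    if t.size < 2:
        raise AssayError("need at least two timepoints for AUC")
    order = np.argsort(t)
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise AssayError("duplicate timepoints in viability series")
    return float(np.trapezoid(v, t))


def auc_by_group(
    measurements: pd.DataFrame,
    group_cols: Sequence[str] = ("cdna",),
    time_col: str = "timepoint_h",
    value_col: str = "value",
) -> pd.DataFrame:
    """AUC per group (e.g. per cDNA or per cDNA x replicate) from a long
    table of viability measurements."""
    records = []
    for key, g in measurements.groupby(list(group_cols)):
        key = key if isinstance(key, tuple) else (key,)
        records.append(
            dict(zip(group_cols, key)) | {"auc": viability_auc(g[time_col], g[value_col])}
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------

class DifferentiationAssay:
    """Plate-based differentiation assay (alkaline-phosphatase absorbance).

    Parameters
    ----------
    measurements : DataFrame
        Long format with columns ``plate``, ``cdna``, ``value`` (and
        optionally ``treatment``).
    control : str
        Control cDNA compared against all others.
    """

    REQUIRED = ("plate", "cdna", "value")

    def __init__(self, measurements: pd.DataFrame, control: str = "GFP"):
        missing = [c for c in self.REQUIRED if c not in measurements.columns]
        if missing:
            raise AssayError(f"measurement table missing columns: {missing}")
        if not np.isfinite(measurements["value"]).all():
            raise AssayError("non-finite assay values")
        self.measurements = measurements
        self.control = control

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DifferentiationAssay":
        return cls(pd.read_csv(path), **kwargs)

    def fit(self, alpha: float = 0.1) -> "AssayResults":
        """Normalize per plate, test each cDNA vs control, apply BKY FDR."""
        normalized = normalize_assay_plate(self.measurements)
        table = kw_dunn_vs_control(normalized, control=self.control)
        kw_h, kw_p = table.attrs["kw_h"], table.attrs["kw_p"]
        fdr = bky_fdr(table["p"], alpha=alpha)
        table = table.join(fdr[["q", "significant"]])
        mean_norm = normalized.groupby("cdna")["normalized"].mean()
        table.insert(0, "mean_normalized", mean_norm.reindex(table.index))
        return AssayResults(model=self, table=table, alpha=alpha, kw_h=kw_h, kw_p=kw_p)


class AssayResults:
    """Per-cDNA differentiation statistics from :class:`DifferentiationAssay`."""

    def __init__(self, model, table, alpha, kw_h, kw_p):
        self.model = model
        self.table = table
        self.alpha = alpha
        self.kw_h = kw_h
        self.kw_p = kw_p

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            "Differentiation assay (alkaline phosphatase)",
            "=" * 60,
            f"cDNAs tested vs {self.model.control}: {len(self.table)}",
            f"Kruskal-Wallis H = {self.kw_h:.3f}, p = {self.kw_p:.3g}",
            f"significant at q < {self.alpha:g}: {len(self.significant)}",
            "",
            f"{'cdna':<12}{'mean':>8}{'z':>8}{'p':>10}{'q':>10}  sig",
        ]
        for cdna, row in self.table.sort_values("p").head(10).iterrows():
            lines.append(
                f"{cdna:<12}{row['mean_normalized']:>8.3f}{row['dunn_z']:>8.2f}"
                f"{row['p']:>10.3g}{row['q']:>10.3g}  {'*' if row['significant'] else ''}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = ["mean_normalized", "n", "dunn_z", "p", "q", "significant"]
        self.table[cols].reset_index().to_csv(path, sep="\t", index=False)
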