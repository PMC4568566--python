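"""Derivation of an induced/repressed gene signature from a grouped experiment.

The derivation mirrors standard microarray practice: an optional raw-intensity
filter removes features whose maximum raw value falls outside a detection
window, a classical one-way ANOVA on log2 values yields per-gene p-values,
Benjamini–Hochberg step-up adjustment controls the FDR, and genes passing the
adjusted-p cutoff are split by linear fold change into the induced
(FC > cutoff) and repressed (FC < 1/cutoff) halves of the signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOG2, RAW_LINEAR, ExpressionMatrix, SampleGroups
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: default raw-intensity detection window (linear scale)
DEFAULT_RAW_FILTER = (50.0, 35272.484)


@dataclass
class Signature:
    """Two disjoint ordered gene lists summarising a perturbation footprint."""

    induced: list[str]
    repressed: list[str]
    thresholds: dict = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        self.induced = [str(g).strip().upper() for g in self.induced]
        self.repressed = [str(g).strip().upper() for g in self.repressed]
        for name, half in (("induced", self.induced), ("repressed", self.repressed)):
            if len(half) != len(set(half)):
                raise ValidationError(f"{name} gene list contains duplicates")
        if set(self.induced) & set(self.repressed):
            raise ValidationError("induced and repressed halves overlap")

    def swapped(self) -> "Signature":
        return Signature(self.repressed, self.induced, dict(self.thresholds), self.source)


def raw_intensity_filter(
    matrix: ExpressionMatrix, lo: float, hi: float, statistic: str = "max"
) -> ExpressionMatrix:
    """Keep features whose per-row summary raw intensity lies in ``[lo, hi]``.

    ``statistic`` selects what must fall in the window: the row ``"max"``
    (default), the row ``"min"``, or ``"all"`` samples.
    """
    if matrix.scale != RAW_LINEAR:
        raise ValidationError(
            "raw_intensity_filter requires raw_linear values; supply the raw matrix "
            "or skip the filter for log2 data"
        )
    if not lo < hi:
        raise ValidationError("raw filter needs lo < hi")
    vals = matrix.values.to_numpy()
    if statistic == "max":
        summary_ok = (vals.max(axis=1) >= lo) & (vals.max(axis=1) <= hi)
    elif statistic == "min":
        summary_ok = (vals.min(axis=1) >= lo) & (vals.min(axis=1) <= hi)
    elif statistic == "all":
        summary_ok = ((vals >= lo) & (vals <= hi)).all(axis=1)
    else:
        raise ValidationError(f"unknown filter statistic {statistic!r}")
    keep = [f for f, ok in zip(matrix.feature_ids, summary_ok) if ok]
    logger.info("raw intensity filter dropped %d of %d features", matrix.n_features - len(keep), matrix.n_features)
    return matrix.subset_features(keep)


def one_way_anova(matrix: ExpressionMatrix, groups: SampleGroups) -> pd.DataFrame:
    """Classical fixed-effects one-way ANOVA per gene.

    Returns a DataFrame indexed by gene with columns ``F`` and ``p``.  With
    exactly two groups F equals the square of the pooled two-sample t.
    Degenerate genes with zero within-group variance get p = 0 when the group
    means differ and p = 1 when every value is identical.
    """
    if matrix.scale != LOG2:
        raise ValidationError("one_way_anova expects log2-scale values")
    group_labels = groups.groups
    if len(group_labels) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    groups.require_min_per_group(2)
    missing = [s for s in matrix.sample_ids if s not in groups.assignment]
    if missing:
        raise ValidationError(f"samples without group assignment: {missing[:5]}")

    X = matrix.values.to_numpy(dtype=float)
    n = X.shape[1]
    k = len(group_labels)
    col_idx = {s: j for j, s in enumerate(matrix.sample_ids)}
    grand = X.mean(axis=1)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in group_labels:
        idx = [col_idx[s] for s in groups.samples_in(g) if s in col_idx]
        if len(idx) < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples in the matrix")
        sub = X[:, idx]
        m = sub.mean(axis=1)
        ssb += len(idx) * (m - grand) ** 2
        ssw += ((sub - m[:, None]) ** 2).sum(axis=1)

    dfb, dfw = k - 1, n - k
    scale2 = np.maximum(np.abs(X).max(axis=1), 1.0) ** 2
    degenerate = ssw <= 1e-24 * scale2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(F, dfb, dfw)
    all_identical = degenerate & (ssb <= 1e-24 * scale2)
    means_differ = degenerate & ~all_identical
    F[means_differ], p[means_differ] = np.inf, 0.0
    F[all_identical], p[all_identical] = 0.0, 1.0
    return pd.DataFrame({"F": F, "p": p}, index=matrix.feature_ids)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1 or not np.isfinite(p).all()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_changes(
    matrix: ExpressionMatrix, groups: SampleGroups, method: str = "log_mean"
) -> pd.DataFrame:
    """Linear-scale fold change (treated vs reference) and direction per gene.

    ``method="log_mean"`` (default) computes ``2 ** (mean_log2_treated −
    mean_log2_reference)``; ``method="linear_mean"`` takes the ratio of
    linear-scale group means instead.  The absolute fold change used for
    thresholding is ``max(fc, 1/fc)``.
    """
    if method not in ("log_mean", "linear_mean"):
        raise ValidationError(f"unknown fold-change method {method!r}")
    treated = groups.treated_group()
    ref_cols = [s for s in matrix.sample_ids if groups.assignment.get(s) == groups.reference_group]
    trt_cols = [s for s in matrix.sample_ids if groups.assignment.get(s) == treated]
    if not ref_cols or not trt_cols:
        raise ValidationError("both treated and reference groups must appear in the matrix")
    vals = matrix.values
    if method == "log_mean":
        fc = np.power(2.0, vals[trt_cols].mean(axis=1) - vals[ref_cols].mean(axis=1))
    else:
        lin = np.power(2.0, vals) if matrix.scale == LOG2 else vals
        fc = lin[trt_cols].mean(axis=1) / lin[ref_cols].mean(axis=1)
    direction = np.where(fc > 1, "up", np.where(fc < 1, "down", "flat"))
    return pd.DataFrame({"fc_linear": fc, "direction": direction}, index=matrix.feature_ids)


def derive_signature(
    matrix: ExpressionMatrix,
    groups: SampleGroups,
    q_cutoff: float = 0.05,
    fc_cutoff: float = 1.2,
    raw: ExpressionMatrix | None = None,
    raw_lo: float = DEFAULT_RAW_FILTER[0],
    raw_hi: float = DEFAULT_RAW_FILTER[1],
    fc_method: str = "log_mean",
    source: str = "derived",
) -> tuple[Signature, pd.DataFrame]:
    """Derive the induced/repressed signature and return the full DE table.

    Induced genes satisfy ``q <= q_cutoff`` and ``fc_linear > fc_cutoff``;
    repressed genes satisfy ``q <= q_cutoff`` and ``fc_linear < 1/fc_cutoff``.
    Both halves are ordered by ascending q, ties broken by gene id.  The DE
    table (group means, p, q, fold change, direction, calls) is returned in
    the matrix's gene order for audit.
    """
    if not 0 < q_cutoff <= 1:
        raise ValidationError("q_cutoff must lie in (0, 1]")
    if fc_cutoff < 1:
        raise ValidationError("fc_cutoff must be >= 1")
    work = matrix
    if raw is not None:
        filtered = raw_intensity_filter(raw, raw_lo, raw_hi)
        keep = [f for f in matrix.feature_ids if f in set(filtered.feature_ids)]
        work = matrix.subset_features(keep)

    anova = one_way_anova(work, groups)
    fc = fold_changes(work, groups, method=fc_method)
    q = bh_adjust(anova["p"].to_numpy())
    de = pd.DataFrame(index=work.feature_ids)
    for g in groups.groups:
        cols = [s for s in work.sample_ids if groups.assignment.get(s) == g]
        de[f"mean_{g}"] = work.values[cols].mean(axis=1)
    de["p_anova"] = anova["p"]
    de["q_bh"] = q
    de["fc_linear"] = fc["fc_linear"]
    de["direction"] = fc["direction"]
    de["induced"] = (de["q_bh"] <= q_cutoff) & (de["fc_linear"] > fc_cutoff)
    de["repressed"] = (de["q_bh"] <= q_cutoff) & (de["fc_linear"] < 1.0 / fc_cutoff)

    def _ordered(mask: pd.Series) -> list[str]:
        sub = de.loc[mask, ["q_bh"]].copy()
        sub["gene"] = sub.index
        return list(sub.sort_values(["q_bh", "gene"]).index)

    induced = _ordered(de["induced"])
    repressed = _ordered(de["repressed"])
    if not induced or not repressed:
        warnings.warn("signature derivation produced an empty half", stacklevel=2)
    thresholds = {
        "q_cutoff": q_cutoff,
        "fc_cutoff": fc_cutoff,
        "raw_filter": [raw_lo, raw_hi] if raw is not None else None,
    }
    return Signature(induced, repressed, thresholds, source=source), de
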