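"""Downstream statistics against the signature score.

Three operations: two-group comparison of a single measurement (fold change
plus two-sided t-test), a per-gene Pearson correlation screen against the
per-sample score with signed significance calls, and a one-sided upper-tail
hypergeometric over-representation test for gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LOG2, ExpressionMatrix, GeneSet, SampleGroups
from .derive import bh_adjust
from .errors import ValidationError
from .scoring import ScoreTable


@dataclass
class GroupComparison:
    """Fold change and two-sided t-test of treated vs reference."""

    fold_change: float
    t: float
    p: float
    n_treated: int
    n_reference: int


@dataclass
class CorrelationReport:
    """Per-gene Pearson correlation with the score, with direction calls.

    ``table`` is indexed by gene with columns ``r``, ``p_two_sided``, ``call``
    (positive / negative / ns at raw p < alpha), plus the stricter
    BH-adjusted ``q_bh`` and ``call_bh``.  Genes requested but absent from
    the matrix are listed in ``skipped``.
    """

    table: pd.DataFrame
    alpha: float
    n_samples: int
    skipped: list[str]


def group_compare(
    values: pd.Series,
    groups: SampleGroups,
    data_scale: str = "linear",
    fc_method: str = "mean_ratio",
) -> GroupComparison:
    """Two-sided pooled t-test and linear fold change, treated vs reference.

    The t-test runs on the supplied scale.  Fold change is the ratio of
    linear-scale group means (``fc_method="mean_ratio"``); log2 inputs are
    exponentiated first.  ``fc_method="log_mean"`` instead uses
    ``2 ** (mean_log2_treated − mean_log2_reference)``.
    """
    if data_scale not in ("linear", "log2"):
        raise ValidationError(f"unknown data_scale {data_scale!r}")
    if fc_method not in ("mean_ratio", "log_mean"):
        raise ValidationError(f"unknown fc_method {fc_method!r}")
    treated_label = groups.treated_group()
    groups.require_min_per_group(2)
    vals = pd.Series(values, dtype=float)
    trt = vals[[s for s in vals.index if groups.assignment.get(s) == treated_label]].to_numpy()
    ref = vals[[s for s in vals.index if groups.assignment.get(s) == groups.reference_group]].to_numpy()
    if trt.size < 2 or ref.size < 2:
        raise ValidationError("each group needs >= 2 values present in the series")

    t, p = stats.ttest_ind(trt, ref, equal_var=True)
    lin_trt = np.power(2.0, trt) if data_scale == "log2" else trt
    lin_ref = np.power(2.0, ref) if data_scale == "log2" else ref
    if fc_method == "mean_ratio":
        fc = lin_trt.mean() / lin_ref.mean()
    else:
        log_trt = trt if data_scale == "log2" else np.log2(trt)
        log_ref = ref if data_scale == "log2" else np.log2(ref)
        fc = float(2.0 ** (log_trt.mean() - log_ref.mean()))
    return GroupComparison(float(fc), float(t), float(p), trt.size, ref.size)


def correlation_screen(
    matrix: ExpressionMatrix,
    scores: ScoreTable,
    genes_of_interest=None,
    alpha: float = 0.05,
) -> CorrelationReport:
    """Pearson-correlate each gene's expression with the per-sample score.

    For each gene, r is computed across samples against the t-scores; the
    two-sided p comes from the exact transform t = r sqrt((n−2)/(1−r²)) on
    n−2 degrees of freedom.  Calls: positive (r > 0, p < alpha), negative
    (r < 0, p < alpha), else ns.  Constant genes get r = NaN and call ns.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    samples = scores.sample_ids
    missing = [s for s in samples if s not in matrix.values.columns]
    if missing:
        raise ValidationError(f"scored samples absent from the matrix: {missing[:5]}")
    n = len(samples)
    if n < 4:
        raise ValidationError("correlation screen needs >= 4 samples")

    requested = list(genes_of_interest) if genes_of_interest is not None else matrix.feature_ids
    by_upper = {str(g).upper(): g for g in matrix.feature_ids}
    found, skipped = [], []
    for g in requested:
        key = str(g).strip().upper()
        (found if key in by_upper else skipped).append(key)
    rows = [by_upper[g] for g in found]

    X = matrix.values.loc[rows, samples].to_numpy(dtype=float)
    y = scores.table.loc[samples, "t_score"].to_numpy(dtype=float)
    yc = y - y.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    constant = sx == 0
    r[constant], p[constant] = np.nan, np.nan

    call = np.where(
        constant | np.isnan(p),
        "ns",
        np.where((r > 0) & (p < alpha), "positive", np.where((r < 0) & (p < alpha), "negative", "ns")),
    )
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if valid.any():
        q[valid] = bh_adjust(p[valid])
    call_bh = np.where(
        ~valid,
        "ns",
        np.where((r > 0) & (q < alpha), "positive", np.where((r < 0) & (q < alpha), "negative", "ns")),
    )
    table = pd.DataFrame(
        {"r": r, "p_two_sided": p, "call": call, "n": n, "q_bh": q, "call_bh": call_bh},
        index=pd.Index(found, name="gene"),
    )
    return CorrelationReport(table=table, alpha=alpha, n_samples=n, skipped=skipped)


def ora_hypergeometric(hits, universe, pathway) -> float:
    """One-sided upper-tail hypergeometric over-representation p-value.

    Drawing ``|hits|`` genes from a universe of ``|universe|`` with
    ``|pathway ∩ universe|`` marked, the p-value is P(overlap >= observed).
    """
    hits = {str(g).upper() for g in hits}
    universe = {str(g).upper() for g in universe}
    members = pathway.members if isinstance(pathway, GeneSet) else {str(g).upper() for g in pathway}
    if not hits <= universe:
        raise ValidationError("hits must be a subset of the universe")
    marked = members & universe
    if not marked:
        raise ValidationError("pathway does not intersect the universe")
    k = len(hits & marked)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(marked), len(hits)))
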