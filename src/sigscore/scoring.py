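"""Projection of a signature onto an independent cohort.

The per-sample score is a plain two-sample t statistic computed *within* one
sample's centered profile: induced-gene values form one group, repressed-gene
values the other.  A positive score means the induced genes sit above the
repressed genes in that sample — the signature "manifests".  Before scoring,
probe-level matrices are collapsed to genes (highest-variance probe wins),
every gene row is centered to standard deviations from its cohort median, and
the signature is translated onto the cohort's gene symbols (optionally through
an explicit ortholog map).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    GENE,
    PROBE,
    ExpressionMatrix,
    OrthologMap,
    ProbeAnnotation,
)
from .derive import Signature
from .errors import ScoringRefusedError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-sample signature t-scores with degrees of freedom, coverage and rank.

    ``table`` is indexed by sample id with columns ``t_score``, ``df``,
    ``n_induced_used``, ``n_repressed_used`` and ``rank`` (1 = strongest
    manifestation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"t_score", "df", "n_induced_used", "n_repressed_used", "rank"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"score table missing columns: {sorted(missing)}")
        ranks = sorted(int(r) for r in self.table["rank"])
        if ranks != list(range(1, len(self.table) + 1)):
            raise ValidationError("ranks must be a permutation of 1..n_samples")
        for col in ("n_induced_used", "n_repressed_used"):
            if self.table[col].nunique() > 1:
                raise ValidationError(f"{col} must be constant across the cohort")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def scores(self) -> pd.Series:
        return self.table["t_score"]

    def sample_order(self) -> list[str]:
        """Samples ordered by manifestation (rank 1 first)."""
        return list(self.table.sort_values("rank").index)


@dataclass
class CoverageReport:
    """How many signature genes were requested, translated and found per half."""

    induced_requested: int
    induced_mapped: int
    induced_found: int
    repressed_requested: int
    repressed_mapped: int
    repressed_found: int


@dataclass
class CenteredMatrix:
    """A centered gene-level matrix plus the genes flagged as zero-variance."""

    matrix: ExpressionMatrix
    degenerate_genes: list[str]


def collapse_probes(matrix: ExpressionMatrix, annotation: ProbeAnnotation) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes, keeping the highest-variance probe.

    Variance is the sample variance (n−1 denominator) across cohort samples;
    exact ties go to the lexicographically smallest probe id.  Probes absent
    from the annotation are dropped (count logged).  Output genes are sorted.
    """
    if matrix.feature_level != PROBE:
        raise ValidationError("collapse_probes expects a probe-level matrix")
    annotated = [p for p in matrix.feature_ids if p in annotation.mapping]
    if not annotated:
        raise ValidationError("no probe in the matrix is annotated to a gene")
    logger.info(
        "collapse_probes: %d of %d probes annotated", len(annotated), matrix.n_features
    )
    sub = matrix.values.loc[annotated]
    var = sub.var(axis=1, ddof=1)
    choice = pd.DataFrame(
        {
            "gene": [annotation.mapping[p] for p in annotated],
            "var": var.to_numpy(),
            "probe": annotated,
        }
    ).sort_values(["gene", "var", "probe"], ascending=[True, False, True])
    winners = choice.drop_duplicates("gene", keep="first")
    out = matrix.values.loc[winners["probe"]].copy()
    out.index = list(winners["gene"])
    return ExpressionMatrix(out, scale=matrix.scale, feature_level=GENE)


def center_genes(matrix: ExpressionMatrix) -> CenteredMatrix:
    """Center each gene row to standard deviations from its cohort median.

    Row transform: ``(x − median(x)) / sd(x)`` with the n−1 sd, computed across
    the samples of the cohort being scored.  Zero-variance rows become all
    zeros and are listed in ``degenerate_genes``.
    """
    if matrix.n_samples < 3:
        raise ValidationError("centering needs >= 3 samples")
    vals = matrix.values
    med = vals.median(axis=1)
    sd = vals.std(axis=1, ddof=1)
    degenerate = sd == 0
    safe_sd = sd.where(~degenerate, 1.0)
    out = vals.sub(med, axis=0).div(safe_sd, axis=0)
    out.loc[degenerate] = 0.0
    if degenerate.any():
        logger.info("center_genes: %d zero-variance rows set to 0", int(degenerate.sum()))
    return CenteredMatrix(
        ExpressionMatrix(out, scale=matrix.scale, feature_level=matrix.feature_level),
        degenerate_genes=list(vals.index[degenerate]),
    )


def map_signature(
    signature: Signature,
    ortholog_map: OrthologMap | None,
    cohort_genes,
    min_per_half: int = 3,
) -> tuple[Signature, CoverageReport]:
    """Translate signature genes onto a cohort's symbols and intersect.

    Translation precedence: explicit ortholog map, else case-normalised
    identity.  Either half dropping below ``min_per_half`` surviving genes
    refuses scoring with a message naming the counts.
    """
    omap = ortholog_map or OrthologMap({})
    cohort = {str(g).strip().upper() for g in cohort_genes}

    def _map_half(genes: list[str]) -> tuple[list[str], int]:
        translated: list[str] = []
        for g in genes:
            t = omap.translate(g)
            if t not in translated:
                translated.append(t)
        return [g for g in translated if g in cohort], len(translated)

    ind_found, ind_mapped = _map_half(signature.induced)
    rep_found, rep_mapped = _map_half(signature.repressed)
    report = CoverageReport(
        induced_requested=len(signature.induced),
        induced_mapped=ind_mapped,
        induced_found=len(ind_found),
        repressed_requested=len(signature.repressed),
        repressed_mapped=rep_mapped,
        repressed_found=len(rep_found),
    )
    if len(ind_found) < min_per_half or len(rep_found) < min_per_half:
        raise ScoringRefusedError(
            f"too few signature genes on the cohort platform: induced "
            f"{len(ind_found)}/{len(signature.induced)}, repressed "
            f"{len(rep_found)}/{len(signature.repressed)} (floor {min_per_half})"
        )
    mapped = Signature(ind_found, rep_found, dict(signature.thresholds), signature.source)
    return mapped, report


def t_score(induced_values, repressed_values, variant: str = "pooled") -> tuple[float, float]:
    """Two-sample t statistic of induced vs repressed values within one profile.

    Positive when the induced mean exceeds the repressed mean.  ``variant``
    is ``"pooled"`` (df = n1+n2−2) or ``"welch"`` (Welch–Satterthwaite df).
    """
    x = np.asarray(induced_values, dtype=float)
    y = np.asarray(repressed_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need >= 2 induced and >= 2 repressed values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in t_score input")
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t variant {variant!r}")
    n1, n2 = x.size, y.size
    d = x.mean() - y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if variant == "pooled":
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        if se2 > 0:
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)
    if se == 0:
        if d == 0:
            return 0.0, df
        raise ValidationError("zero variance with unequal means: pathological profile")
    return float(d / se), float(df)


def score_cohort(
    matrix: ExpressionMatrix,
    signature: Signature,
    annotation: ProbeAnnotation | None = None,
    ortholog_map: OrthologMap | None = None,
    variant: str = "pooled",
    min_per_half: int = 3,
) -> ScoreTable:
    """Score every cohort sample for manifestation of the signature.

    Pipeline: probe collapsing (when the matrix is probe-level) → per-gene
    centering → signature mapping → per-sample t-score → ranking by
    descending score (ties broken by sample id; rank 1 = strongest).
    """
    # canonical sample order makes per-sample scores bit-identical under
    # any input column permutation (row statistics sum in a fixed order)
    matrix = matrix.reorder_samples(sorted(matrix.sample_ids))
    if matrix.feature_level == PROBE:
        if annotation is None:
            raise ValidationError("a probe-level matrix requires a probe annotation")
        matrix = collapse_probes(matrix, annotation)
    centered = center_genes(matrix)
    genes_upper = {str(g).upper(): g for g in centered.matrix.feature_ids}
    mapped, _report = map_signature(signature, ortholog_map, genes_upper, min_per_half)
    ind_rows = centered.matrix.values.loc[[genes_upper[g] for g in mapped.induced]]
    rep_rows = centered.matrix.values.loc[[genes_upper[g] for g in mapped.repressed]]

    records = {}
    for sample in centered.matrix.sample_ids:
        t, df = t_score(ind_rows[sample], rep_rows[sample], variant=variant)
        records[sample] = (t, df)
    samples = list(records)
    table = pd.DataFrame(
        {
            "t_score": [records[s][0] for s in samples],
            "df": [records[s][1] for s in samples],
            "n_induced_used": len(mapped.induced),
            "n_repressed_used": len(mapped.repressed),
        },
        index=pd.Index(samples, name="sample"),
    )
    order = sorted(samples, key=lambda s: (-records[s][0], s))
    table["rank"] = pd.Series({s: i + 1 for i, s in enumerate(order)})
    return ScoreTable(table)
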