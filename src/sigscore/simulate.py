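"""Simulators with known ground truth for every downstream stage.

Two generative models are provided:

``simulate_two_group``
    A small two-group (e.g. 3 control vs 3 treated ventricle pools) log2
    expression experiment with a planted set of induced/repressed genes of
    fixed log2 effect size and i.i.d. Gaussian gene-level noise.  This is the
    training-side design from which a signature is derived.

``simulate_activity_cohort``
    An independent cohort in which each sample carries a latent scalar
    "signature activity" that shifts induced genes up and repressed genes
    down by the same amount, on top of per-gene baselines and Gaussian noise.
    A configurable fraction of signature genes is removed, emulating genes
    absent from the target platform.

Both draw from a single explicitly seeded generator, genes in the outer loop
and samples inner, so results are bit-reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GENE, LOG2, ExpressionMatrix, SampleGroups
from .errors import ValidationError


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``mode`` is ``"two_group"`` (planted differential genes) or ``"activity"``
    (per-sample latent activities).
    """

    mode: str
    de_up: set[str] = field(default_factory=set)
    de_down: set[str] = field(default_factory=set)
    effect_log2: dict[str, float] = field(default_factory=dict)
    activities: dict[str, float] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise ValidationError("a gene cannot be both induced and repressed")
        if (self.activities is not None) != (self.mode == "activity"):
            raise ValidationError("activities present iff mode='activity'")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_two_group(
    n_genes: int,
    n_per_group: int,
    n_up: int,
    n_down: int,
    effect_log2: float,
    noise_sd: float,
    baseline_log2_range: tuple[float, float] = (4.0, 12.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SampleGroups, SimTruth]:
    """Simulate a two-group log2 expression experiment with planted DE genes.

    Gene ``g`` in sample ``s`` is ``baseline_g + delta_g * 1[s treated] + eps``
    with ``eps ~ N(0, noise_sd^2)`` and ``delta_g`` equal to ``+effect_log2``
    for the first ``n_up`` genes, ``-effect_log2`` for the next ``n_down``,
    and 0 otherwise.  With ``effect_log2 == 0`` the planted sets are empty and
    the two groups are exchangeable.
    """
    if n_up < 0 or n_down < 0 or n_up + n_down > n_genes:
        raise ValidationError("need n_up + n_down <= n_genes and non-negative counts")
    if n_per_group < 2:
        raise ValidationError("n_per_group must be >= 2")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    lo, hi = baseline_log2_range
    if not lo < hi:
        raise ValidationError("baseline_log2_range must be a non-empty interval")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    ctrl = [f"CTRL_{i}" for i in range(1, n_per_group + 1)]
    treated = [f"TREATED_{i}" for i in range(1, n_per_group + 1)]

    baselines = rng.uniform(lo, hi, size=n_genes)
    noise = rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))

    delta = np.zeros(n_genes)
    if effect_log2 != 0:
        delta[:n_up] = effect_log2
        delta[n_up : n_up + n_down] = -effect_log2
    values = baselines[:, None] + noise
    values[:, n_per_group:] += delta[:, None]

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=ctrl + treated),
        scale=LOG2,
        feature_level=GENE,
    )
    groups = SampleGroups(
        {**{s: "CTRL" for s in ctrl}, **{s: "TREATED" for s in treated}},
        reference_group="CTRL",
    )
    if effect_log2 != 0:
        de_up, de_down = set(genes[:n_up]), set(genes[n_up : n_up + n_down])
    else:
        de_up, de_down = set(), set()
    truth = SimTruth(
        mode="two_group",
        de_up=de_up,
        de_down=de_down,
        effect_log2={g: float(d) for g, d in zip(genes, delta) if d != 0},
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, groups, truth


def simulate_activity_cohort(
    signature,
    n_samples: int,
    n_background_genes: int,
    activity_sd: float,
    noise_sd: float,
    missing_fraction: float = 0.0,
    baseline_log2_range: tuple[float, float] = (4.0, 12.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate an independent cohort carrying a latent signature activity.

    Per sample ``s`` a latent ``a_s ~ N(0, activity_sd^2)`` is drawn; gene
    values are ``baseline_g + a_s * d_g + eps`` with ``d_g = +1`` for induced
    signature genes, ``-1`` for repressed and ``0`` for background genes.
    A fraction ``missing_fraction`` of signature genes (chosen by the seed) is
    removed from the output, emulating platform coverage gaps.
    """
    if not 0 <= missing_fraction < 1:
        raise ValidationError("missing_fraction must lie in [0, 1)")
    if noise_sd <= 0:
        raise ValidationError("noise_sd must be positive")
    if activity_sd < 0:
        raise ValidationError("activity_sd must be non-negative")
    if n_samples < 3:
        raise ValidationError("n_samples must be >= 3 (cohort centering needs >= 3)")
    lo, hi = baseline_log2_range
    if not lo < hi:
        raise ValidationError("baseline_log2_range must be a non-empty interval")

    rng = np.random.default_rng(seed)
    induced = [g.upper() for g in signature.induced]
    repressed = [g.upper() for g in signature.repressed]
    background = [f"BG{i:06d}" for i in range(1, n_background_genes + 1)]
    clash = (set(induced) | set(repressed)) & set(background)
    if clash:
        raise ValidationError(f"background gene ids collide with signature genes: {clash}")
    genes = induced + repressed + background
    direction = np.concatenate(
        [np.ones(len(induced)), -np.ones(len(repressed)), np.zeros(len(background))]
    )
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]

    baselines = rng.uniform(lo, hi, size=len(genes))
    activities = rng.normal(0.0, activity_sd, size=n_samples) if activity_sd > 0 else np.zeros(n_samples)
    noise = rng.normal(0.0, noise_sd, size=(len(genes), n_samples))
    values = baselines[:, None] + direction[:, None] * activities[None, :] + noise

    n_sig = len(induced) + len(repressed)
    n_missing = int(round(missing_fraction * n_sig))
    drop_idx = set(rng.choice(n_sig, size=n_missing, replace=False)) if n_missing else set()
    keep = [i for i in range(len(genes)) if i not in drop_idx]
    surviving = [genes[i] for i in keep]
    for half, ids in (("induced", induced), ("repressed", repressed)):
        n_left = len(set(ids) & set(surviving))
        if n_left < 2:
            raise ValidationError(
                f"only {n_left} {half} genes survive missing_fraction={missing_fraction}; need >= 2"
            )

    matrix = ExpressionMatrix(
        pd.DataFrame(values[keep], index=surviving, columns=samples),
        scale=LOG2,
        feature_level=GENE,
    )
    truth = SimTruth(
        mode="activity",
        activities={s: float(a) for s, a in zip(samples, activities)},
        noise_sd=noise_sd,
        seed=seed,
    )
    return matrix, truth
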