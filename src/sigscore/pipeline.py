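"""End-to-end orchestration: derive → score → rank → correlate, with a manifest.

A run is described by a flat YAML config (paths, thresholds, t variant,
seed).  ``run_full`` executes the stages in a fixed order into an output
directory and writes a machine-readable ``manifest.json`` carrying the
config hash and package version; rerunning with identical config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as sio
from .derive import DEFAULT_RAW_FILTER, derive_signature
from .errors import PipelineError, ValidationError
from .association import correlation_screen
from .scoring import score_cohort

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "signature.gmt",
    "de_results.tsv",
    "scores.tsv",
    "ordered_matrix.tsv",
    "correlation_report.tsv",
)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    matrix: str
    groups: str
    reference_group: str
    cohort: str
    outdir: str
    raw: str | None = None
    raw_lo: float = DEFAULT_RAW_FILTER[0]
    raw_hi: float = DEFAULT_RAW_FILTER[1]
    cohort_feature_level: str = "gene"
    annotation: str | None = None
    orthologs: str | None = None
    genes_of_interest: str | None = None
    q_cutoff: float = 0.05
    fc_cutoff: float = 1.2
    alpha: float = 0.05
    t_variant: str = "pooled"
    min_per_half: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.q_cutoff <= 1:
            raise ValidationError(f"q_cutoff {self.q_cutoff} outside (0, 1]")
        if self.fc_cutoff < 1:
            raise ValidationError(f"fc_cutoff {self.fc_cutoff} must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if self.t_variant not in ("pooled", "welch"):
            raise ValidationError(f"unknown t_variant {self.t_variant!r}")
        if self.raw is not None and not self.raw_lo < self.raw_hi:
            raise ValidationError("raw_lo must be < raw_hi")
        for name in ("matrix", "groups", "cohort", "raw", "annotation", "orthologs", "genes_of_interest"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"config input {name} = {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def run_full(config: RunConfig) -> dict:
    """Execute derive → score → order → correlate and write a run manifest.

    Returns the manifest dict.  A stage failure raises :class:`PipelineError`
    naming the stage; outputs of completed stages are left in place.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_file = outdir / "run.log"
    handler = logging.FileHandler(log_file, mode="w")
    handler.setLevel(config.log_level)
    root = logging.getLogger("sigscore")
    root.addHandler(handler)

    stage = "load_inputs"
    try:
        matrix = sio.read_expression_matrix(config.matrix, scale="log2", feature_level="gene")
        groups = sio.read_sample_groups(config.groups, config.reference_group)
        raw = (
            sio.read_expression_matrix(config.raw, scale="raw_linear", feature_level="gene")
            if config.raw
            else None
        )
        cohort = sio.read_expression_matrix(
            config.cohort, scale="log2", feature_level=config.cohort_feature_level
        )
        annotation = sio.read_probe_annotation(config.annotation) if config.annotation else None
        orthologs = sio.read_ortholog_map(config.orthologs) if config.orthologs else None
        genes_of_interest = (
            [
                line.strip()
                for line in Path(config.genes_of_interest).read_text().splitlines()
                if line.strip()
            ]
            if config.genes_of_interest
            else None
        )

        stage = "derive_signature"
        signature, de = derive_signature(
            matrix,
            groups,
            q_cutoff=config.q_cutoff,
            fc_cutoff=config.fc_cutoff,
            raw=raw,
            raw_lo=config.raw_lo,
            raw_hi=config.raw_hi,
        )
        sio.write_signature_gmt(signature, outdir / "signature.gmt")
        de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene")

        stage = "score_cohort"
        scores = score_cohort(
            cohort,
            signature,
            annotation=annotation,
            ortholog_map=orthologs,
            variant=config.t_variant,
            min_per_half=config.min_per_half,
        )
        sio.write_score_table(scores, outdir / "scores.tsv")

        stage = "order_matrix"
        sio.write_ordered_matrix(cohort, scores.sample_order(), outdir / "ordered_matrix.tsv")

        stage = "correlate"
        report = correlation_screen(cohort, scores, genes_of_interest, alpha=config.alpha)
        report.table.to_csv(outdir / "correlation_report.tsv", sep="\t", index_label="gene")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "config_hash": config.config_hash(),
            "config": asdict(config),
            "outputs": list(OUTPUT_FILES),
            "n_induced": len(signature.induced),
            "n_repressed": len(signature.repressed),
            "n_cohort_samples": len(scores.sample_ids),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def write_demo_inputs(directory, seed: int = 0) -> Path:
    """Generate a self-contained synthetic demo run directory.

    Writes a small planted two-group experiment, an activity cohort scored
    against the planted truth, a genes-of-interest list and a ``config.yaml``;
    returns the config path.
    """
    from .derive import Signature
    from .simulate import simulate_activity_cohort, simulate_two_group

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, groups, truth = simulate_two_group(
        n_genes=600,
        n_per_group=3,
        n_up=25,
        n_down=25,
        effect_log2=2.0,
        noise_sd=0.25,
        seed=seed,
    )
    planted = Signature(sorted(truth.de_up), sorted(truth.de_down), source="planted")
    cohort, _truth = simulate_activity_cohort(
        planted,
        n_samples=60,
        n_background_genes=400,
        activity_sd=1.0,
        noise_sd=0.5,
        missing_fraction=0.1,
        seed=seed + 1,
    )
    sio.write_expression_matrix(matrix, directory / "training_matrix.tsv")
    sio.write_sample_groups(groups, directory / "training_groups.tsv")
    sio.write_expression_matrix(cohort, directory / "cohort_matrix.tsv")
    goi = sorted(truth.de_up)[:5] + sorted(truth.de_down)[:5]
    (directory / "genes_of_interest.txt").write_text("\n".join(goi) + "\n")
    config = RunConfig(
        matrix=str(directory / "training_matrix.tsv"),
        groups=str(directory / "training_groups.tsv"),
        reference_group="CTRL",
        cohort=str(directory / "cohort_matrix.tsv"),
        genes_of_interest=str(directory / "genes_of_interest.txt"),
        outdir=str(directory / "run"),
        seed=seed,
    )
    cfg_path = directory / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return cfg_path
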