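"""End-to-end orchestration: preprocess -> dynamics -> ordination -> Mantel -> digestion.

:func:`run_pipeline` executes the full fingerprint analysis on a peak table
and covariate table (plus an optional clone FASTA), writes every stage's
outputs under one directory, and finishes with a ``manifest.json`` recording
the configuration, seeds and SHA-256 checksums of all outputs.  The manifest
carries no wall-clock information, so two runs with the same config are
byte-identical — the manifest alone is sufficient to reproduce a run.

A stage failure aborts the run with the stage name and cause; outputs already
written are retained next to a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cca import fit_cca, forward_select
from .digest import digest_clones, read_clones, results_table
from .dynamics import moving_window
from .mantel import mantel_table
from .preprocess import preprocess_peaks, read_peak_table
from .profiles import read_env_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    peak_csv: str
    env_csv: str
    clones_fasta: str | None = None
    output_dir: str = "trflpdyn_out"
    # preprocessing
    min_bp: float = 50.0
    max_bp: float = 500.0
    bin_tolerance_bp: float = 1.0
    noise_floor: float = 0.02
    renormalize: bool = True
    # dynamics
    exclude_before_day: float | None = None
    # ordination
    cca_scaling: str = "species"
    cca_n_perm: int = 499
    cca_alpha: float = 0.05
    cca_seed: int = 0
    # Mantel
    mantel_metric: str = "bray-curtis"
    mantel_n_perm: int = 999
    mantel_tail: str = "greater"
    mantel_seed: int = 0
    # digestion
    enzyme_site: str = "TCGA"
    cut_offset: int = 1
    match_tolerance_bp: int = 3

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write outputs and the manifest, return the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "preprocess"
        logger.info("stage %s", stage)
        peaks = read_peak_table(config.peak_csv)
        env = read_env_table(config.env_csv)
        series, env_aligned = preprocess_peaks(
            peaks,
            env,
            min_bp=config.min_bp,
            max_bp=config.max_bp,
            bin_tolerance_bp=config.bin_tolerance_bp,
            noise_floor=config.noise_floor,
            renormalize=config.renormalize,
        )
        outputs["profiles"] = out / "profiles.tsv"
        series.to_tsv(outputs["profiles"])

        stage = "dynamics"
        logger.info("stage %s", stage)
        changes = moving_window(series, config.exclude_before_day)
        outputs["change_series"] = out / "change_series.tsv"
        changes.to_tsv(outputs["change_series"])
        outputs["change_summary"] = out / "change_summary.json"
        _write_json(outputs["change_summary"], changes.summary())

        stage = "ordination"
        logger.info("stage %s", stage)
        env_vars = [
            c for c in env_aligned.columns if c not in ("sample_id", "time_days")
        ]
        Y = series.matrix()
        X = env_aligned.set_index("sample_id")[env_vars]
        cca = fit_cca(
            Y, X, scaling=config.cca_scaling,
            n_perm=config.cca_n_perm, seed=config.cca_seed,
        )
        trace = forward_select(
            Y, X, alpha=config.cca_alpha,
            n_perm=config.cca_n_perm, seed=config.cca_seed,
        )
        outputs["cca_result"] = out / "cca_result.json"
        _write_json(
            outputs["cca_result"],
            {**cca.to_dict(), "forward_selected": trace.included},
        )
        for name, frame in (
            ("cca_site_scores", cca.site_scores),
            ("cca_species_scores", cca.species_scores),
            ("cca_biplot_scores", cca.biplot_scores),
            ("forward_selection_trace", trace.rows),
        ):
            outputs[name] = out / f"{name}.tsv"
            frame.to_csv(outputs[name], sep="\t")

        stage = "mantel"
        logger.info("stage %s", stage)
        table = mantel_table(
            series, env_aligned, metric=config.mantel_metric,
            n_perm=config.mantel_n_perm, seed=config.mantel_seed,
            tail=config.mantel_tail,
        )
        outputs["mantel_table"] = out / "mantel_table.tsv"
        table.to_csv(outputs["mantel_table"], sep="\t", index=False)

        if config.clones_fasta:
            stage = "digestion"
            logger.info("stage %s", stage)
            clones = read_clones(config.clones_fasta)
            results = digest_clones(
                clones,
                bins=series.bin_labels,
                enzyme_site=config.enzyme_site,
                cut_offset=config.cut_offset,
                tolerance_bp=config.match_tolerance_bp,
            )
            outputs["digest_results"] = out / "digest_results.tsv"
            results_table(results).to_csv(
                outputs["digest_results"], sep="\t", index=False
            )
    except Exception as exc:  # noqa: BLE001 — re-raised with stage context
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise StageError(stage, exc) from exc

    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    manifest = {
        "tool": "trflpdyn",
        "version": __version__,
        "config": asdict(config),
        "outputs": {k: str(v.name) for k, v in outputs.items()},
        "checksums": {str(v.name): _sha256(v) for v in outputs.values()},
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
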