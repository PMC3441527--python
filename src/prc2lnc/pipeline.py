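"""End-to-end pipeline runner: FASTA in, reproducible artifact directory out.

Runs sequence IO -> feature extraction -> selection -> training/LOOCV and
writes every artifact next to a resolved-configuration document (parameters,
seeds, package versions), so a deterministic rerun reproduces the outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .classify import ClassifierSpec, save_model
from .features import read_jaspar_pfms
from .model import PRC2BindingModel
from .seqio import POSITIVE, NEGATIVE

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative parameters for one pipeline run."""

    positive_fasta: str
    negative_fasta: str
    k: int = 6
    alpha: float = 0.05
    pwm_path: str | None = None
    min_score_fraction: float = 0.8
    include_kc: bool = True
    classifiers: tuple[str, ...] = ("svm_linear", "sda", "random_forest", "logistic_regression")
    cost_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0)
    nested_tuning: bool = True
    strict_selection: bool = False
    min_length_exclusive: int = 100
    equalize: bool = True
    loocv: bool = True
    seed: int = 0

    def resolved(self) -> dict:
        doc = asdict(self)
        doc["package_version"] = __version__
        doc["python"] = platform.python_version()
        return doc


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full workflow and write artifacts under ``outdir``.

    Artifacts: resolved_config.json, feature_matrix.tsv, selection.tsv,
    consensus.txt, cv_<classifier>.json, model_<classifier>.json(.pkl).
    Returns a manifest mapping artifact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.json", "w") as fh:
        json.dump(config.resolved(), fh, indent=1)

    pwms = read_jaspar_pfms(config.pwm_path) if config.pwm_path else []
    model = PRC2BindingModel.from_fasta(
        config.positive_fasta,
        config.negative_fasta,
        min_length_exclusive=config.min_length_exclusive,
        equalize=config.equalize,
        seed=config.seed,
        k=config.k,
        pwms=pwms,
        include_kc=config.include_kc,
        alpha=config.alpha,
        min_score_fraction=config.min_score_fraction,
    )
    manifest: dict[str, str] = {"resolved_config": str(outdir / "resolved_config.json")}

    model.feature_matrix.to_tsv(outdir / "feature_matrix.tsv")
    manifest["feature_matrix"] = str(outdir / "feature_matrix.tsv")

    first = True
    for kind in config.classifiers:
        model.spec = ClassifierSpec(kind)
        res = model.fit(
            loocv=config.loocv,
            nested_tuning=config.nested_tuning if kind == "svm_linear" else False,
            cost_grid=config.cost_grid,
            strict_selection=config.strict_selection,
            seed=config.seed,
        )
        if first:
            res.selection_table.to_csv(outdir / "selection.tsv", sep="\t")
            manifest["selection"] = str(outdir / "selection.tsv")
            with open(outdir / "consensus.txt", "w") as fh:
                for cls in (POSITIVE, NEGATIVE):
                    cons = res.consensus(cls)
                    if cons is not None:
                        fh.write(f"{cls}\t{cons.iupac}\t{cons.support}\n")
            manifest["consensus"] = str(outdir / "consensus.txt")
            first = False
        if res.cv is not None:
            cv_path = outdir / f"cv_{kind}.json"
            res.cv.to_json(cv_path)
            manifest[f"cv_{kind}"] = str(cv_path)
        model_path = outdir / f"model_{kind}.json"
        save_model(res.classifier, model_path)
        manifest[f"model_{kind}"] = str(model_path)
        logger.info("finished %s", kind)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
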