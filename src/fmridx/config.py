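"""Run configuration: schema, defaults, validation, and orchestration.

A single config file (YAML or JSON) drives the whole pipeline; defaults are
the study conditions (185 s truncation, 0.5 s target volume time, k=3
averaging, global z-normalization, sigma=150, 10 folds).  Unknown keys are
rejected so typos fail loudly before any compute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigError
from .preprocess import NORMALIZATIONS, preprocess_scan
from .reduction import PROCESS_NAMES
from .evaluation import (
    SETTINGS,
    Cohort,
    EvalResult,
    FeatureSpec,
    cross_validate,
    make_folds,
    results_table,
)
from .synthetic import default_cohort_spec, generate_cohort

log = logging.getLogger(__name__)

#: Keys accepted in the ``synthetic`` section (forwarded to
#: :func:`fmridx.synthetic.default_cohort_spec`).
SYNTHETIC_KEYS = (
    "n_control",
    "n_combined",
    "n_inattentive",
    "noise_sd",
    "grid",
    "duration_s",
    "site_gain",
)


@dataclass
class RunConfig:
    """Validated, fully-defaulted pipeline configuration."""

    seed: int = 0
    setting: str = "two_class"
    n_folds: int = 10
    svm_c: float = 1.0
    transductive: bool = False
    processes: tuple = PROCESS_NAMES
    m: object = None
    sigma: float = 150.0
    duration_s: float = 185.0
    target_period_s: float = 0.5
    avg_k: int = 3
    normalization: str = "zn2"
    mask: str = "auto"
    include_phenotypes: bool = True
    synthetic: dict = field(default_factory=dict)
    output_dir: str = "results"

    def __post_init__(self) -> None:
        self.processes = tuple(self.processes)
        self.validate()

    def validate(self) -> None:
        if self.setting not in SETTINGS:
            raise ConfigError(f"setting: must be one of {SETTINGS}, got {self.setting!r}")
        if self.n_folds < 2:
            raise ConfigError("n_folds: must be >= 2")
        if not self.svm_c > 0:
            raise ConfigError("svm_c: must be positive")
        for p in self.processes:
            if p not in PROCESS_NAMES:
                raise ConfigError(f"processes: unknown process {p!r}")
        if not self.sigma > 0:
            raise ConfigError("sigma: must be positive")
        if not self.duration_s > 0:
            raise ConfigError("duration_s: must be positive")
        if not self.target_period_s > 0:
            raise ConfigError("target_period_s: must be positive")
        if int(self.avg_k) != self.avg_k or self.avg_k < 1:
            raise ConfigError("avg_k: must be a positive integer")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigError(
                f"normalization: must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )
        unknown = set(self.synthetic) - set(SYNTHETIC_KEYS)
        if unknown:
            raise ConfigError(f"synthetic: unknown key(s) {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["processes"] = list(self.processes)
        return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON config; empty file means all defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path=None) -> str:
    """Serialize the normalized config; ``dump(load(c))`` is stable."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def _sha(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def run_pipeline(
    config: RunConfig, out_dir=None, dry_run: bool = False
) -> tuple[list[EvalResult], dict]:
    """Execute simulate -> preprocess -> features -> evaluate per the config.

    Evaluates the phenotypic-only feature set plus, for every configured
    process, the imaging-only and imaging+phenotypic sets.  Returns the
    results and a provenance manifest (config hash, seeds, versions,
    per-stage input/output hashes).  ``dry_run=True`` validates and returns
    the planned feature sets without computing.
    """
    plan = ["phenotypic"]
    for p in config.processes:
        plan.append(p)
        if config.include_phenotypes:
            plan.append(f"{p}+phenotypic")
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": _sha(dump_config(config).encode()),
        "seed": config.seed,
        "versions": _versions(),
        "plan": plan,
    }
    if dry_run:
        return [], manifest

    spec = default_cohort_spec(seed=config.seed, **config.synthetic)
    scans, phenotypes, truth = generate_cohort(spec)
    manifest["stages"] = {
        "simulate": {
            "n_subjects": len(scans),
            "sha256": _sha(b"".join(np.ascontiguousarray(s.values).tobytes() for s in scans)),
        }
    }
    processed = [
        preprocess_scan(
            s,
            duration_s=config.duration_s,
            target_period_s=config.target_period_s,
            avg_k=int(config.avg_k),
            normalization=config.normalization,
        )
        for s in scans
    ]
    manifest["stages"]["preprocess"] = {
        "grid": list(processed[0].dims),
        "sha256": _sha(b"".join(np.ascontiguousarray(s.values).tobytes() for s in processed)),
    }
    cohort = Cohort(scans=processed, phenotypes=phenotypes)
    folds = make_folds(
        phenotypes["dx"], phenotypes["site"], n_folds=config.n_folds, seed=config.seed
    )

    specs = [FeatureSpec.phenotypic_only()]
    for p in config.processes:
        specs.append(FeatureSpec.from_process(p, m=config.m, sigma=config.sigma))
        if config.include_phenotypes:
            specs.append(
                FeatureSpec.from_process(p, use_phenotypes=True, m=config.m, sigma=config.sigma)
            )
    results = [
        cross_validate(
            cohort,
            fs,
            config.setting,
            folds,
            C=config.svm_c,
            transductive=config.transductive,
        )
        for fs in specs
    ]
    df = results_table(results)
    manifest["stages"]["evaluate"] = {
        "n_results": len(results),
        "sha256": _sha(df.to_csv(index=False).encode()),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "results.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        manifest["outputs"] = ["results.csv", "manifest.json"]
    return results, manifest


def _versions() -> dict:
    import nibabel
    import pandas
    import scipy
    import sklearn

    from . import __version__

    return {
        "fmridx": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "nibabel": nibabel.__version__,
    }
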