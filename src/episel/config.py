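"""Run configuration (YAML), manifests and bundled test fixtures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._rng import child_seed
from .experiment import ExperimentConfig

__all__ = ["parse_config", "serialize_config", "RunManifest", "make_fixture"]

_FIELDS = {f.name: f for f in dataclasses.fields(ExperimentConfig)}


def parse_config(path: str | Path | dict) -> ExperimentConfig:
    """Load an experiment configuration from a YAML file (or mapping).

    Unknown keys are rejected (named in the error); omitted keys take the
    standard defaults (N=500, 7 generations, 10% selected per sex, ...).
    """
    if isinstance(path, dict):
        raw = dict(path)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping of option: value")
    unknown = sorted(set(raw) - set(_FIELDS))
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return ExperimentConfig(**raw)


def serialize_config(config: ExperimentConfig) -> str:
    """YAML text that round-trips through :func:`parse_config`."""
    return yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)


@dataclass
class RunManifest:
    """Reproducibility record for one run directory."""

    config: dict
    root_seed: int
    replicate_seeds: list[int]
    version: str
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256

    @classmethod
    def for_run(cls, config: ExperimentConfig) -> "RunManifest":
        from . import __version__

        return cls(
            config=dataclasses.asdict(config),
            root_seed=config.seed,
            replicate_seeds=[child_seed(config.seed, "replicate", r)
                             for r in range(config.n_replicates)],
            version=__version__,
        )

    def register(self, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[Path(path).name] = digest

    def write(self, path: Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def make_fixture(size: str = "tiny", seed: int = 0) -> ExperimentConfig:
    """Bundled desk-scale configurations for tests and smoke runs.

    ``tiny`` (seconds): 240 sites over 3 chromosomes, 20 founder lines,
    8 QTN in 4 pairs, N = 40, 2+2 parents, short chains.  ``small``
    (minutes): 5,000 sites, N = 250, one replicate.  With so few QTN the
    frequency-calibration targets are matched loosely.
    """
    if size == "tiny":
        return ExperimentConfig(
            seed=seed, n_sites=240, n_lines=20, n_large=2, n_small=6,
            N=40, n_sires=2, n_dams=2, offspring_per_mating=20,
            burn_generations=3, n_generations=2, n_replicates=1,
            n_iter=300, mcmc_burn_in=100,
            qtn_corr_tol=0.7, qtn_mean_tol=0.15,
            bv_subsample=0, track_inbreeding=True,
        )
    if size == "small":
        return ExperimentConfig(
            seed=seed, n_sites=5000, n_lines=205, N=250,
            n_sires=25, n_dams=25, offspring_per_mating=10,
            burn_generations=10, n_generations=7, n_replicates=1,
            n_iter=2000, mcmc_burn_in=500,
            bv_subsample=0,
        )
    raise ValueError("size must be 'tiny' or 'small'")
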