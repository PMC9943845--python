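"""Run configuration, seeding and logging plumbing.

A run is fully described by a :class:`RunConfig`: scheme source, parameter
ranges, SNR, fitter choice/hyperparameters and a single global seed.  The
config serialises to YAML and is written next to every artifact directory
so a run can be reproduced exactly.

Seeding rule: the single global seed is expanded into independent
per-stage seeds with ``stage_seed(seed, stage)`` =
``SeedSequence(seed, spawn_key=(hash32(stage),)).generate_state(1)``, so
stages are decoupled yet each is a pure function of (seed, stage name).
"""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .fit_dnn import DnnHyperparams
from .simulate import DEFAULT_SNR, ParameterRanges

__all__ = ["RunConfig", "stage_seed", "setup_logging", "load_config", "save_config"]

log = logging.getLogger("rverdict")


def setup_logging(logfile=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from one global seed."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "little")
    ss = np.random.SeedSequence(seed, spawn_key=(h,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    scheme: str = "innovate"            # path to a scheme table or "innovate"
    snr: float = DEFAULT_SNR
    seed: int = 0
    fitter: str = "dnn"                 # "dnn" | "nlls"
    training_n: int = 100_000
    ranges: ParameterRanges = field(default_factory=ParameterRanges)
    dnn: DnnHyperparams = field(default_factory=DnnHyperparams)
    nlls_grid_points: int = 3
    nlls_refine: int = 10
    output_dir: str = "rverdict-out"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dnn"]["hidden"] = list(d["dnn"]["hidden"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "ranges" in d and isinstance(d["ranges"], dict):
            d["ranges"] = ParameterRanges(
                **{k: tuple(v) for k, v in d["ranges"].items()}
            )
        if "dnn" in d and isinstance(d["dnn"], dict):
            dn = dict(d["dnn"])
            if "hidden" in dn:
                dn["hidden"] = tuple(dn["hidden"])
            d["dnn"] = DnnHyperparams(**dn)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
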