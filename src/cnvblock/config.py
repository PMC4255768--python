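"""Run configurations: packaged cohort presets, YAML round-trip, hashing.

Two presets mirror the study conditions of the two end-to-end analyses:

* ``human_config`` -- a 68-sample cohort, one contiguous 322-kb CNV block
  (diploid copy numbers 2-7 against a diploid reference) inside a 1.2-Mb
  region tiled at ~2.4 probes/kb, with decoy CNVs in both flanks whose copy
  numbers are independent of the block's, and a 2-kb polymorphic dropout
  (an element absent in 12 of the 68) inside the block. Copy number is
  assayed by PRT.
* ``macaque_config`` -- a 16-sample cohort, a 20-kb tandem-repeat CNV (copy
  numbers 3-6) inside a 982-kb region tiled at ~1.5 probes/kb and a noisier
  platform, assayed by PRT and duplex ddPCR with ddPCR as the integer-call
  anchor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .genome import Interval
from .synthetic import CohortConfig, DecoySpec, DropoutSpec, NoiseModel


def human_config(n_samples: int = 68) -> CohortConfig:
    """Human-locus-like preset: 322-kb block, copy numbers 2-7, PRT assay."""
    return CohortConfig(
        name="human",
        region=Interval("chrSim", 0, 1_200_000),
        mean_spacing=412.0,
        block=Interval("chrSim", 450_000, 772_000),  # 322 kb
        cn_range=(2, 7),
        n_samples=n_samples,
        noise=NoiseModel(sd=0.15),
        decoys=(
            DecoySpec(Interval("chrSim", 80_000, 200_000), cn_range=(1, 4)),
            DecoySpec(Interval("chrSim", 900_000, 1_100_000), cn_range=(1, 4)),
        ),
        dropout=DropoutSpec(
            Interval("chrSim", 600_000, 602_000), n_carriers=12, delta=1.0
        ),
        assay_names=("prt",),
        anchor_method="prt",
    )


def macaque_config(n_samples: int = 16) -> CohortConfig:
    """Macaque-locus-like preset: 20-kb tandem unit, copy numbers 3-6,
    noisier platform, PRT + ddPCR with ddPCR anchoring integer calls."""
    return CohortConfig(
        name="macaque",
        region=Interval("chrSim", 0, 982_000),
        mean_spacing=667.0,
        block=Interval("chrSim", 481_000, 501_000),  # 20 kb
        cn_range=(3, 6),
        n_samples=n_samples,
        noise=NoiseModel(sd=0.25),
        decoys=(DecoySpec(Interval("chrSim", 100_000, 160_000), cn_range=(1, 4)),),
        dropout=None,
        assay_names=("prt", "ddpcr"),
        anchor_method="ddpcr",
    )


PRESETS = {"human": human_config, "macaque": macaque_config}


def config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)


def config_from_dict(data: dict) -> CohortConfig:
    try:
        return CohortConfig(
            name=data["name"],
            region=Interval(**data["region"]),
            mean_spacing=float(data["mean_spacing"]),
            block=Interval(**data["block"]),
            cn_range=tuple(data["cn_range"]),
            n_samples=int(data["n_samples"]),
            noise=NoiseModel(**data.get("noise", {})),
            decoys=tuple(
                DecoySpec(
                    interval=Interval(**d["interval"]),
                    cn_range=tuple(d.get("cn_range", (1, 4))),
                )
                for d in data.get("decoys", [])
            ),
            dropout=(
                DropoutSpec(
                    interval=Interval(**data["dropout"]["interval"]),
                    n_carriers=int(data["dropout"]["n_carriers"]),
                    delta=float(data["dropout"].get("delta", 1.0)),
                )
                if data.get("dropout")
                else None
            ),
            reference_cn=int(data.get("reference_cn", 2)),
            assay_names=tuple(data.get("assay_names", ("prt", "ddpcr"))),
            anchor_method=data.get("anchor_method", "ddpcr"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid cohort config: {exc}") from exc


def save_config(config: CohortConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)


def config_hash(config: CohortConfig) -> str:
    """Short stable digest of a configuration, for output-file provenance."""
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
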