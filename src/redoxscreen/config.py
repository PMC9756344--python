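"""Run configuration: every tunable in one serializable place.

All randomness in a run flows from a single master seed; per-component
seeds are derived deterministically with :func:`derive_seed` and recorded
in the run manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, asdict, fields

import yaml


def derive_seed(master_seed: int, component: str) -> int:
    """Stable per-component seed below 2**31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{component}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Defaults for every pipeline stage.

    Unknown keys in a config file are rejected rather than ignored, so a
    typo cannot silently fall back to a default.
    """

    master_seed: int = 0

    # qm_features
    imputation_sentinel: float = 0.0

    # graph_embedding
    label_precision: int = 3
    wl_depth: int = 3
    embedding_dimension: int = 128
    embedding_epochs: int = 50
    negative_samples: int = 5
    embedding_learning_rate: float = 0.025
    use_bond_orders: bool = False
    infer_steps: int = 50

    # fingerprint_baselines
    morgan_radius: int = 2
    morgan_length: int = 1024
    sweep_radii: tuple[int, ...] = (1, 2, 3)
    sweep_lengths: tuple[int, ...] = (512, 1024, 2048)

    # modeling
    site_max_iter: int = 200
    site_threshold: float = 0.5
    logo_mode: str = "pooled"
    pls_components: int = 5
    ensemble_members: int = 10
    ensemble_train_fraction: float = 116 / 141
    ridge_alpha: float = 1.0
    ridge_alpha_grid: tuple[float, ...] | None = None

    # synthetic_data
    n_molecules: int = 141
    atom_range: tuple[int, int] = (4, 12)
    positive_fraction: float = 60 / 141
    site_positive_fraction: float = 0.08
    n_template_groups: int = 5
    noise_scale: float = 0.1

    def seed_for(self, component: str) -> int:
        return derive_seed(self.master_seed, component)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("sweep_radii", "sweep_lengths", "atom_range",
                    "ridge_alpha_grid"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("sweep_radii", "sweep_lengths", "atom_range",
                    "ridge_alpha_grid"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
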