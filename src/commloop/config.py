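"""Model and run configuration.

``ModelConfig`` mirrors the network hyperparameters: 128 single-feature and
96 pair-feature channels per residue, eight refinement cycles with shared
parameters, AlphaFold-style IPA sizes, and the loss weights
(1.0, 1.0, 0.3, 0.5) for the structure terms and (0.01, 1.0) for the
auxiliary terms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ModelConfig:
    # feature sizes
    c_s: int = 128                 # single-feature channels per residue
    c_z: int = 96                  # pair-feature channels per residue pair
    embed_dim: int = 2560          # width of the sequence-embedding input
    community_size: int = 32       # N, number of community members
    n_cycles: int = 8              # refinement cycles (shared parameters)

    # invariant point attention
    ipa_heads: int = 8
    ipa_qk_points: int = 4
    ipa_v_points: int = 8

    # community cross-over attention
    crossover_heads: int = 8

    # pair stack
    n_triangle_blocks: int = 2
    tri_mult_hidden: int = 128
    tri_attn_heads: int = 4
    tri_attn_channels: int = 32
    pair_transition_factor: int = 2

    # output heads
    distogram_bins: int = 64
    distogram_min: float = 2.0     # Angstrom
    distogram_max: float = 22.0    # Angstrom
    plddt_bins: int = 50
    torsion_blocks: int = 2

    # initialization perturbations (Angstrom / degrees)
    loop_trans_perturb: float = 1.0
    loop_rot_perturb_deg: float = 15.0
    framework_trans_perturb: float = 0.1
    framework_rot_perturb_deg: float = 2.0

    # loss weights
    w_rmsd: float = 1.0
    w_fape: float = 1.0
    w_disto: float = 0.3
    w_tors: float = 0.5
    w_plddt: float = 0.01
    w_viol: float = 1.0

    # training / loss internals
    fape_clamp: float = 10.0       # Angstrom
    fape_scale: float = 10.0       # Angstrom
    lddt_radius: float = 15.0      # Angstrom inclusion radius
    crop_size: int = 100
    crop_center_perturb: float = 2.0   # Angstrom
    p_drop_antigen: float = 0.7
    p_include_other_cdrs: float = 0.5
    other_cdrs_flexible: bool = True

    seed: int = 0

    def __post_init__(self):
        for name in ("c_s", "c_z", "community_size", "n_cycles", "ipa_heads",
                     "ipa_qk_points", "ipa_v_points", "crossover_heads",
                     "distogram_bins", "plddt_bins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.c_s % self.crossover_heads:
            raise ValueError("c_s must be divisible by crossover_heads")
        if self.c_s % self.ipa_heads:
            raise ValueError("c_s must be divisible by ipa_heads")
        for w in ("w_rmsd", "w_fape", "w_disto", "w_tors", "w_plddt", "w_viol"):
            if getattr(self, w) < 0:
                raise ValueError(f"{w} must be >= 0")

    @property
    def loss_weights(self) -> dict[str, float]:
        return {"rmsd": self.w_rmsd, "fape": self.w_fape, "disto": self.w_disto,
                "tors": self.w_tors, "plddt": self.w_plddt, "viol": self.w_viol}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kw) -> "ModelConfig":
        return dataclasses.replace(self, **kw)

    # -- file round trip ------------------------------------------------
    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def show(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def toy_config(**overrides) -> ModelConfig:
    """Desk-scale configuration used by fixtures, toy training and tests."""
    base = dict(c_s=32, c_z=16, embed_dim=64, community_size=4, n_cycles=2,
                ipa_heads=4, ipa_qk_points=4, ipa_v_points=4,
                crossover_heads=4, tri_mult_hidden=32, tri_attn_heads=2,
                tri_attn_channels=8, distogram_bins=16, plddt_bins=10,
                crop_size=24)
    base.update(overrides)
    return ModelConfig(**base)
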