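"""Run configuration: YAML-backed, schema-validated, paper-default values.

Every physical parameter has a named default equal to the reference
protocol (kBT=1, dt=1e-4, xi=0.5, kappa=30, R0=1.5, 20 sigma box,
phi=0.15); protocol presets scale only the run length and box:

* smoke: 1e5 steps, small box — seconds, for wiring tests
* desk:  1e7 steps — minutes-to-hours, qualitative self-assembly
* paper: 3.5e8 steps, 20 sigma box — the full published protocol
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class MoleculeConfig(BaseModel):
    x: int = Field(8, ge=1, description="backbone length (A beads)")
    y: int = Field(1, ge=0, description="side-chain length (B beads)")
    n: int = Field(2, ge=0, description="grafting number")
    topology_seed: int = 0

    @model_validator(mode="after")
    def _n_le_x(self):
        if self.n > self.x:
            raise ValueError(f"grafting number n={self.n} exceeds backbone x={self.x}")
        return self


class ForceFieldConfig(BaseModel):
    kappa: float = Field(30.0, gt=0)
    R0: float = Field(1.5, gt=0)
    epsilon: float = Field(1.0, gt=0)
    sigma: float = Field(1.0, gt=0)
    cutoff_aa: float = Field(2.5, gt=0)
    cutoff_ab: float = Field(2.0 ** (1 / 6), gt=0)
    cutoff_bb: float = Field(2.0 ** (1 / 6), gt=0)
    exclude_bonded_lj: bool = False


class ProtocolConfig(BaseModel):
    preset: Literal["smoke", "desk", "paper", "custom"] = "custom"
    kBT: float = Field(1.0, gt=0)
    dt: float = Field(1e-4, gt=0)
    xi: float = Field(0.5, gt=0)
    n_steps: int = Field(100_000, ge=0)
    save_every: int = Field(10_000, ge=1)
    replicas: int = Field(1, ge=1)
    seed: int = 0
    equilibration_fraction: float = Field(
        0.5, ge=0, lt=1,
        description="fraction of initial frames excluded from ensemble averages",
    )

    @model_validator(mode="after")
    def _apply_preset(self):
        presets = {
            "smoke": 100_000,
            "desk": 10_000_000,
            "paper": 350_000_000,
        }
        if self.preset in presets and self.n_steps == 100_000 and self.preset != "smoke":
            self.n_steps = presets[self.preset]
        return self


class BoxConfig(BaseModel):
    lengths: tuple[float, float, float] = (20.0, 20.0, 20.0)
    phi: float = Field(0.15, gt=0, lt=1)
    placement_seed: int = 0


class AnalysisConfig(BaseModel):
    cluster_cutoff: float = Field(1.5, gt=0)
    shell_width: float = Field(0.25, gt=0)
    dispersed_chain_fraction: float = 0.5
    asphericity_spherical: float = 0.1
    cavity_min_shells: int = 2
    bowl_max_open_fraction: float = 0.5
    profile_peak_fraction: float = 0.1
    smoothing_window: int = 5
    coexist_fraction: float = 0.25


class SCFTConfig(BaseModel):
    chiN: float = Field(15.0, ge=0)
    phi: float = Field(0.15, gt=0, lt=1)
    gamma: float = Field(0.2, gt=0)
    ds: float = Field(0.0125, gt=0)
    mix: float = Field(0.1, gt=0)
    max_iter: int = Field(20000, ge=1)
    tol: float = 1e-6


class RunConfig(BaseModel):
    molecule: MoleculeConfig = MoleculeConfig()
    forcefield: ForceFieldConfig = ForceFieldConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    box: BoxConfig = BoxConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    scft: SCFTConfig = SCFTConfig()
    output_dir: str = "combsim_out"
    trajectory_format: Literal["xyz", "lammps"] = "xyz"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    # ---- object factories -------------------------------------------------

    def pair_table(self):
        import numpy as np

        from .forcefield import PairTable

        ff = self.forcefield
        return PairTable(
            epsilon=np.full((2, 2), ff.epsilon),
            sigma=np.full((2, 2), ff.sigma),
            rc=np.array([
                [ff.cutoff_aa, ff.cutoff_ab],
                [ff.cutoff_ab, ff.cutoff_bb],
            ]),
        )

    def fene(self):
        from .forcefield import FENEParams

        return FENEParams(kappa=self.forcefield.kappa, R0=self.forcefield.R0)

    def bd_params(self, seed: int | None = None):
        from .bd import BDParams

        p = self.protocol
        return BDParams(
            dt=p.dt, xi=p.xi, kBT=p.kBT, n_steps=p.n_steps,
            save_every=p.save_every,
            seed=p.seed if seed is None else seed,
            exclude_bonded_lj=self.forcefield.exclude_bonded_lj,
        )

    def topology(self):
        from .topology import make_topology

        m = self.molecule
        return make_topology(m.x, m.y, m.n, m.topology_seed)

    def packing_spec(self):
        from .builder import PackingSpec

        return PackingSpec(
            box=self.box.lengths, phi=self.box.phi,
            placement_seed=self.box.placement_seed,
        )

    def thresholds(self):
        from .analysis import ClassifierThresholds

        a = self.analysis
        return ClassifierThresholds(
            cluster_cutoff=a.cluster_cutoff,
            dispersed_chain_fraction=a.dispersed_chain_fraction,
            asphericity_spherical=a.asphericity_spherical,
            cavity_min_shells=a.cavity_min_shells,
            shell_width=a.shell_width,
            bowl_max_open_fraction=a.bowl_max_open_fraction,
            profile_peak_fraction=a.profile_peak_fraction,
        )

    def scft_params(self, architecture=None):
        from .scft import SCFTParams, StarArchitecture

        s = self.scft
        return SCFTParams(
            chiN=s.chiN, phi=s.phi, gamma=s.gamma, ds=s.ds, mix=s.mix,
            max_iter=s.max_iter, tol=s.tol,
            architecture=architecture or StarArchitecture(),
        )
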