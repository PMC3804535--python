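"""Validated run configuration.

All tunable sampling/energy parameters in one structured, YAML-loadable
object.  Defaults are the standard protocol settings (20-degree grids, 0.8
rama filter, 0.10/0.25/1.0 A clustering radii, 400-model stages, 1000 CCD
cycles, 1.5 A closure screen, chainbreak weight 150); ``coarse()`` returns
the scaled-down desk-size preset used by the synthetic-fixture studies.
"""

from __future__ import annotations

from pydantic import BaseModel, Field

from .buildup import GridSpec


class GridConfig(BaseModel):
    torsion_step: float = 20.0
    rama_cutoff: float = 0.8
    sample_adjacent: bool = True
    cis_preproline: bool = True

    def spec(self) -> GridSpec:
        return GridSpec(self.torsion_step, self.rama_cutoff,
                        self.sample_adjacent, self.cis_preproline)


class SamplingConfig(BaseModel):
    rotamer_sweeps: int = 2
    neighbor_cutoff: float = 10.0
    prepack_sweeps: int = 20


class RetentionConfig(BaseModel):
    collate_max: int = 4000
    fine_radius: float = 0.10
    stage_radius: float = 0.25
    keep: int = 400
    final_radius: float = 1.0
    final_keep: int = 5


class ClosureConfig(BaseModel):
    max_cycles: int = 1000
    tol: float = 1.0e-4
    screen: float = 1.5
    chainbreak_weight: float = 150.0
    max_parents: int | None = None
    recombine_max_pairs: int = 10000


class MinimizeConfig(BaseModel):
    max_iter: int = 200
    tol: float = 1.0e-4
    grow_max_iter: int = 50
    closure_max_iter: int = 60
    final_polish_iter: int = 150


class EnergyConfig(BaseModel):
    sampling_overrides: dict[str, float] = Field(default_factory=dict)
    minimization_overrides: dict[str, float] = Field(default_factory=dict)


class NativeScreenConfig(BaseModel):
    """Native-constrained runs: backbone-RMSD screen + fade restraints."""

    rmsd_screen: float | None = None
    constrain_ca: bool = False


class RunConfig(BaseModel):
    mode: str = "auto"  # auto | linear | full
    max_gap: int = 3
    seed: int = 0
    sample_loop_takeoff: bool = False
    grid: GridConfig = Field(default_factory=GridConfig)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    retention: RetentionConfig = Field(default_factory=RetentionConfig)
    closure: ClosureConfig = Field(default_factory=ClosureConfig)
    minimize: MinimizeConfig = Field(default_factory=MinimizeConfig)
    energy: EnergyConfig = Field(default_factory=EnergyConfig)
    native: NativeScreenConfig = Field(default_factory=NativeScreenConfig)

    @classmethod
    def coarse(cls, **overrides) -> "RunConfig":
        """Desk-scale preset: same protocol, smaller ensembles.

        Keeps the 20-degree grid and all protocol thresholds but carries
        fewer models per stage, samples only the newly added residue's
        backbone, and runs shorter minimizations, so a complete loop
        rebuild finishes in minutes on one CPU.
        """
        cfg = cls(
            grid=GridConfig(sample_adjacent=False),
            sampling=SamplingConfig(rotamer_sweeps=1, prepack_sweeps=8),
            retention=RetentionConfig(collate_max=60, keep=8),
            closure=ClosureConfig(max_cycles=200, max_parents=8,
                                  recombine_max_pairs=12),
            minimize=MinimizeConfig(grow_max_iter=12, closure_max_iter=18,
                                    final_polish_iter=100),
        )
        return cfg.model_copy(update=overrides)


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def default_config_yaml() -> str:
    import yaml

    return yaml.safe_dump(RunConfig().model_dump(), sort_keys=False)
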