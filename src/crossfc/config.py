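"""Pipeline configuration.

Defaults reproduce the emulated study's analysis settings: discard 5
volumes, pooled 5-component CompCor, 12 motion regressors, scrub at
composite displacement 0.9 mm / global-signal z 5, exclude at >30% bad
volumes or >3 mm translation, band-pass 0.01-0.1 Hz, gFCD threshold 0.6
(robustness 0.4/0.5), 8 mm FWHM smoothing of derived maps, cluster
inference at height p < 0.001 with cluster-level FWE alpha 0.05.
Configs load from YAML; CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import asdict, dataclass

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    cohort_root: str = ""
    output_root: str = ""
    # preprocessing
    n_discard: int = 5
    band_hz: tuple[float, float] = (0.01, 0.1)
    compcor_k: int = 5
    filter_order: int = 2
    fd_threshold_mm: float = 0.9
    global_z_threshold: float = 5.0
    bad_fraction_max: float = 0.30
    max_translation_mm: float = 3.0
    scrub_mode: str = "regress"
    # derived maps
    gfcd_threshold: float = 0.6
    gfcd_robustness_thresholds: tuple[float, ...] = (0.4, 0.5)
    fwhm_mm: float = 8.0
    # group statistics
    height_p: float = 0.001
    cluster_alpha: float = 0.05
    n_permutations: int = 1000
    connectivity: int = 18
    rng_seed: int = 0
    # exploratory thresholding (p < 0.005, extent > 10) without FWE control
    uncorrected: bool = False

    def __post_init__(self) -> None:
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if not 0 < self.gfcd_threshold < 1:
            raise ValueError("gfcd_threshold must lie in (0, 1)")
        if not 0 < self.height_p < 1:
            raise ValueError("height_p must lie in (0, 1)")
        if self.scrub_mode not in ("regress", "delete"):
            raise ValueError("scrub_mode must be 'regress' or 'delete'")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config; keyword overrides win over file values."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(loaded) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("band_hz", "gfcd_robustness_thresholds"):
        if key in values and isinstance(values[key], list):
            values[key] = tuple(values[key])
    return PipelineConfig(**values)
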