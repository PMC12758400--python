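"""Pipeline configuration: one structured YAML file drives everything.

Every tunable default of the analysis lives here with a range check;
unknown keys are rejected at load so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"config: {msg}")


@dataclass
class Params:
    mapq_min: int = 20
    repli_bin_bp: int = 1000
    window_bins: int = 3
    repli_max_width: int = 500
    prior_sd: float = 2.0
    grid_lo: float = -10.0
    grid_hi: float = 10.0
    grid_points: int = 801
    loess_span_bp: float = 100_000.0
    seed_bf: float = 1.0
    extend_bf: float = 0.5
    max_gap_bp: int = 3000
    min_region_bp: int = 20_000
    chic_step_bp: int = 20
    mono_len_min: int = 100
    mono_len_max: int = 200
    sigma_bp: float = 40.0
    epsilon: float | None = None       # None -> 5th-percentile rule
    min_prominence: float | None = None
    cpm_threshold: float = 5.0
    fc_min: float = 1.5
    s_max: float = 1e-4
    fe_hi: float = 0.2
    fe_lo: float = -0.2
    tss_flank_bp: int = 1000

    def validate(self) -> None:
        _check(self.mapq_min >= 0, "mapq_min must be >= 0")
        _check(self.repli_bin_bp > 0, "repli_bin_bp must be positive")
        _check(self.window_bins >= 1 and self.window_bins % 2 == 1,
               "window_bins must be odd and >= 1")
        _check(self.prior_sd > 0, "prior_sd must be positive")
        _check(self.grid_lo < 0 < self.grid_hi and
               abs(self.grid_lo + self.grid_hi) < 1e-12,
               "theta grid must be symmetric about 0")
        _check(self.grid_points >= 3, "grid_points must be >= 3")
        _check(self.seed_bf >= self.extend_bf,
               "seed_bf must be >= extend_bf")
        _check(self.min_region_bp > 0, "min_region_bp must be positive")
        _check(self.mono_len_min < self.mono_len_max,
               "mono_len_min must be < mono_len_max")
        _check(self.sigma_bp > 0, "sigma_bp must be positive")
        _check(self.epsilon is None or self.epsilon > 0,
               "epsilon must be positive")
        _check(self.cpm_threshold >= 0, "cpm_threshold must be >= 0")
        _check(self.fc_min > 1, "fc_min must exceed 1")
        _check(0 < self.s_max < 1, "s_max must be in (0, 1)")
        _check(self.fe_hi > 0 > self.fe_lo, "fe bounds must bracket 0")


@dataclass
class PipelineConfig:
    layout: str = "layout.yaml"
    input_dir: str = "."
    output_dir: str = "out"
    cell_types: list[str] = field(default_factory=lambda: ["GSC", "CySC"])
    marks: list[str] = field(default_factory=lambda: ["H3K4me3", "H3K27me3",
                                                      "H3K9me3"])
    replicates: int = 2
    seed: int = 0
    params: Params = field(default_factory=Params)

    def validate(self) -> None:
        _check(len(self.cell_types) >= 1, "need at least one cell type")
        _check(self.replicates >= 1, "need at least one replicate")
        self.params.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        params_raw = payload.pop("params", {})
        known = {f.name for f in fields(cls)} - {"params"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"config: unknown keys {sorted(unknown)}")
        pknown = {f.name for f in fields(Params)}
        punknown = set(params_raw) - pknown
        if punknown:
            raise ValueError(f"config: unknown parameter keys "
                             f"{sorted(punknown)}")
        cfg = cls(**payload, params=Params(**params_raw))
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)
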