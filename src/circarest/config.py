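"""Analysis configuration: every tunable threshold, cutoff, resample count
and seed in one place, loadable from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class IngestConfig:
    room_temp_c: float = 21.0        # indoor reference for off-body detection
    offbody_delta_c: float = 2.0     # "near room temperature" tolerance
    offbody_plateau_min: int = 10    # minimum plateau length to flag
    offbody_decay_window_min: int = 15  # backward monotone-decay extension
    temp_band_c: tuple = (15.0, 42.0)   # plausibility band for skin temperature
    bin_missing_frac: float = 0.5    # >50% missing minutes -> bin missing
    interp_warn_frac: float = 0.30   # warn when more than 30% interpolated
    interp_hard_fail: bool = False


@dataclass
class DichotomyConfig:
    threshold_percent: float = 97.5  # low/high classification boundary
    classification_window_h: float = 72.0
    min_out_of_bed_h: float = 4.0


@dataclass
class HmmConfig:
    bin_min: int = 5
    n_states: int = 3
    n_restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-6                # relative log-likelihood change
    degenerate_mass: float = 0.01    # state posterior mass below this -> refit
    harmonic_em_iter: int = 15


@dataclass
class RhythmConfig:
    period_min_h: float = 6.0
    period_max_h: float = 30.0
    period_step_h: float = 0.1
    n_resamples: int = 500
    n_scrambles: int = 200
    significance_level: float = 0.05


@dataclass
class CosinorConfig:
    n_bootstrap: int = 500
    alpha: float = 0.10              # 90% confidence intervals
    f_test_alpha: float = 0.05
    min_profile_coverage: float = 0.5
    cortisol_min_samples: int = 9


@dataclass
class DlmoConfig:
    dim_light_cutoff_lux: float = 50.0
    dim_light_peak_factor: float = 4.0
    rise_fraction: float = 0.25      # sustained-rise size relative to run mean
    baseline_cv_max: float = 0.33


@dataclass
class DeterminantsConfig:
    max_predictors: int = 4
    include_intercept: bool = True
    min_pairs: int = 5


@dataclass
class AnalysisConfig:
    seed: int = 0
    ingest: IngestConfig = field(default_factory=IngestConfig)
    dichotomy: DichotomyConfig = field(default_factory=DichotomyConfig)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    rhythm: RhythmConfig = field(default_factory=RhythmConfig)
    cosinor: CosinorConfig = field(default_factory=CosinorConfig)
    dlmo: DlmoConfig = field(default_factory=DlmoConfig)
    determinants: DeterminantsConfig = field(default_factory=DeterminantsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in d:
                continue
            v = d[f.name]
            if dataclasses.is_dataclass(f.type) or f.name != "seed":
                sub_cls = {
                    "ingest": IngestConfig, "dichotomy": DichotomyConfig,
                    "hmm": HmmConfig, "rhythm": RhythmConfig,
                    "cosinor": CosinorConfig, "dlmo": DlmoConfig,
                    "determinants": DeterminantsConfig,
                }.get(f.name)
                kwargs[f.name] = sub_cls(**v) if sub_cls else v
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
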