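"""Flat run configuration with paper-default constants, YAML-loadable.

Every stage parameter defaults to the protocol value: 256 Hz sampling,
0.5-5 Hz fourth-order zero-phase band-pass, 0.5 s event windows, factor-16
decimation, 100-sample DTW resampling, 10 rows per participant, 300 trees,
100 iterations.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .classify import ClassifierConfig
from .features import FeatureConfig
from .preprocess import FilterSpec


@dataclass
class RunConfig:
    # paths
    input_dir: str = ""
    output_dir: str = "runs"
    # data model
    fs: float = 256.0
    # signal prep
    band_low_hz: float = 0.5
    band_high_hz: float = 5.0
    filter_order: int = 4
    decimation_factor: int = 16
    event_window_s: float = 0.5
    # features
    dtw_resample_len: int = 100
    pitch_alpha: float = 0.98
    thigh_length_m: float = 0.40
    shank_length_m: float = 0.40
    # classification
    rows_per_participant: int = 10
    n_trees: int = 300
    n_iterations: int = 100
    adasyn_neighbors: int = 5
    seed: int = 0

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(band=(self.band_low_hz, self.band_high_hz),
                          order=self.filter_order)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(resample_len=self.dtw_resample_len,
                             pitch_alpha=self.pitch_alpha,
                             thigh_length_m=self.thigh_length_m,
                             shank_length_m=self.shank_length_m)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(n_trees=self.n_trees,
                                n_iterations=self.n_iterations,
                                adasyn_neighbors=self.adasyn_neighbors,
                                rows_per_participant=self.rows_per_participant,
                                master_seed=self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
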