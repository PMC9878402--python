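"""Pipeline configuration and logging.

All defaults mirror the analysis conventions of the emulated study design:
25-frame sliding window (18 s at TR 0.72 s), k = 12 sub-clusters, 100
k-means restarts, FD scrubbing at 0.5 mm with a 30-frame tail, a 60-event
minimum per run, 0.009-0.08 Hz band, 38-frame run trimming, 50-frame GLM
trimming, 50-frame occurrence smoothing, and 100-frame PMI exclusions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger("swsync")


def get_logger() -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


@dataclass
class PipelineConfig:
    """Every tunable parameter of the end-to-end pipeline."""

    tr: float = 0.72                 # seconds
    window_size: int = 25            # frames (odd)
    k: int = 12                      # sub-clusters
    n_init: int = 100                # k-means restarts
    fd_threshold: float = 0.5        # mm
    scrub_after: int = 30            # frames masked after a movement
    min_ts: int = 60                 # minimum TS events per run
    band_low: float = 0.009          # Hz
    band_high: float = 0.08          # Hz
    trim: int = 38                   # frames trimmed at each run edge
    glm_trim: int = 50               # frames trimmed at each edge for the GLM
    pmi_smooth: int = 50             # occurrence moving-average width, frames
    pmi_t_trim: int = 100            # frames excluded at run edges in PMI fits
    pmi_tau_min: int = 100           # minimum lag entering the lag-effect fit
    var_smooth: int = 0              # optional smoothing of the variance
                                     # timecourse before the maxima search
    knn_k: int = 100                 # neighbours for task-TSP transfer
    knn_k_alt: int = 5               # alternative preset reported alongside
    n_random: int = 10000            # random patterns for the kNN null
    cca_n_pcs: int = 50
    cca_n_perm: int = 10000
    head_radius: float = 50.0        # mm, FD rotation conversion
    seed: int = 0

    def validate(self):
        if self.window_size % 2 == 0:
            raise ValueError("window_size must be odd")
        if not (0 < self.band_low < self.band_high):
            raise ValueError("band edges must satisfy 0 < low < high")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
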