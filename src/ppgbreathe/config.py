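"""Run configuration: every tunable of the pipeline, YAML round-trippable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    The 20-s window with a 1-s slide is the primary operating point; the
    window size is sweepable (15/20/25/30 s).  Filter bands and orders match
    the two filtering procedures; quality parameters are the calibrated
    motion threshold and the two rule constants; Welch parameters control the
    spectral feature resolution; model hyperparameters are conservative
    gradient-boosting settings for feature tables of order 10^3 rows.
    """

    window_s: float = 20.0
    slide_s: float = 1.0
    # filtering procedure 1 (cardiac band) and 2 (respiration band)
    proc1_band: tuple = (0.5, 2.75)
    proc1_ma_width: int = 5
    winsor_limits: tuple = (1.0, 99.0)
    proc2_band: tuple = (0.15, 0.4)
    proc2_ma_width: int = 25
    filter_order: int = 3
    # quality
    threshold_mode: str = "tukey"
    threshold: float | None = None
    min_clean_s: int = 15
    run_len: int = 3
    # pulse
    hampel_half_window: int = 3
    hampel_n_sigmas: float = 3.0
    pp_target_fs: float = 25.0
    # spectral features
    welch_seg_s: float = 10.0
    welch_overlap: float = 0.5
    welch_grid_hz: float = 0.025
    # model
    hyperparams: dict = field(
        default_factory=lambda: {
            "n_estimators": 300,
            "learning_rate": 0.05,
            "max_depth": 4,
            "subsample": 0.8,
        }
    )
    seed: int = 0

    def filter_params(self) -> dict:
        return {
            "procedure_1": {
                "band": tuple(self.proc1_band),
                "order": self.filter_order,
                "ma_width": self.proc1_ma_width,
                "winsor_limits": tuple(self.winsor_limits),
            },
            "procedure_2": {
                "band": tuple(self.proc2_band),
                "order": self.filter_order,
                "ma_width": self.proc2_ma_width,
            },
        }

    def welch_params(self) -> dict:
        return {
            "seg_s": self.welch_seg_s,
            "overlap": self.welch_overlap,
            "grid_hz": self.welch_grid_hz,
        }

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        # YAML has no tuple type; normalize list-valued fields back
        cfg.proc1_band = tuple(cfg.proc1_band)
        cfg.proc2_band = tuple(cfg.proc2_band)
        cfg.winsor_limits = tuple(cfg.winsor_limits)
        return cfg
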