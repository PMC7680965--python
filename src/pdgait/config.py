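"""Pipeline configuration: every tunable of the analysis in one place.

Defaults follow the reference protocol where it is stated (25 hidden
resilient-backpropagation units for diagnosis, 13 hidden Levenberg-Marquardt
units with tanh activation for staging, [-1, 1] input scaling, the
oversampling amounts balancing the Hoehn & Yahr classes) and field-standard
choices where it is not (3-sample median window, 5% stance threshold,
body-weight force normalization, k = 5 SMOTE neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0

    # preprocessing
    median_window: int = 3                   # samples (30 ms)
    normalization: str = "BODY_WEIGHT"       # "BODY_WEIGHT" | "MAX"

    # segmentation / events
    stance_threshold: float = 0.05           # fraction of aggregate max
    threshold_relative: bool = True
    prominence_fraction: float = 0.10
    event_window_fraction: float = 0.40
    heel_sensor: int = 1
    toe_sensor: int = 8
    validation_mode: str = "FIG4_ORDER"      # | "LITERAL_INEQUALITY"

    # features
    ratio_convention: str = "CORRECTED"      # | "PAPER_LITERAL"
    fmv_floor_n: float = 1.0
    n_fmv_sensors: int = 2
    asymmetry_source: str = "stride"         # | "stance"

    # class balancing
    smote_amounts: dict = field(default_factory=lambda: {3.0: 20, 2.5: 28, 2.0: 0})
    smote_k_neighbors: int = 5
    smote_in_folds: bool = True              # never oversample test rows

    # diagnosis network
    diagnosis_hidden: int = 25
    diagnosis_algorithm: str = "RPROP"
    # severity network
    severity_hidden: int = 13
    severity_algorithm: str = "LM"

    max_epochs: int = 1000
    val_fraction: float = 0.15
    patience: int = 6

    # cross-validation
    cv_scheme: str = "KFOLD"                 # "HOLDOUT" | "KFOLD" | "LOO"
    cv_k: int = 5

    # unit of analysis
    per_subject_aggregation: bool = True     # mean feature vector per subject

    # demographics column names (canonical field -> file header)
    column_map: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        if "smote_amounts" in blob:
            blob["smote_amounts"] = {float(k): int(v)
                                     for k, v in blob["smote_amounts"].items()}
        return cls(**blob)
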