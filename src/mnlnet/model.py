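"""Model/Results front end over the cross-validation pipeline.

``MNLModel`` binds a segment table to a class-combination scheme and a
training configuration; ``fit()`` runs the stratified k-fold protocol and
returns an ``MNLResults`` carrying per-fold metrics, their means, training
histories, and a ``summary()`` table in the familiar k1..k10 + Mean layout.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .io import EvalReport, SegmentTable, read_uci_csv, write_report
from .network import ArchitectureSpec
from .preprocessing import TaskScheme, parse_scheme
from .training import TrainConfig, cross_validate

__all__ = ["MNLModel", "MNLResults"]


class MNLModel:
    """Seizure-detection classifier bound to data and a task scheme.

    Parameters
    ----------
    segments : SegmentTable
        Raw (unnormalized) segments covering at least the sets the scheme
        references; normalization happens inside the pipeline.
    scheme : str or TaskScheme
        Class-combination string, e.g. ``"A-E"`` or ``"AB-CD-E"``.
    config : TrainConfig, optional
        Optimizer/schedule settings; defaults follow the published protocol.
    arch : ArchitectureSpec, optional
        Network hyperparameters; input length and class count are inferred.
    """

    def __init__(self, segments: SegmentTable, scheme: TaskScheme | str,
                 config: TrainConfig | None = None,
                 arch: ArchitectureSpec | None = None):
        self.segments = segments
        self.scheme = parse_scheme(scheme) if isinstance(scheme, str) else scheme
        self.config = config or TrainConfig()
        self.arch = arch

    @classmethod
    def from_uci_csv(cls, path, scheme, **kwargs) -> "MNLModel":
        return cls(read_uci_csv(path), scheme, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scheme, **kwargs) -> "MNLModel":
        """Build from a UCI-layout DataFrame (numeric columns + label column 'y')."""
        import tempfile
        from pathlib import Path
        with tempfile.TemporaryDirectory() as tmp:
            p = Path(tmp) / "segments.csv"
            df.to_csv(p, index=False)
            table = read_uci_csv(p)
        return cls(table, scheme, **kwargs)

    def fit(self, k: int = 10, seed: int | None = None) -> "MNLResults":
        config = self.config if seed is None else replace(self.config, seed=seed)
        report, histories = cross_validate(
            self.segments, self.scheme, config=config, k=k, arch=self.arch,
            return_histories=True)
        return MNLResults(self, report, histories, config)


class MNLResults:
    """Cross-validated fit results: per-fold metrics and diagnostics."""

    def __init__(self, model: MNLModel, report: EvalReport,
                 histories: list[dict], config: TrainConfig):
        self.model = model
        self.report = report
        self.histories = histories
        self.config = config

    @property
    def mean_accuracy(self) -> float:
        return self.report.mean("accuracy")

    def metric_frame(self) -> pd.DataFrame:
        """Metrics as a DataFrame: one row per metric, columns k1..kN, mean."""
        rows = {}
        for metric, vals in self.report.fold_metrics.items():
            rows[metric] = {f"k{i + 1}": v for i, v in enumerate(vals)}
            rows[metric]["mean"] = self.report.mean(metric)
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        """Readable per-fold table (percentages, two decimals)."""
        df = (self.metric_frame() * 100).round(2)
        lines = [
            f"MNL-Network cross-validation  |  task {self.report.scheme}  "
            f"|  k = {self.report.k}",
            f"epochs <= {self.config.max_epochs}, lr {self.config.learning_rate}, "
            f"batch {self.config.batch_size}, seed {self.config.seed}",
            "",
            df.to_string(),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        write_report(self.report, path)

    def plot_history(self, ax=None):
        """Per-fold validation-accuracy curves (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for i, h in enumerate(self.histories):
            ax.plot(np.arange(1, len(h["val_accuracy"]) + 1),
                    h["val_accuracy"], label=f"fold {i + 1}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("validation accuracy")
        ax.set_title(f"task {self.report.scheme}")
        ax.legend(fontsize="small")
        return ax
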