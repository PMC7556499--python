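"""End-to-end orchestration: surrogate training, optimization, validation.

The optimization surrogates are five GRNNs (one per morphological response)
trained on the complete dataset rather than a 70% partition: model-family
selection happens beforehand on held-out splits, and at optimization time
the best surrogate of the data is wanted, not an honest error estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as M
from .dataset import (
    FACTOR_COLUMNS,
    RESPONSE_COLUMNS,
    ExperimentTable,
    Normalizer,
    encode_features,
)
from .evaluation import metric_set
from .nsga2 import DEFAULT_BOUNDS, GAConfig, ParetoFront, optimize, select_ideal_point


@dataclass
class SurrogateSet:
    """Five fitted GRNNs plus the normalizers that frame them.

    ``predict`` maps raw design vectors (melatonin_uM, day, species code
    +-1, fc_percent) to the five responses in original units.
    """

    x_norm: Normalizer
    y_norm: Normalizer
    models: dict  # response name -> GRNNModel
    spreads: dict  # response name -> selected h

    @classmethod
    def fit(
        cls,
        table: ExperimentTable,
        spread_grid: np.ndarray | None = None,
        exclude_suspect: bool = False,
    ) -> "SurrogateSet":
        if exclude_suspect:
            table = table.without_suspect()
        X, Y, meta = encode_features(table)
        x_norm = Normalizer.fit(X)
        y_norm = Normalizer.fit(Y)
        Xn = x_norm.apply(X)
        models, spreads = {}, {}
        for j, resp in enumerate(meta["response_columns"]):
            t_n = y_norm.apply_column(Y[:, j], j)
            h = M.select_spread(Xn, t_n, spread_grid)
            models[resp] = M.grnn_fit(Xn, t_n, h)
            spreads[resp] = h
        return cls(x_norm, y_norm, models, spreads)

    def predict(self, designs: np.ndarray) -> np.ndarray:
        """Design matrix (N x 4, original units) -> responses (N x 5)."""
        Xn = self.x_norm.apply(np.atleast_2d(np.asarray(designs, float)))
        out = np.empty((len(Xn), len(RESPONSE_COLUMNS)))
        for j, resp in enumerate(RESPONSE_COLUMNS):
            out[:, j] = self.y_norm.invert_column(self.models[resp].predict(Xn), j)
        return out

    def predict_frame(self, designs: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(self.predict(designs), columns=list(RESPONSE_COLUMNS))

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "x_norm": {"mins": self.x_norm.mins.tolist(), "maxs": self.x_norm.maxs.tolist()},
            "y_norm": {"mins": self.y_norm.mins.tolist(), "maxs": self.y_norm.maxs.tolist()},
            "models": {k: m.to_dict() for k, m in self.models.items()},
            "spreads": self.spreads,
            "feature_columns": list(FACTOR_COLUMNS),
            "response_columns": list(RESPONSE_COLUMNS),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateSet":
        return cls(
            Normalizer(np.array(d["x_norm"]["mins"]), np.array(d["x_norm"]["maxs"])),
            Normalizer(np.array(d["y_norm"]["mins"]), np.array(d["y_norm"]["maxs"])),
            {k: M.GRNNModel.from_dict(v) for k, v in d["models"].items()},
            dict(d["spreads"]),
        )

    @classmethod
    def from_json(cls, text: str) -> "SurrogateSet":
        return cls.from_dict(json.loads(text))


@dataclass
class OptimizationResult:
    front: ParetoFront
    ideal_index: int

    @property
    def ideal(self) -> pd.Series:
        return self.front.to_dataframe().iloc[self.ideal_index]


def run_optimization(
    surrogates: SurrogateSet,
    config: GAConfig,
    track_hypervolume: bool = False,
) -> OptimizationResult:
    """NSGA-II over the design box, maximizing all five predicted responses,
    then ideal-point selection on the final front."""
    front = optimize(
        surrogates.predict,
        config,
        bounds=DEFAULT_BOUNDS,
        objective_names=list(RESPONSE_COLUMNS),
        track_hypervolume=track_hypervolume,
    )
    idx = select_ideal_point(front, tie_objective=0)
    return OptimizationResult(front, idx)


def validate_predictions(
    surrogates: SurrogateSet, observed: ExperimentTable
) -> pd.DataFrame:
    """Score surrogate predictions against observed rows (R^2 / RMSE / MBE).

    The observed table may be any CSV in the packaged dialect, e.g. a
    wet-lab validation run at optimizer-selected design points.
    """
    if len(observed) == 0:
        raise ValueError("observed table is empty")
    X, Y, meta = encode_features(observed)
    pred = surrogates.predict(X)
    rows = []
    for j, resp in enumerate(meta["response_columns"]):
        ms = metric_set(Y[:, j], pred[:, j])
        rows.append(dict(response=resp, r2=ms.r2, rmse=ms.rmse, mbe=ms.mbe, n=ms.n))
    return pd.DataFrame(rows)
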