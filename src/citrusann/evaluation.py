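"""Performance measures (R^2, RMSE, MBE) and the model-family comparison.

Metrics are always computed on the original measurement scale (leaves, cm):
models are fitted on [-1, 1]-normalized features and targets, but their
predictions are mapped back through the response normalizer before scoring,
so an RMSE of e.g. 16 for the leaf-count response means 16 leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    ExperimentTable,
    Normalizer,
    SplitSpec,
    encode_features,
    split_train_test,
)
from . import models as M

FAMILIES = ("MLP", "RBF", "GRNN")


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(observed, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if len(y) != len(p) or len(y) < 2:
        raise ValueError("need two vectors of equal length >= 2")
    vy = y - y.mean()
    vp = p - p.mean()
    sy = float(vy @ vy)
    sp = float(vp @ vp)
    if sy == 0 or sp == 0:
        raise ValueError(
            "R^2 undefined: zero variance in "
            + ("observed" if sy == 0 else "predicted")
            + " values"
        )
    r = float(vy @ vp) / np.sqrt(sy * sp)
    return r * r


def mbe(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean bias error, mean(observed - predicted): negative = over-prediction."""
    y = np.asarray(observed, float).ravel()
    p = np.asarray(predicted, float).ravel()
    return float(np.mean(y - p))


def rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((observed - predicted)^2))."""
    y = np.asarray(observed, float).ravel()
    p = np.asarray(predicted, float).ravel()
    return float(np.sqrt(np.mean((y - p) ** 2)))


@dataclass(frozen=True)
class MetricSet:
    r2: float
    rmse: float
    mbe: float
    n: int


def metric_set(observed: np.ndarray, predicted: np.ndarray) -> MetricSet:
    return MetricSet(
        r_squared(observed, predicted),
        rmse(observed, predicted),
        mbe(observed, predicted),
        len(np.asarray(observed).ravel()),
    )


@dataclass
class FitContext:
    """One normalized train/test split of the encoded dataset."""

    X_train_n: np.ndarray
    X_test_n: np.ndarray
    Y_train: np.ndarray
    Y_test: np.ndarray
    x_norm: Normalizer
    y_norm: Normalizer
    train_idx: np.ndarray
    test_idx: np.ndarray


def make_split_context(
    X: np.ndarray,
    Y: np.ndarray,
    seed: int,
    train_fraction: float = 0.70,
    feature_mask: np.ndarray | None = None,
) -> FitContext:
    """Split rows, then fit normalizers on the training partition only.

    ``feature_mask`` optionally drops input columns (used by the
    sensitivity analysis) while keeping the split itself identical.
    """
    if feature_mask is not None:
        X = X[:, np.asarray(feature_mask, bool)]
    tr, te = split_train_test(len(X), SplitSpec(train_fraction, seed))
    x_norm = Normalizer.fit(X[tr])
    y_norm = Normalizer.fit(Y[tr])
    return FitContext(
        x_norm.apply(X[tr]),
        x_norm.apply(X[te]),
        Y[tr],
        Y[te],
        x_norm,
        y_norm,
        tr,
        te,
    )


def fit_family(
    family: str,
    X_train_n: np.ndarray,
    t_train_n: np.ndarray,
    seed: int,
    spread_grid: np.ndarray | None = None,
    mlp_config: M.MLPConfig | None = None,
):
    """Fit one regressor of the requested family on normalized data."""
    family = family.upper()
    if family == "GRNN":
        h = M.select_spread(X_train_n, t_train_n, spread_grid)
        return M.grnn_fit(X_train_n, t_train_n, h)
    if family == "RBF":
        h = M.select_rbf_spread(X_train_n, t_train_n, spread_grid, seed=seed)
        return M.rbf_fit(X_train_n, t_train_n, h)
    if family == "MLP":
        return M.select_mlp(X_train_n, t_train_n, config=mlp_config, seed=seed)
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class ComparisonReport:
    """Per-seed and aggregated metrics for family x response x partition."""

    per_seed: pd.DataFrame
    table: pd.DataFrame = field(init=False)
    best_family: dict = field(init=False)

    def __post_init__(self) -> None:
        agg = (
            self.per_seed.groupby(["family", "response", "partition"], sort=False)[
                ["r2", "rmse", "mbe"]
            ]
            .median()
            .reset_index()
        )
        agg["n_seeds"] = self.per_seed["seed"].nunique()
        self.table = agg
        test = agg[agg["partition"] == "test"]
        best = {}
        for resp, grp in test.groupby("response", sort=False):
            # best family: highest test R^2, ties by lower test RMSE
            grp = grp.sort_values(["r2", "rmse"], ascending=[False, True])
            best[resp] = grp.iloc[0]["family"]
        self.best_family = best


def compare_models(
    table: ExperimentTable,
    families=FAMILIES,
    responses: list[str] | None = None,
    split_seeds=(0,),
    train_fraction: float = 0.70,
    exclude_suspect: bool = False,
    spread_grid: np.ndarray | None = None,
    mlp_config: M.MLPConfig | None = None,
) -> ComparisonReport:
    """Fit every family to every response across seeded splits and score them.

    A failed fit is recorded as NaN metrics for that (family, response, seed)
    cell; it does not abort the rest of the report.
    """
    if exclude_suspect:
        table = table.without_suspect()
    X, Y, meta = encode_features(table)
    if responses is None:
        responses = meta["response_columns"]
    rows = []
    for seed in split_seeds:
        ctx = make_split_context(X, Y, seed, train_fraction)
        for j, resp in enumerate(responses):
            col = meta["response_columns"].index(resp)
            t_train_n = ctx.y_norm.apply_column(ctx.Y_train[:, col], col)
            for family in families:
                try:
                    model = fit_family(
                        family, ctx.X_train_n, t_train_n, seed, spread_grid, mlp_config
                    )
                    for part, Xn, Yobs in (
                        ("train", ctx.X_train_n, ctx.Y_train),
                        ("test", ctx.X_test_n, ctx.Y_test),
                    ):
                        pred_n = model.predict(Xn)
                        pred = ctx.y_norm.invert_column(pred_n, col)
                        ms = metric_set(Yobs[:, col], pred)
                        rows.append(
                            dict(
                                seed=seed,
                                family=family,
                                response=resp,
                                partition=part,
                                r2=ms.r2,
                                rmse=ms.rmse,
                                mbe=ms.mbe,
                                n=ms.n,
                            )
                        )
                except Exception as e:  # noqa: BLE001 - record, keep going
                    for part in ("train", "test"):
                        rows.append(
                            dict(
                                seed=seed,
                                family=family,
                                response=resp,
                                partition=part,
                                r2=np.nan,
                                rmse=np.nan,
                                mbe=np.nan,
                                n=0,
                                error=str(e),
                            )
                        )
    return ComparisonReport(pd.DataFrame(rows))
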