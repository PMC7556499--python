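"""Leave-one-input-out variable importance (VSE / VSR) for the GRNN.

VSE (variable sensitivity error) is the test RMSE of a GRNN retrained from
scratch — fresh spread selection included — with one of the four inputs
removed.  VSR is that error divided by the full four-input model's test
RMSE on the same splits; a VSR well above 1 marks an input the model cannot
do without.  "Removed" means retrained-without-feature, not zeroed or
mean-substituted: for a lazy kernel regressor, only retraining keeps the
model well defined on the reduced input space.  (A substitution mode is
available for comparison.)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models as M
from .dataset import FACTOR_COLUMNS, RESPONSE_COLUMNS, ExperimentTable, encode_features
from .evaluation import make_split_context, rmse


def _grnn_test_rmse_per_seed(
    X: np.ndarray,
    Y: np.ndarray,
    col: int,
    seeds,
    feature_mask: np.ndarray | None = None,
    spread_grid: np.ndarray | None = None,
    train_fraction: float = 0.70,
) -> np.ndarray:
    """Test RMSE (original units) of a LOO-tuned GRNN for each split seed."""
    out = []
    for seed in seeds:
        ctx = make_split_context(X, Y, seed, train_fraction, feature_mask)
        t_train_n = ctx.y_norm.apply_column(ctx.Y_train[:, col], col)
        h = M.select_spread(ctx.X_train_n, t_train_n, spread_grid)
        model = M.grnn_fit(ctx.X_train_n, t_train_n, h)
        pred = ctx.y_norm.invert_column(model.predict(ctx.X_test_n), col)
        out.append(rmse(ctx.Y_test[:, col], pred))
    return np.array(out)


def _substitute_test_rmse_per_seed(
    X: np.ndarray,
    Y: np.ndarray,
    col: int,
    seeds,
    clamp_col: int,
    spread_grid: np.ndarray | None = None,
    train_fraction: float = 0.70,
) -> np.ndarray:
    """Diagnostic alternative to retraining: keep the full model but clamp
    the excluded input to its training mean at prediction time."""
    out = []
    for seed in seeds:
        ctx = make_split_context(X, Y, seed, train_fraction)
        t_train_n = ctx.y_norm.apply_column(ctx.Y_train[:, col], col)
        h = M.select_spread(ctx.X_train_n, t_train_n, spread_grid)
        model = M.grnn_fit(ctx.X_train_n, t_train_n, h)
        X_test = ctx.X_test_n.copy()
        X_test[:, clamp_col] = ctx.X_train_n[:, clamp_col].mean()
        pred = ctx.y_norm.invert_column(model.predict(X_test), col)
        out.append(rmse(ctx.Y_test[:, col], pred))
    return np.array(out)


def _mask_for(excluded_input: str | None) -> np.ndarray | None:
    if excluded_input is None:
        return None
    if excluded_input not in FACTOR_COLUMNS:
        raise ValueError(
            f"unknown input {excluded_input!r}; expected one of {FACTOR_COLUMNS}"
        )
    mask = np.array([c != excluded_input for c in FACTOR_COLUMNS])
    return mask


def compute_vse(
    table: ExperimentTable,
    response: str,
    excluded_input: str | None,
    seeds=(0,),
    spread_grid: np.ndarray | None = None,
    exclude_suspect: bool = False,
) -> float:
    """Median test RMSE of the GRNN retrained without one input.

    ``excluded_input=None`` is the control path: it returns the full
    four-input model's RMSE itself.
    """
    if exclude_suspect:
        table = table.without_suspect()
    X, Y, meta = encode_features(table)
    mask = _mask_for(excluded_input)
    if mask is not None:
        remaining = X[:, mask]
        if any(len(np.unique(remaining[:, j])) < 2 for j in range(remaining.shape[1])):
            raise ValueError(
                f"reduced design after removing {excluded_input!r} has a "
                "constant feature column"
            )
    col = meta["response_columns"].index(response)
    per_seed = _grnn_test_rmse_per_seed(X, Y, col, seeds, mask, spread_grid)
    return float(np.median(per_seed))


def compute_vsr_table(
    table: ExperimentTable,
    seeds=(0,),
    spread_grid: np.ndarray | None = None,
    exclude_suspect: bool = False,
    mode: str = "retrain",
) -> pd.DataFrame:
    """The full 5 responses x 4 inputs VSE/VSR/rank grid.

    VSR per cell is the median over seeds of the per-seed ratio
    (reduced-model RMSE / full-model RMSE); ``vse`` and ``rmse_full``
    columns report the median RMSEs themselves.  Rank 1 within a response
    is the largest VSR; ties break in input order (melatonin, day,
    species, FC).  ``mode='substitute'`` replaces the excluded column by
    its training mean instead of retraining (diagnostic alternative).
    """
    if mode not in ("retrain", "substitute"):
        raise ValueError("mode must be 'retrain' or 'substitute'")
    if exclude_suspect:
        table = table.without_suspect()
    X, Y, meta = encode_features(table)
    rows = []
    for response in RESPONSE_COLUMNS:
        col = meta["response_columns"].index(response)
        full = _grnn_test_rmse_per_seed(X, Y, col, seeds, None, spread_grid)
        cells = []
        for inp in FACTOR_COLUMNS:
            if mode == "retrain":
                reduced = _grnn_test_rmse_per_seed(
                    X, Y, col, seeds, _mask_for(inp), spread_grid
                )
            else:
                reduced = _substitute_test_rmse_per_seed(
                    X, Y, col, seeds, FACTOR_COLUMNS.index(inp), spread_grid
                )
            cells.append(
                dict(
                    response=response,
                    input=inp,
                    vse=float(np.median(reduced)),
                    rmse_full=float(np.median(full)),
                    vsr=float(np.median(reduced / full)),
                )
            )
        # rank 1 = highest VSR; stable sort keeps input order on ties
        order = np.argsort([-c["vsr"] for c in cells], kind="stable")
        for rank, idx in enumerate(order, start=1):
            cells[idx]["rank"] = rank
        rows.extend(cells)
    return pd.DataFrame(rows)
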