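"""Loading, encoding, normalization and splitting of the citrus morphology dataset.

The experiment measured five morphological responses (number of leaves per
plant, leaf length, internode length, crown diameter, plant height) of two
lime species under a full factorial of melatonin dose (0/50/100/150 uM),
drought severity (40/75/100 % of field capacity) and observation day
(15/30/45/60), giving 4 x 3 x 4 x 2 = 96 experimental rows.  The packaged
fixture transcribes the published measurements verbatim; two cells that are
inconsistent with their factorial neighbours are flagged ``suspect`` but
never altered.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

FACTOR_COLUMNS = ("melatonin_uM", "day", "species", "fc_percent")
RESPONSE_COLUMNS = (
    "n_leaves",
    "leaf_length_cm",
    "internode_cm",
    "crown_cm",
    "height_cm",
)
CSV_COLUMNS = (
    "melatonin_uM",
    "fc_percent",
    "day",
    "species",
    "n_leaves",
    "leaf_length_cm",
    "internode_cm",
    "crown_cm",
    "height_cm",
)

SPECIES_CODES = {"persian": -1.0, "mexican": +1.0}

#: Cells whose printed values are wildly inconsistent with their factorial
#: neighbours (a leaf count of 105.5 amid ~1060; a crown of 2.13 amid ~3.44).
#: Keyed by (melatonin_uM, fc_percent, day, species) -> column name.
SUSPECT_CELLS = {
    (100, 100, 30, "mexican"): "n_leaves",
    (0, 100, 60, "persian"): "crown_cm",
}

_FIXTURE_NAME = "citrus_morphology.csv"


@dataclass
class ExperimentTable:
    """The factorial morphology dataset as a DataFrame plus provenance flags.

    ``data`` holds one row per (melatonin, FC, day, species) combination with
    the five measured responses; ``suspect`` is a boolean Series marking rows
    containing a suspected transcription anomaly in the source table.
    """

    data: pd.DataFrame
    suspect: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.suspect is None:
            self.suspect = pd.Series(False, index=self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def query_row(self, species: str, melatonin_uM: float, fc_percent: float, day: float) -> pd.Series:
        """Return the single observation for one factor combination."""
        d = self.data
        mask = (
            (d["species"] == species)
            & (d["melatonin_uM"] == melatonin_uM)
            & (d["fc_percent"] == fc_percent)
            & (d["day"] == day)
        )
        hits = d[mask]
        if len(hits) != 1:
            raise KeyError(
                f"expected exactly one row for ({species}, {melatonin_uM} uM, "
                f"{fc_percent}% FC, day {day}); found {len(hits)}"
            )
        return hits.iloc[0]

    def without_suspect(self) -> "ExperimentTable":
        """Copy with rows carrying a suspect cell dropped."""
        keep = ~self.suspect
        return ExperimentTable(
            self.data[keep].reset_index(drop=True),
            self.suspect[keep].reset_index(drop=True),
        )

    def checksum(self) -> str:
        """SHA-256 of the canonical CSV rendering (provenance/integrity check)."""
        text = self.data.to_csv(index=False, lineterminator="\n")
        return hashlib.sha256(text.encode()).hexdigest()


def _flag_suspect(df: pd.DataFrame) -> pd.Series:
    flags = pd.Series(False, index=df.index)
    for (mel, fc, day, sp), _col in SUSPECT_CELLS.items():
        mask = (
            (df["melatonin_uM"] == mel)
            & (df["fc_percent"] == fc)
            & (df["day"] == day)
            & (df["species"] == sp)
        )
        flags |= mask
    return flags


def load_table(path: str | Path) -> ExperimentTable:
    """Load an experiment table from a CSV file in the packaged dialect.

    The CSV must be UTF-8 with '.' decimals and the header
    ``melatonin_uM,fc_percent,day,species,...`` (see :data:`CSV_COLUMNS`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"experiment table not found: {path}")
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"experiment table {path} lacks columns: {sorted(missing)}")
    df = df[list(CSV_COLUMNS)]
    unknown = set(df["species"].unique()) - set(SPECIES_CODES)
    if unknown:
        raise ValueError(f"unknown species labels in {path}: {sorted(unknown)}")
    return ExperimentTable(df, _flag_suspect(df))


def load_citrus_table() -> ExperimentTable:
    """Load the packaged 96-row citrus morphology dataset.

    Returns the table exactly as published, including the two anomalous cells
    (flagged via :attr:`ExperimentTable.suspect`, never edited).
    """
    ref = resources.files("citrusann.data").joinpath(_FIXTURE_NAME)
    with resources.as_file(ref) as path:
        if not path.exists():
            raise FileNotFoundError(f"packaged fixture missing: {path}")
        table = load_table(path)
    if len(table) != 96:
        raise ValueError(
            f"packaged fixture corrupt: expected 96 rows, found {len(table)}"
        )
    return table


def encode_features(table: ExperimentTable) -> tuple[np.ndarray, np.ndarray, dict]:
    """Encode the factor columns to a numeric N x 4 design matrix.

    Species is coded -1 (Persian lime) / +1 (Mexican lime); the three numeric
    factors pass through.  Column order is (melatonin_uM, day, species,
    fc_percent) and is recorded in the returned metadata together with the
    response column order.
    """
    if len(table) == 0:
        raise ValueError("cannot encode an empty table")
    d = table.data
    species_code = d["species"].map(SPECIES_CODES)
    if species_code.isna().any():
        bad = sorted(set(d["species"][species_code.isna()]))
        raise ValueError(f"unknown species labels: {bad}")
    X = np.column_stack(
        [
            d["melatonin_uM"].to_numpy(float),
            d["day"].to_numpy(float),
            species_code.to_numpy(float),
            d["fc_percent"].to_numpy(float),
        ]
    )
    Y = d[list(RESPONSE_COLUMNS)].to_numpy(float)
    meta = {
        "feature_columns": list(FACTOR_COLUMNS),
        "response_columns": list(RESPONSE_COLUMNS),
        "species_codes": dict(SPECIES_CODES),
    }
    return X, Y, meta


def decode_species(codes: np.ndarray) -> list[str]:
    """Invert the +-1 species coding back to labels (sign-based)."""
    inv = {v: k for k, v in SPECIES_CODES.items()}
    return [inv[1.0 if c > 0 else -1.0] for c in np.asarray(codes, float)]


class Normalizer:
    """Per-column min-max map onto [-1, +1] with exact inversion.

    Values outside the fitted range extrapolate linearly (no clipping), so
    the map is a plain affine transform per column.
    """

    def __init__(self, mins: np.ndarray, maxs: np.ndarray):
        mins = np.asarray(mins, float)
        maxs = np.asarray(maxs, float)
        if np.any(maxs <= mins):
            bad = np.nonzero(maxs <= mins)[0].tolist()
            raise ValueError(
                f"cannot normalize constant column(s) {bad}: max must exceed min"
            )
        self.mins = mins
        self.maxs = maxs

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Normalizer":
        matrix = np.atleast_2d(np.asarray(matrix, float))
        return cls(matrix.min(axis=0), matrix.max(axis=0))

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        x = np.asarray(matrix, float)
        return 2.0 * (x - self.mins) / (self.maxs - self.mins) - 1.0

    def invert(self, matrix: np.ndarray) -> np.ndarray:
        z = np.asarray(matrix, float)
        return (z + 1.0) / 2.0 * (self.maxs - self.mins) + self.mins

    def apply_column(self, values: np.ndarray, col: int) -> np.ndarray:
        x = np.asarray(values, float)
        return 2.0 * (x - self.mins[col]) / (self.maxs[col] - self.mins[col]) - 1.0

    def invert_column(self, values: np.ndarray, col: int) -> np.ndarray:
        z = np.asarray(values, float)
        return (z + 1.0) / 2.0 * (self.maxs[col] - self.mins[col]) + self.mins[col]


@dataclass(frozen=True)
class SplitSpec:
    """A seeded 70/30-style random partition of row indices."""

    train_fraction: float = 0.70
    seed: int = 0


def split_train_test(n_rows: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test partition; train size = round-half-up(fraction * N).

    Deterministic for a fixed seed; returns sorted index arrays that are
    disjoint and jointly cover ``range(n_rows)``.
    """
    n_train = int(np.floor(spec.train_fraction * n_rows + 0.5))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_rows)
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return train, test
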