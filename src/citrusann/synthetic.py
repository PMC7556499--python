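"""Phenomenological dose-response surface generator with known ground truth.

Emulates the statistical structure of the citrus morphology experiment —
a unimodal melatonin dose response (growth promoted up to a mid-range peak,
inhibited at the highest dose), monotone degradation with drought severity,
a multiplicative species effect, a weak time trend, and additive Gaussian
noise — without any mechanistic plant physiology.  Because the noiseless
surface and its analytic maximizer are known, every downstream stage
(model fitting, optimization, sensitivity) can be tested for recovery of
a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CSV_COLUMNS, RESPONSE_COLUMNS, ExperimentTable

#: Default factor grid: the experiment's own 4 x 3 x 4 x 2 = 96-row design.
DEFAULT_GRID = {
    "melatonin_uM": (0.0, 50.0, 100.0, 150.0),
    "fc_percent": (40.0, 75.0, 100.0),
    "day": (15.0, 30.0, 45.0, 60.0),
    "species": ("persian", "mexican"),
}

#: Baseline response levels (well-watered Persian control at day 15),
#: sized so the synthetic responses span ranges comparable to the real
#: measurements (leaf counts in the hundreds, lengths of a few cm).
DEFAULT_BASES = {
    "n_leaves": 300.0,
    "leaf_length_cm": 5.0,
    "internode_cm": 2.5,
    "crown_cm": 1.8,
    "height_cm": 120.0,
}

DEFAULT_NOISE_SD = {
    "n_leaves": 15.0,
    "leaf_length_cm": 0.25,
    "internode_cm": 0.12,
    "crown_cm": 0.09,
    "height_cm": 6.0,
}


@dataclass
class SurfaceConfig:
    """Parameters of the noiseless surface plus the noise level.

    dose response: quadratic in dose, peaking at ``peak_melatonin`` with
    amplitude ``inhibition_strength`` (the factor rises from 1 at 0 uM to
    1 + inhibition_strength at the peak, then falls — by construction the
    highest dose sits below the peak response).
    drought: factor 1 - drought_slope * (100 - fc), decreasing as FC falls.
    species: Mexican lime multiplies every response by ``species_multiplier``.
    time: factor 1 + time_slope * (day - 15).
    """

    peak_melatonin: float = 100.0
    inhibition_strength: float = 1.5
    drought_slope: float = 0.01
    species_multiplier: float = 1.4
    time_slope: float = 0.002
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    bases: dict = field(default_factory=lambda: dict(DEFAULT_BASES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_melatonin <= 150.0:
            raise ValueError("peak_melatonin must lie in [0, 150] uM")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd must be nonnegative")

    # -- surface pieces ----------------------------------------------------

    def dose_factor(self, melatonin_uM) -> np.ndarray:
        m = np.asarray(melatonin_uM, float)
        if self.peak_melatonin == 0:  # degenerate: monotone inhibition
            rel = m / 150.0
        else:
            rel = (m - self.peak_melatonin) / self.peak_melatonin
        return 1.0 + self.inhibition_strength * (1.0 - rel**2)

    def drought_factor(self, fc_percent) -> np.ndarray:
        fc = np.asarray(fc_percent, float)
        return np.maximum(1.0 - self.drought_slope * (100.0 - fc), 0.0)

    def species_factor(self, species) -> np.ndarray:
        s = np.asarray(species)
        return np.where(s == "mexican", self.species_multiplier, 1.0)

    def time_factor(self, day) -> np.ndarray:
        d = np.asarray(day, float)
        return 1.0 + self.time_slope * (d - 15.0)

    def mean_response(self, response: str, melatonin_uM, fc_percent, day, species) -> np.ndarray:
        """The noiseless surface for one response, in original units."""
        return (
            self.bases[response]
            * self.species_factor(species)
            * self.drought_factor(fc_percent)
            * self.dose_factor(melatonin_uM)
            * self.time_factor(day)
        )


def generate_table(config: SurfaceConfig, grid: dict | None = None) -> ExperimentTable:
    """Evaluate the surface on a factor grid and add seeded Gaussian noise.

    Responses are truncated at zero; the returned table uses the same layout
    as the packaged experimental dataset.
    """
    grid = grid or DEFAULT_GRID
    rows = []
    for mel in grid["melatonin_uM"]:
        for fc in grid["fc_percent"]:
            for day in grid["day"]:
                for sp in grid["species"]:
                    rows.append((mel, fc, day, sp))
    df = pd.DataFrame(rows, columns=["melatonin_uM", "fc_percent", "day", "species"])
    rng = np.random.default_rng(config.seed)
    for resp in RESPONSE_COLUMNS:
        mean = config.mean_response(
            resp, df["melatonin_uM"], df["fc_percent"], df["day"], df["species"]
        )
        noise = rng.normal(0.0, config.noise_sd.get(resp, 0.0), len(df))
        df[resp] = np.maximum(np.asarray(mean) + noise, 0.0)
    return ExperimentTable(df[list(CSV_COLUMNS)])


def true_optimum(config: SurfaceConfig, grid: dict | None = None) -> tuple[dict, dict]:
    """Analytic maximizer of the noiseless surface over the continuous box.

    Every response shares the same multiplicative factors, so one design
    maximizes all five jointly: the better species, full field capacity,
    the time-trend-preferred day extreme, and the dose peak.
    """
    grid = grid or DEFAULT_GRID
    days = [float(d) for d in grid["day"]]
    design = {
        "melatonin_uM": float(config.peak_melatonin),
        "fc_percent": float(max(grid["fc_percent"])),
        "day": max(days) if config.time_slope >= 0 else min(days),
        "species": "mexican" if config.species_multiplier > 1 else "persian",
    }
    responses = {
        resp: float(
            config.mean_response(
                resp,
                design["melatonin_uM"],
                design["fc_percent"],
                design["day"],
                design["species"],
            )
        )
        for resp in RESPONSE_COLUMNS
    }
    return design, responses
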