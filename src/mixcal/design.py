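"""Five-level, four-factor calibration/validation concentration design.

The 25-mixture design used throughout the package assigns each of the four
components (BUP, DEX, CBA, DMA) five equally spaced concentration levels
inside its linear range (5-25, 8-16, 2-10 and 2-10 ug/mL respectively),
with every factor visiting every level exactly five times, the first run at
the all-centre point, and eight designated validation mixtures.  The
canonical 25-row table ships as an embedded fixture; a generic cyclic
generator builds designs of the same family for new level grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DesignTable",
    "load_design_fixture",
    "build_multilevel_design",
    "split_calibration_validation",
    "COMPONENT_RANGES",
    "COMPONENT_LEVELS",
]

COMPONENTS = ("BUP", "DEX", "CBA", "DMA")
COMPONENT_RANGES = {"BUP": (5.0, 25.0), "DEX": (8.0, 16.0), "CBA": (2.0, 10.0), "DMA": (2.0, 10.0)}
COMPONENT_LEVELS = {
    "BUP": (5.0, 10.0, 15.0, 20.0, 25.0),
    "DEX": (8.0, 10.0, 12.0, 14.0, 16.0),
    "CBA": (2.0, 4.0, 6.0, 8.0, 10.0),
    "DMA": (2.0, 4.0, 6.0, 8.0, 10.0),
}

# Canonical 25-mixture design: (mixture_id, role, BUP, DEX, CBA, DMA), ug/mL.
_FIXTURE_ROWS = [
    (1, "validation", 15.00, 12.00, 6.00, 6.00),
    (2, "calibration", 15.00, 8.00, 4.00, 2.00),
    (3, "validation", 5.00, 10.00, 2.00, 10.00),
    (4, "calibration", 10.00, 8.00, 10.00, 10.00),
    (5, "calibration", 5.00, 16.00, 10.00, 6.00),
    (6, "validation", 25.00, 16.00, 6.00, 4.00),
    (7, "validation", 25.00, 12.00, 4.00, 10.00),
    (8, "calibration", 15.00, 10.00, 10.00, 4.00),
    (9, "calibration", 10.00, 16.00, 4.00, 8.00),
    (10, "validation", 25.00, 10.00, 8.00, 8.00),
    (11, "calibration", 10.00, 14.00, 8.00, 6.00),
    (12, "calibration", 20.00, 14.00, 6.00, 10.00),
    (13, "validation", 20.00, 12.00, 10.00, 8.00),
    (14, "calibration", 15.00, 16.00, 8.00, 10.00),
    (15, "calibration", 25.00, 14.00, 10.00, 2.00),
    (16, "calibration", 20.00, 16.00, 2.00, 2.00),
    (17, "calibration", 25.00, 8.00, 2.00, 6.00),
    (18, "calibration", 5.00, 8.00, 6.00, 8.00),
    (19, "calibration", 5.00, 12.00, 8.00, 2.00),
    (20, "calibration", 15.00, 14.00, 2.00, 8.00),
    (21, "validation", 20.00, 8.00, 8.00, 4.00),
    (22, "calibration", 5.00, 14.00, 4.00, 4.00),
    (23, "validation", 20.00, 10.00, 4.00, 6.00),
    (24, "calibration", 10.00, 10.00, 6.00, 2.00),
    (25, "calibration", 10.00, 12.00, 2.00, 4.00),
]


@dataclass
class DesignTable:
    """Ordered mixture design with calibration/validation role flags."""

    mixture_ids: list[int]
    roles: list[str]
    concentrations: np.ndarray = field(repr=False)  # n x 4, ug/mL
    component_names: tuple[str, ...] = COMPONENTS
    check_levels: bool = True

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        n = len(self.mixture_ids)
        if len(self.roles) != n or self.concentrations.shape[0] != n:
            raise ValueError("mixture_ids, roles and concentrations must align")
        if self.concentrations.shape[1] != len(self.component_names):
            raise ValueError("concentration columns must match component names")
        if len(set(self.mixture_ids)) != n:
            raise ValueError("mixture ids must be unique")
        bad = set(self.roles) - {"calibration", "validation"}
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        if self.check_levels:
            for j, name in enumerate(self.component_names):
                levels = COMPONENT_LEVELS.get(name)
                if levels is None:
                    continue
                col = self.concentrations[:, j]
                on_grid = np.isclose(col[:, None], np.asarray(levels)[None, :]).any(axis=1)
                if not on_grid.all():
                    off = col[~on_grid]
                    raise ValueError(f"{name} concentrations {off} not on the 5-level grid {levels}")

    def __len__(self) -> int:
        return len(self.mixture_ids)

    @property
    def role_array(self) -> np.ndarray:
        return np.asarray(self.roles)

    def subset(self, mask: np.ndarray) -> "DesignTable":
        idx = np.flatnonzero(mask)
        return DesignTable(
            [self.mixture_ids[i] for i in idx],
            [self.roles[i] for i in idx],
            self.concentrations[idx],
            self.component_names,
            self.check_levels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations, columns=list(self.component_names))
        df.insert(0, "role", self.roles)
        df.insert(0, "mixture_id", self.mixture_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, check_levels: bool = True) -> "DesignTable":
        comps = [c for c in df.columns if c not in ("mixture_id", "role")]
        return cls(
            [int(m) for m in df["mixture_id"]],
            [str(r) for r in df["role"]],
            df[comps].to_numpy(dtype=float),
            tuple(comps),
            check_levels,
        )


def load_design_fixture() -> DesignTable:
    """The canonical 25-mixture table: 17 calibration + 8 validation rows."""
    rows = _FIXTURE_ROWS
    return DesignTable(
        [r[0] for r in rows],
        [r[1] for r in rows],
        np.array([r[2:] for r in rows], dtype=float),
    )


def _coded_base_sequence() -> np.ndarray:
    """Coded (-2..+2) levels of the first factor in runs 2..25 of the fixture."""
    fix = _FIXTURE_ROWS
    levels = np.asarray(COMPONENT_LEVELS["BUP"])
    vals = np.array([r[2] for r in fix[1:]])
    return np.array([int(np.flatnonzero(np.isclose(levels, v))[0]) - 2 for v in vals])


def build_multilevel_design(
    levels: int = 5,
    factors: int = 4,
    level_values: dict[str, tuple[float, ...]] | None = None,
    seed_sequence: np.ndarray | list[int] | None = None,
) -> DesignTable:
    """Cyclic multilevel calibration design (levels**2 runs).

    Run 1 is the all-centre point; runs 2..n of factor ``f`` are the coded
    seed sequence cyclically left-shifted ``f`` positions, which makes every
    factor visit each of its levels exactly ``levels`` times and every coded
    column sum to zero.

    Only the five-level construction is supported with the default seed
    sequence (the shipped sequence is 24 coded values balancing 5 levels).
    """
    if level_values is None:
        level_values = COMPONENT_LEVELS
    if factors != len(level_values):
        raise ValueError("factors must match the number of level-value entries")
    names = tuple(level_values)
    for name, vals in level_values.items():
        if len(vals) != levels:
            raise ValueError(f"{name}: expected {levels} level values, got {len(vals)}")
        if np.any(np.diff(vals) <= 0):
            raise ValueError(f"{name}: level values must be strictly increasing")
    if seed_sequence is None:
        if levels != 5:
            raise ValueError("default seed sequence supports only 5 levels")
        base = _coded_base_sequence()
    else:
        base = np.asarray(seed_sequence, dtype=int)
        if base.size != levels * levels - 1:
            raise ValueError(f"seed sequence must have {levels*levels - 1} entries")
    n_runs = levels * levels
    center = (levels - 1) // 2
    coded = np.empty((n_runs, factors), dtype=int)
    coded[0] = 0
    for f in range(factors):
        coded[1:, f] = np.roll(base, -f)
    conc = np.empty((n_runs, factors), dtype=float)
    for f, name in enumerate(names):
        vals = np.asarray(level_values[name], dtype=float)
        conc[:, f] = vals[coded[:, f] + center]
    check = level_values is COMPONENT_LEVELS
    return DesignTable(
        list(range(1, n_runs + 1)), ["calibration"] * n_runs, conc, names, check_levels=check
    )


def split_calibration_validation(design: DesignTable) -> tuple[DesignTable, DesignTable]:
    """Order-preserving partition into (calibration, validation) tables."""
    roles = design.role_array
    return design.subset(roles == "calibration"), design.subset(roles == "validation")
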