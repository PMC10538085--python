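"""Synthetic cell cohorts, gap-array routing, and device-design outputs.

The measured A549 size distribution (mean 17.27 um, SD 2.91 um, observed
range roughly 12-28 um) is the default cohort model.  Cohorts are routed
through a graded gap array (gaps strictly decreasing from inlet to outlet);
each cell is captured at the first array whose rule fires:

* ``size-fraction``: gap <= threshold_fraction x diameter (the classical
  25%-of-cell-size design heuristic), or
* ``critical-pressure``: the power-law critical pressure at that gap
  exceeds the chosen operating pressure.

Cells never captured are counted as escaped, not forced into the last
array.  The module also recommends gaps (fraction x diameter) and evaluates
operating-pressure curves for a packaged panel of tumor cell lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .empirical import predict_critical_pressure
from .errors import (
    DegenerateGeneratorError,
    InvalidBinsError,
    InvalidInputError,
)
from .types import PowerLawModel, TrapGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "Cohort",
    "ArraySequence",
    "CaptureRule",
    "TrappingReport",
    "CellTypeEntry",
    "A549_DIAMETER_MEAN",
    "A549_DIAMETER_SD",
    "A549_BINS",
    "DEVICE_ARRAYS",
    "generate_cohort",
    "generate_cohort_binned",
    "route",
    "recommend_gap",
    "operating_pressure_curves",
    "load_cell_panel",
    "load_bin_gap_association",
]

#: Measured A549 diameter distribution parameters (um).
A549_DIAMETER_MEAN = 17.27
A549_DIAMETER_SD = 2.91
A549_DIAMETER_RANGE = (12.0, 28.0)

#: Measured A549 population shares per diameter bin (um ranges, as printed;
#: the shares total 101% and are renormalized with a warning when sampled).
A549_BINS = (
    ((12.0, 18.0), 0.60),
    ((18.0, 20.0), 0.23),
    ((20.0, 23.0), 0.13),
    ((23.0, 28.0), 0.05),
)

#: Default modulus assigned to generated cohorts (Pa, A549 mid-range).
DEFAULT_MODULUS = 430.0


@dataclass(frozen=True)
class Cohort:
    """Sampled population: per-cell diameters (um) and moduli (Pa)."""

    diameters: np.ndarray
    moduli: np.ndarray
    seed: int
    provenance: str

    def __post_init__(self):
        d = np.asarray(self.diameters, dtype=float)
        m = np.asarray(self.moduli, dtype=float)
        if d.size == 0 or d.size != m.size:
            raise InvalidInputError("diameters and moduli must be equal, non-empty")
        if np.any(d <= 0) or np.any(m <= 0):
            raise InvalidInputError("diameters and moduli must be positive")
        object.__setattr__(self, "diameters", d)
        object.__setattr__(self, "moduli", m)

    def __len__(self):
        return len(self.diameters)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"diameter_um": self.diameters, "modulus_pa": self.moduli}
        )


@dataclass(frozen=True)
class ArraySequence:
    """Gap sizes (um) from inlet to outlet; must be strictly decreasing."""

    gaps: tuple[float, ...]

    def __post_init__(self):
        g = tuple(float(x) for x in self.gaps)
        if not g or any(x <= 0 for x in g):
            raise InvalidInputError("gaps must be positive and non-empty")
        if any(b >= a for a, b in zip(g, g[1:])):
            raise InvalidInputError("gaps must be strictly decreasing")
        object.__setattr__(self, "gaps", g)


#: The fabricated device's array progression (the inlet filter array spans
#: gaps above 14 um; its nominal value here is 14).
DEVICE_ARRAYS = ArraySequence(gaps=(14.0, 10.0, 8.0, 4.0))


@dataclass(frozen=True)
class CaptureRule:
    """How a cell is captured at an array.

    kind "size-fraction": capture iff gap <= threshold_fraction * diameter.
    kind "critical-pressure": capture iff the model's Pc at the gap exceeds
    the operating pressure (the cell cannot be pushed through).
    """

    kind: str = "size-fraction"
    threshold_fraction: float = 0.25
    operating_pressure: float = 0.0
    model: PowerLawModel = field(default_factory=PowerLawModel)

    def __post_init__(self):
        if self.kind not in ("size-fraction", "critical-pressure"):
            raise InvalidInputError(f"unknown capture rule kind {self.kind!r}")
        if not 0 < self.threshold_fraction < 1:
            raise InvalidInputError("threshold_fraction must be in (0, 1)")
        if self.operating_pressure < 0:
            raise InvalidInputError("operating_pressure must be >= 0")


@dataclass(frozen=True)
class TrappingReport:
    """Routing outcome: per-array captured counts/fractions (fractions are
    of the whole cohort and, together with the escaped fraction, sum to 1)
    and the per-cell assignment (array index, or -1 for escaped)."""

    gaps: tuple[float, ...]
    captured_counts: tuple[int, ...]
    escaped_count: int
    assignment: np.ndarray

    @property
    def cohort_size(self) -> int:
        return int(sum(self.captured_counts) + self.escaped_count)

    @property
    def captured_fractions(self) -> tuple[float, ...]:
        n = self.cohort_size
        return tuple(c / n for c in self.captured_counts)

    @property
    def escaped_fraction(self) -> float:
        return self.escaped_count / self.cohort_size

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"gap_um": g, "captured": c, "fraction": f}
            for g, c, f in zip(self.gaps, self.captured_counts, self.captured_fractions)
        ]
        rows.append(
            {"gap_um": np.nan, "captured": self.escaped_count,
             "fraction": self.escaped_fraction}
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CellTypeEntry:
    name: str
    diameter: float  # um
    stiffness: float  # Pa

    def __post_init__(self):
        if self.diameter <= 0 or self.stiffness <= 0:
            raise InvalidInputError("diameter and stiffness must be positive")


def generate_cohort(
    n: int,
    mean: float = A549_DIAMETER_MEAN,
    sd: float = A549_DIAMETER_SD,
    seed: int = 0,
    truncation: tuple[float, float] | None = None,
    modulus: float = DEFAULT_MODULUS,
) -> Cohort:
    """Sample ``n`` cell diameters from a normal model.

    Untruncated by default: truncating to the observed range would shift
    the sample mean away from the measured value (by about +0.23 um for the
    A549 parameters), so truncation is opt-in.  With ``truncation`` the
    distribution is renormalized over the range (scipy truncnorm).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if sd <= 0:
        raise InvalidInputError("sd must be > 0")
    rng = np.random.default_rng(seed)
    if truncation is None:
        d = rng.normal(mean, sd, size=n)
        prov = f"normal(mean={mean}, sd={sd})"
    else:
        lo, hi = truncation
        if lo >= hi:
            raise InvalidInputError("truncation range must have lo < hi")
        if hi < mean - 5 * sd or lo > mean + 5 * sd:
            raise DegenerateGeneratorError(
                "truncation range excludes essentially all probability mass"
            )
        a, b = (lo - mean) / sd, (hi - mean) / sd
        d = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        prov = f"truncnorm(mean={mean}, sd={sd}, range=({lo}, {hi}))"
    d = np.clip(d, 1e-6, None)  # a >5-sigma negative draw would be invalid
    return Cohort(diameters=d, moduli=np.full(n, float(modulus)), seed=seed,
                  provenance=prov)


def generate_cohort_binned(
    n: int,
    bins: Sequence[tuple[tuple[float, float], float]] = A549_BINS,
    seed: int = 0,
    modulus: float = DEFAULT_MODULUS,
) -> Cohort:
    """Sample diameters from a histogram model: pick a bin by its
    population share, then uniformly within the bin range.

    Shares that do not sum to 1 (the printed shares total 101%) are
    renormalized with a logged warning.  Overlapping bins are rejected.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    ranges = [tuple(map(float, r)) for r, _ in bins]
    props = np.array([p for _, p in bins], dtype=float)
    if np.any(props < 0):
        raise InvalidBinsError("bin proportions must be >= 0")
    for (lo, hi) in ranges:
        if lo >= hi:
            raise InvalidBinsError(f"bin range ({lo}, {hi}) is empty")
    for (lo1, hi1), (lo2, hi2) in zip(sorted(ranges), sorted(ranges)[1:]):
        if lo2 < hi1:
            raise InvalidBinsError("bins overlap")
    total = props.sum()
    if abs(total - 1.0) > 1e-6:
        logger.warning("bin proportions sum to %.4f; renormalizing", total)
    props = props / total
    rng = np.random.default_rng(seed)
    which = rng.choice(len(ranges), size=n, p=props)
    lows = np.array([r[0] for r in ranges])
    highs = np.array([r[1] for r in ranges])
    d = rng.uniform(lows[which], highs[which])
    return Cohort(
        diameters=d,
        moduli=np.full(n, float(modulus)),
        seed=seed,
        provenance=f"binned({len(bins)} bins, renormalized from {total:.4f})",
    )


def route(cohort: Cohort, arrays: ArraySequence, rule: CaptureRule) -> TrappingReport:
    """Send every cell through the arrays in order; capture at the first
    array where the rule fires, else count it as escaped.

    Boundary ties (gap exactly equal to the size-fraction threshold) count
    as captures.
    """
    d = cohort.diameters
    m = cohort.moduli
    assignment = np.full(len(d), -1, dtype=int)
    remaining = np.ones(len(d), dtype=bool)
    for k, gap in enumerate(arrays.gaps):
        if rule.kind == "size-fraction":
            fires = gap <= rule.threshold_fraction * d
        else:
            geom = TrapGeometry(gap=gap)
            ratio = d / gap
            pc = rule.model.coefficient * m * ratio**rule.model.exponent
            fires = pc > rule.operating_pressure
        captured_here = remaining & fires
        assignment[captured_here] = k
        remaining &= ~captured_here
    counts = tuple(int(np.sum(assignment == k)) for k in range(len(arrays.gaps)))
    return TrappingReport(
        gaps=arrays.gaps,
        captured_counts=counts,
        escaped_count=int(np.sum(assignment == -1)),
        assignment=assignment,
    )


def recommend_gap(diameter: float, fraction: float = 0.25) -> float:
    """Gap recommended by the fraction-of-cell-size criterion (default 25%)."""
    if diameter <= 0:
        raise InvalidInputError(f"diameter must be > 0, got {diameter}")
    if fraction < 0 or fraction >= 1:
        raise InvalidInputError(f"fraction must be in [0, 1), got {fraction}")
    if fraction == 0:
        logger.warning("fraction = 0 recommends a zero gap (no passage at all)")
    return fraction * diameter


def operating_pressure_curves(
    panel: Sequence[CellTypeEntry],
    gaps: Sequence[float],
    model: PowerLawModel | None = None,
) -> pd.DataFrame:
    """Critical pressure (Pa) vs gap (um) for each cell type.

    Rows are indexed by gap; one column per cell type; every curve is
    strictly decreasing in gap.  Operating below a type's curve keeps that
    type trapped; operating above it loses the cells.
    """
    if not panel:
        raise InvalidInputError("panel must be non-empty")
    model = model or PowerLawModel()
    gaps = np.asarray(list(gaps), dtype=float)
    if np.any(gaps <= 0):
        raise InvalidInputError("gaps must be positive")
    data = {}
    for entry in panel:
        data[entry.name] = (
            model.coefficient * entry.stiffness * (entry.diameter / gaps) ** model.exponent
        )
    return pd.DataFrame(data, index=pd.Index(gaps, name="gap_um"))


def _read_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("pillartrap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_cell_panel() -> list[CellTypeEntry]:
    """The packaged tumor-cell panel (name, diameter um, stiffness Pa)."""
    df = _read_packaged_csv("cell_panel.csv")
    return [
        CellTypeEntry(name=r.name, diameter=r.diameter_um, stiffness=r.stiffness_pa)
        for r in df.itertuples(index=False)
    ]


def load_bin_gap_association() -> pd.DataFrame:
    """Measured A549 diameter-bin to capture-gap association (fixture)."""
    return _read_packaged_csv("a549_bin_gap_association.csv")
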