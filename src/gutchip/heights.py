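"""Synthetic confocal monolayer-height datasets and morphology calls.

Monolayer height is the morphometric readout linking culture condition to
cell shape: static day-8 monolayers stay low (≈ 13 µm, bulge-like cells),
day-5 perfused monolayers are intermediate and variable (≈ 27 µm), and
day-8 perfused monolayers — constant or decreased flow alike — reach
≈ 34 µm (tall columnar cells).  Real measurements come from Z-stack
projections of confocal images, many height readings per projection, so the
generator uses a two-level hierarchy: projection means scatter around the
condition mean (between-projection spread: field-to-field and chip-to-chip
variability), and individual measurements scatter around their projection
mean (within-projection spread: surface undulation and reading error).
Both levels are normal, truncated below at 1 µm for physical positivity.

Only the condition means are measured quantities; the spreads are declared
assumptions (defaults 4 µm between / 3 µm within, doubled for the mid-run
day-5 condition, whose monolayers are reported as markedly more variable).
Classification back to a morphology label uses midpoint thresholds between
the reference heights 13/27/34 µm, ties resolved toward the shorter class.

Everything is seeded explicitly; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.stats import truncnorm

MIN_HEIGHT_UM = 1.0

#: Reference heights (µm) defining the morphology classes.
REFERENCE_HEIGHTS = {"small": 13.0, "medium": 27.0, "tall": 34.0}

#: Midpoint decision thresholds; means at or below a threshold take the
#: shorter class.
_THRESHOLDS = ((20.0, "small"), (30.5, "medium"))


@dataclass(frozen=True)
class ConditionParameters:
    """Two-level model parameters for one culture condition."""

    mean_um: float
    between_projection_sd_um: float
    within_projection_sd_um: float

    def __post_init__(self) -> None:
        if self.mean_um <= 0.0:
            raise ValueError(f"mean height must be > 0, got {self.mean_um}")
        if self.between_projection_sd_um < 0.0 or self.within_projection_sd_um < 0.0:
            raise ValueError("spreads must be >= 0")


#: Default parameters per condition: C = constant flow, D = decreased flow,
#: S = static, with the sampling day appended.
CONDITION_DEFAULTS: dict[str, ConditionParameters] = {
    "S8": ConditionParameters(13.0, 4.0, 3.0),
    "C5": ConditionParameters(27.0, 8.0, 6.0),
    "C8": ConditionParameters(34.0, 4.0, 3.0),
    "D8": ConditionParameters(34.0, 4.0, 3.0),
}

DEFAULT_N_MEASUREMENTS = 820
DEFAULT_N_PROJECTIONS = 103


@dataclass(frozen=True)
class HeightDataset:
    """Synthetic monolayer-height measurements grouped into projections."""

    condition: str
    heights_um: np.ndarray
    projection_ids: np.ndarray
    seed: int
    parameters: ConditionParameters

    def __post_init__(self) -> None:
        if self.heights_um.size == 0:
            raise ValueError("empty dataset")
        if np.any(self.heights_um <= 0.0):
            raise ValueError("heights must be > 0")

    @property
    def n(self) -> int:
        return int(self.heights_um.size)

    @property
    def n_projections(self) -> int:
        return int(np.unique(self.projection_ids).size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"projection_id": self.projection_ids, "height_um": self.heights_um}
        )


def _truncated_normal(rng, loc, scale, size):
    """Normal(loc, scale) truncated to heights above ``MIN_HEIGHT_UM``.

    ``loc`` may be an array broadcast against ``size``."""
    loc = np.broadcast_to(np.asarray(loc, dtype=float), (size,))
    if scale == 0.0:
        return loc.copy()
    a = (MIN_HEIGHT_UM - loc) / scale
    return truncnorm.rvs(a, np.inf, loc=loc, scale=scale, size=size, random_state=rng)


def generate_heights(
    condition: str,
    n_measurements: int = DEFAULT_N_MEASUREMENTS,
    n_projections: int = DEFAULT_N_PROJECTIONS,
    seed: int = 0,
    parameters: ConditionParameters | None = None,
) -> HeightDataset:
    """Draw a seeded two-level height dataset for a condition label.

    Measurements are split as evenly as possible over projections (the
    first ``n_measurements mod n_projections`` projections receive one
    extra).  Identical seeds regenerate identical datasets.
    """
    if parameters is None:
        try:
            parameters = CONDITION_DEFAULTS[condition]
        except KeyError:
            raise ValueError(
                f"unknown condition {condition!r}; known: "
                f"{sorted(CONDITION_DEFAULTS)}"
            ) from None
    if not (n_measurements >= n_projections >= 1):
        raise ValueError("need n_measurements >= n_projections >= 1")
    # fold the condition label into the stream so equal-parameter conditions
    # (e.g. the two day-8 flow groups) are independent samples per seed
    rng = np.random.default_rng([seed, *condition.encode()])
    base, extra = divmod(n_measurements, n_projections)
    sizes = np.full(n_projections, base)
    sizes[:extra] += 1
    proj_means = _truncated_normal(
        rng, parameters.mean_um, parameters.between_projection_sd_um, n_projections
    )
    heights = _truncated_normal(
        rng,
        np.repeat(proj_means, sizes),
        parameters.within_projection_sd_um,
        n_measurements,
    )
    ids = np.repeat(np.arange(n_projections), sizes)
    return HeightDataset(
        condition=condition,
        heights_um=heights,
        projection_ids=ids,
        seed=seed,
        parameters=parameters,
    )


@dataclass(frozen=True)
class HeightSummary:
    """Mean ± SEM summary of a height dataset.

    ``sem_um`` is computed over individual measurements (the reporting
    convention for confocal height panels); ``sem_between_projections_um``
    is the alternative over projection means, also reported because the
    two-level structure makes it the more conservative choice.
    """

    mean_um: float
    sem_um: float
    n: int
    projection_means_um: tuple[float, ...] = field(repr=False)
    sem_between_projections_um: float = 0.0

    @property
    def n_projections(self) -> int:
        return len(self.projection_means_um)


def summarize_heights(dataset: HeightDataset) -> HeightSummary:
    """Mean, SEM and per-projection means; order-invariant."""
    h = dataset.heights_um
    n = h.size
    sem = float(h.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    pm = [
        float(h[dataset.projection_ids == p].mean())
        for p in np.unique(dataset.projection_ids)
    ]
    sem_b = float(np.std(pm, ddof=1) / np.sqrt(len(pm))) if len(pm) > 1 else 0.0
    return HeightSummary(
        mean_um=float(h.mean()),
        sem_um=sem,
        n=int(n),
        projection_means_um=tuple(pm),
        sem_between_projections_um=sem_b,
    )


def classify_morphology(summary: HeightSummary | float) -> str:
    """Map a mean monolayer height to {small, medium, tall}.

    Nearest reference height with midpoint thresholds (20 and 30.5 µm);
    a mean exactly on a threshold takes the shorter class.
    """
    mean = summary.mean_um if isinstance(summary, HeightSummary) else float(summary)
    if mean <= 0.0:
        raise ValueError(f"mean height must be > 0, got {mean}")
    for threshold, label in _THRESHOLDS:
        if mean <= threshold:
            return label
    return "tall"


def analytic_sem(
    parameters: ConditionParameters, n_measurements: int, n_projections: int
) -> float:
    """Closed-form SEM of the grand mean under the two-level model.

    Var(mean) = σ_b²/J + σ_w²/n for J equal projections and n total
    measurements (truncation neglected; it is a sub-percent effect at the
    default parameters).
    """
    return float(
        np.sqrt(
            parameters.between_projection_sd_um**2 / n_projections
            + parameters.within_projection_sd_um**2 / n_measurements
        )
    )
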