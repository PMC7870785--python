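"""Seeded synthetic cohorts for second-trimester serum screening.

The study population this emulates is not publicly available, so cohorts
are simulated with its reported statistical structure: per-group
multivariate Gaussian log10 MoM vectors for AFP, free beta-hCG, uE3 and
sHLA-G (group means, SDs and pairwise correlations from the published
reference tables), group sizes 797 controls / 139 T21 / 83 T18,
maternal age 18-35 years, maternal weight with median 54.5 kg, and
gestational weeks 15-19.  Raw concentrations are reconstructed by
inverting the MoM definition against a control median curve, so every
generated subject carries strictly positive (lognormal) marker levels
that round-trip exactly through MoM normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mom import FLAT_MARKERS, GESTATIONAL_WEEKS, MedianCurve
from .params import MARKERS, GroupParams, load_default_params, load_default_payload


@dataclass
class SimulationConfig:
    """Everything needed to draw one reproducible cohort."""

    group_sizes: dict[str, int]
    group_params: dict[str, GroupParams]
    control_medians: MedianCurve
    age_range: tuple[float, float] = (18.0, 35.0)
    weight_median_kg: float = 54.5
    weight_sigma_log10: float = 0.068
    gestational_weeks: tuple[int, ...] = GESTATIONAL_WEEKS
    seed: int = 0
    markers: tuple[str, ...] = field(default=MARKERS)

    def __post_init__(self) -> None:
        for group, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"group size for {group!r} must be >= 0")
            if n > 0 and group not in self.group_params:
                raise ValueError(f"no parameters for group {group!r}")
        lo, hi = self.age_range
        if not (18.0 <= lo < hi <= 35.0):
            raise ValueError("age range must lie within [18, 35]")
        if self.weight_median_kg <= 0 or self.weight_sigma_log10 <= 0:
            raise ValueError("weight parameters must be positive")


def default_config(seed: int = 0) -> SimulationConfig:
    """The packaged reference-population configuration (797/139/83)."""
    payload = load_default_payload()
    demo = payload["demographics"]
    medians = MedianCurve(
        medians={
            marker: (
                float(entry)
                if not isinstance(entry, dict)
                else {int(w): float(m) for w, m in entry.items()}
            )
            for marker, entry in payload["control_medians"].items()
        }
    )
    return SimulationConfig(
        group_sizes={g: int(n) for g, n in payload["group_sizes"].items()},
        group_params=load_default_params(),
        control_medians=medians,
        age_range=tuple(demo["age_range"]),
        weight_median_kg=float(demo["weight_median_kg"]),
        weight_sigma_log10=float(demo["weight_sigma_log10"]),
        gestational_weeks=tuple(demo["gestational_weeks"]),
        seed=seed,
    )


def sample_log_mom(
    params: GroupParams,
    n: int,
    rng: np.random.Generator | int,
    use_correlations: bool = True,
) -> np.ndarray:
    """Draw ``n`` log10 MoM vectors from the group's Gaussian model.

    Returns an ``(n, n_markers)`` array.  The covariance is built as
    ``D R D`` from the SD vector and correlation matrix (nearest-PD
    repaired if the rounded correlations make it indefinite).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cov = params.covariance(use_correlations=use_correlations)
    return rng.multivariate_normal(
        params.mean_log10_mom, cov, size=n, method="cholesky"
    )


def reconstruct_levels(
    log_mom: np.ndarray,
    curve: MedianCurve,
    week: int,
    markers: tuple[str, ...] = MARKERS,
) -> np.ndarray:
    """Invert the MoM definition: ``level = 10**log10_mom * median``.

    ``log_mom`` may be a single vector or an ``(n, n_markers)`` matrix;
    the control median used per marker is week-specific where the curve
    is week-indexed.
    """
    arr = np.atleast_2d(np.asarray(log_mom, dtype=float))
    medians = np.array(
        [
            curve.median_for(m, None if m in FLAT_MARKERS else week)
            for m in markers
        ]
    )
    levels = 10.0**arr * medians
    return levels[0] if np.asarray(log_mom).ndim == 1 else levels


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full cohort as one DataFrame, reproducible from the seed.

    Columns: ``subject_id, group, age, weight, gestational_week`` and one
    raw concentration per marker (sHLA-G in U/ml).  Groups are emitted in
    the order of ``config.group_sizes``; all randomness flows from the
    single seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    offset = 0
    log_w_sd = config.weight_sigma_log10 * np.log(10.0)
    for group, n in config.group_sizes.items():
        if n == 0:
            continue
        params = config.group_params[group]
        log_mom = sample_log_mom(params, n, rng)
        ages = rng.uniform(config.age_range[0], config.age_range[1], size=n)
        weights = config.weight_median_kg * np.exp(
            rng.normal(0.0, log_w_sd, size=n)
        )
        weeks = rng.choice(np.asarray(config.gestational_weeks), size=n)
        levels = np.vstack(
            [
                reconstruct_levels(log_mom[i], config.control_medians, int(weeks[i]))
                for i in range(n)
            ]
        )
        frame = pd.DataFrame(
            {
                "subject_id": [f"S{offset + i + 1:05d}" for i in range(n)],
                "group": group,
                "age": np.round(ages, 2),
                "weight": np.round(weights, 1),
                "gestational_week": weeks.astype(int),
            }
        )
        for j, marker in enumerate(config.markers):
            frame[marker] = levels[:, j]
        frames.append(frame)
        offset += n
    if not frames:
        raise ValueError("all group sizes are zero")
    return pd.concat(frames, ignore_index=True)
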