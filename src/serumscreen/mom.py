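"""Multiple-of-the-median (MoM) normalization of serum markers.

A marker level is expressed relative to the median level of unaffected
(control) pregnancies: ``MoM = level / median``.  AFP, free beta-hCG and
uE3 vary strongly with gestation and are normalized against the median of
the control stratum at the same completed gestational week; sHLA-G shows
no gestational trend and uses a single flat control median.  Downstream
modelling operates on log10 MoM, which is close to Gaussian within each
group.

The module offers a scikit-learn style :class:`MedianNormalizer`
(fit on controls, transform any cohort) plus thin functional wrappers,
and an optional maternal-weight correction in the screening-literature
convention (expected MoM regressed on reciprocal weight in controls,
observed MoM divided by the expectation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .params import MARKERS

#: Markers normalized within exact integer gestational-week strata.
WEEK_INDEXED_MARKERS: tuple[str, ...] = ("afp", "free_bhcg", "ue3")
#: Markers normalized against one overall control median.
FLAT_MARKERS: tuple[str, ...] = ("shla_g",)

GESTATIONAL_WEEKS: tuple[int, ...] = (15, 16, 17, 18, 19)


def median_low(values) -> float:
    """Sample median with the lower-middle convention for even n.

    Returns an observed value for every sample size, so the subject at
    the median has MoM exactly 1 and MoM tables are bit-reproducible.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise ValueError("median of empty sample")
    return float(arr[(arr.size - 1) // 2])


@dataclass
class MedianCurve:
    """Control medians per marker: flat, or indexed by gestational week."""

    medians: dict[str, float | dict[int, float]] = field(default_factory=dict)

    def median_for(self, marker: str, week: int | None = None) -> float:
        try:
            entry = self.medians[marker]
        except KeyError:
            raise KeyError(f"no median curve for marker {marker!r}") from None
        if isinstance(entry, dict):
            if week is None or int(week) not in entry:
                raise KeyError(
                    f"median curve for {marker!r} has no entry for week {week!r}"
                )
            value = entry[int(week)]
        else:
            value = entry
        if not value > 0:
            raise ValueError(f"median for {marker!r} must be > 0, got {value}")
        return float(value)

    def to_json(self) -> str:
        payload = {
            marker: (
                {str(w): m for w, m in entry.items()}
                if isinstance(entry, dict)
                else entry
            )
            for marker, entry in self.medians.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MedianCurve":
        raw = json.loads(text)
        medians: dict[str, float | dict[int, float]] = {}
        for marker, entry in raw.items():
            if isinstance(entry, dict):
                medians[marker] = {int(w): float(m) for w, m in entry.items()}
            else:
                medians[marker] = float(entry)
        return cls(medians=medians)


def fit_median_curve(
    controls: pd.DataFrame,
    markers: tuple[str, ...] = MARKERS,
    weeks: tuple[int, ...] | None = None,
) -> MedianCurve:
    """Estimate control medians per marker (per week where appropriate).

    Parameters
    ----------
    controls : DataFrame
        Control-subject rows with a ``gestational_week`` column and one
        column per marker.
    markers : tuple of str
        Markers to fit.  Members of :data:`WEEK_INDEXED_MARKERS` get a
        week-indexed curve; all others get a flat median.
    weeks : tuple of int, optional
        Weeks the curve must cover.  Default: the weeks present among
        the controls.  An explicitly requested week with an empty
        control stratum is an error listing the missing weeks.
    """
    if len(controls) == 0:
        raise ValueError("cannot fit a median curve on an empty control set")
    medians: dict[str, float | dict[int, float]] = {}
    week_col = controls["gestational_week"].to_numpy().astype(int)
    present_weeks = sorted(set(week_col.tolist()))
    if weeks is None:
        target_weeks = present_weeks
    else:
        empty = [w for w in weeks if w not in present_weeks]
        if empty:
            raise ValueError(f"empty control stratum at weeks {empty}")
        target_weeks = [int(w) for w in weeks]
    for marker in markers:
        levels = controls[marker].to_numpy(dtype=float)
        if np.any(levels <= 0):
            raise ValueError(f"non-positive {marker} level among controls")
        if marker in WEEK_INDEXED_MARKERS:
            medians[marker] = {
                w: median_low(levels[week_col == w]) for w in target_weeks
            }
        else:
            medians[marker] = median_low(levels)
    return MedianCurve(medians=medians)


def compute_mom(
    records: pd.DataFrame,
    curve: MedianCurve,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Convert raw marker levels to MoM and log10 MoM.

    Returns a DataFrame indexed like ``records`` with columns
    ``{marker}_mom`` and ``{marker}_log10_mom``.
    """
    out = pd.DataFrame(index=records.index)
    weeks = records.get("gestational_week")
    for marker in markers:
        levels = records[marker].to_numpy(dtype=float)
        bad = ~(levels > 0) | ~np.isfinite(levels)
        if np.any(bad):
            where = records.index[bad][0]
            ident = (
                records.loc[where, "subject_id"]
                if "subject_id" in records.columns
                else where
            )
            raise ValueError(
                f"non-positive {marker} level for subject {ident!r}"
            )
        if marker in WEEK_INDEXED_MARKERS:
            if weeks is None:
                raise KeyError("records lack a gestational_week column")
            med = np.array(
                [curve.median_for(marker, int(w)) for w in weeks.to_numpy()]
            )
        else:
            med = curve.median_for(marker)
        mom = levels / med
        out[f"{marker}_mom"] = mom
        out[f"{marker}_log10_mom"] = np.log10(mom)
    return out


class IdentityWeightModel:
    """No-op maternal-weight model: expected MoM is 1 at every weight."""

    def expected_mom(self, weight, marker: str | None = None):
        return np.ones_like(np.asarray(weight, dtype=float))


class ReciprocalWeightModel:
    """Expected MoM regressed on 1/weight in controls, per marker.

    Heavier women dilute serum analytes, so the expected MoM falls with
    weight roughly as ``a + b / weight``.  Dividing observed MoM by the
    fitted expectation re-centres the control median MoM at 1 across the
    weight range.
    """

    def __init__(self) -> None:
        self.coef_: dict[str, tuple[float, float]] = {}

    def fit(
        self,
        weights,
        mom: pd.DataFrame,
        markers: tuple[str, ...] = MARKERS,
    ) -> "ReciprocalWeightModel":
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        x = np.column_stack([np.ones_like(w), 1.0 / w])
        for marker in markers:
            y = mom[f"{marker}_mom"].to_numpy(dtype=float)
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            self.coef_[marker] = (float(beta[0]), float(beta[1]))
        return self

    def expected_mom(self, weight, marker: str):
        if marker not in self.coef_:
            raise KeyError(f"weight model not fitted for marker {marker!r}")
        a, b = self.coef_[marker]
        return a + b / np.asarray(weight, dtype=float)


def weight_adjust(
    mom: pd.DataFrame,
    weights,
    model,
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Divide each observed MoM by the model's expected MoM at the weight."""
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    out = mom.copy()
    for marker in markers:
        if isinstance(model, IdentityWeightModel):
            expected = model.expected_mom(w)
        else:
            expected = np.asarray(model.expected_mom(w, marker), dtype=float)
        adj = mom[f"{marker}_mom"].to_numpy(dtype=float) / expected
        out[f"{marker}_mom"] = adj
        out[f"{marker}_log10_mom"] = np.log10(adj)
    out.attrs["weight_adjusted"] = True
    return out


class MedianNormalizer(TransformerMixin, BaseEstimator):
    """MoM normalizer with a scikit-learn fit/transform surface.

    ``fit`` estimates the control median curve (week-stratified for the
    gestation-dependent markers, flat for sHLA-G) from the control rows
    of a cohort frame; ``transform`` maps any cohort frame to per-marker
    MoM and log10 MoM columns.

    Parameters
    ----------
    markers : tuple of str
        Markers to normalize, default the full four-analyte panel.
    control_label : str
        Value of the ``group`` column identifying controls during fit;
        if the frame has no ``group`` column all rows are used.
    weight_model : {"identity", "reciprocal"}
        Optional maternal-weight MoM correction fitted on the same
        controls; the identity model leaves MoM untouched.

    Attributes
    ----------
    median_curve_ : MedianCurve
        Fitted control medians.
    weight_model_ : IdentityWeightModel or ReciprocalWeightModel
    """

    def __init__(
        self,
        markers: tuple[str, ...] = MARKERS,
        control_label: str = "control",
        weight_model: str = "identity",
    ) -> None:
        self.markers = markers
        self.control_label = control_label
        self.weight_model = weight_model

    def fit(self, X: pd.DataFrame, y=None) -> "MedianNormalizer":
        if self.weight_model not in ("identity", "reciprocal"):
            raise ValueError(
                f"unknown weight_model {self.weight_model!r}; "
                "expected 'identity' or 'reciprocal'"
            )
        controls = (
            X[X["group"] == self.control_label] if "group" in X.columns else X
        )
        self.median_curve_ = fit_median_curve(controls, markers=self.markers)
        if self.weight_model == "reciprocal":
            mom = compute_mom(controls, self.median_curve_, self.markers)
            self.weight_model_ = ReciprocalWeightModel().fit(
                controls["weight"], mom, self.markers
            )
        else:
            self.weight_model_ = IdentityWeightModel()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "median_curve_"):
            raise RuntimeError("MedianNormalizer is not fitted")
        mom = compute_mom(X, self.median_curve_, self.markers)
        if isinstance(self.weight_model_, ReciprocalWeightModel):
            mom = weight_adjust(mom, X["weight"], self.weight_model_, self.markers)
        return mom
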