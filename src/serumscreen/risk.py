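"""Gaussian likelihood-ratio risk calculation for trisomy screening.

Each trisomy risk is a Bayes update: prior odds (from birth prevalence or
a maternal-age table) multiplied by the likelihood ratio of the subject's
four-marker log10 MoM profile under the affected versus the unaffected
Gaussian model,

    LR(x) = N(x; mu_aff, Sigma_aff) / N(x; mu_unaff, Sigma_unaff),
    posterior odds = prior odds * LR.

With ``use_correlations=False`` the LR is the product of four univariate
normal density ratios; with correlations on, full multivariate densities
with covariance D R D per group.

:class:`GaussianRiskClassifier` wraps the model in the scikit-learn
estimator contract so it can be fitted from labelled log10 MoM data,
cross-validated, or constructed directly from published group parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .mom import MedianCurve, compute_mom
from .params import MARKERS, GroupParams
from .stats import summarize_group

#: Default flat priors: T18 newborn prevalence ~1/5000; T21 a conventional
#: mid-thirties screening figure (the T21 prior is a tunable convention).
DEFAULT_PRIORS: dict[str, float] = {"T18": 1.0 / 5000.0, "T21": 1.0 / 700.0}


@dataclass
class PriorModel:
    """Prior probability of an affected pregnancy.

    ``flat`` mode returns one configurable probability regardless of age;
    ``age_table`` mode looks up the completed maternal age year in a
    user-supplied table (no table is bundled).
    """

    mode: str = "flat"
    flat_prior: float = DEFAULT_PRIORS["T18"]
    age_table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("flat", "age_table"):
            raise ValueError(f"unknown prior mode {self.mode!r}")
        if not 0.0 < self.flat_prior < 1.0:
            raise ValueError("flat_prior must be in (0, 1)")
        for age, p in self.age_table.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prior for age {age} outside (0, 1)")

    def prior_for(self, age: float | None = None) -> float:
        if self.mode == "flat":
            return self.flat_prior
        if age is None:
            raise ValueError("age_table prior needs a maternal age")
        year = int(age)
        if year not in self.age_table:
            raise KeyError(f"no prior for maternal age {year}")
        return self.age_table[year]


def likelihood_ratio(
    log_mom: np.ndarray,
    affected: GroupParams,
    unaffected: GroupParams,
    use_correlations: bool = False,
) -> np.ndarray | float:
    """Gaussian density ratio affected/unaffected at the log10 MoM point(s).

    ``log_mom`` may be one profile or an ``(n, k)`` matrix; a scalar or an
    array of positive LRs is returned accordingly.  Computation is done on
    log densities for numerical range.
    """
    x = np.atleast_2d(np.asarray(log_mom, dtype=float))
    if use_correlations:
        num = sps.multivariate_normal(
            affected.mean_log10_mom, affected.covariance(True)
        ).logpdf(x)
        den = sps.multivariate_normal(
            unaffected.mean_log10_mom, unaffected.covariance(True)
        ).logpdf(x)
    else:
        num = sps.norm.logpdf(
            x, affected.mean_log10_mom, affected.sd_log10_mom
        ).sum(axis=1)
        den = sps.norm.logpdf(
            x, unaffected.mean_log10_mom, unaffected.sd_log10_mom
        ).sum(axis=1)
    lr = np.exp(np.atleast_1d(num) - np.atleast_1d(den))
    return float(lr[0]) if np.asarray(log_mom).ndim == 1 else lr


def posterior_risk(prior, lr):
    """Odds-form Bayes update: posterior = prior_odds*LR / (1 + prior_odds*LR)."""
    prior = np.asarray(prior, dtype=float)
    lr = np.asarray(lr, dtype=float)
    if np.any((prior <= 0) | (prior >= 1)):
        raise ValueError("prior must be in (0, 1)")
    if np.any(lr <= 0):
        raise ValueError("likelihood ratio must be > 0")
    odds = prior / (1.0 - prior) * lr
    post = odds / (1.0 + odds)
    return float(post) if post.ndim == 0 else post


class GaussianRiskClassifier(ClassifierMixin, BaseEstimator):
    """Two-class Gaussian likelihood-ratio screener on log10 MoM profiles.

    This is linear/quadratic discriminant analysis specialised to the
    screening convention: class-conditional Gaussians with per-class
    covariance (diagonal by default), an externally specified disease
    prior (screening priors come from prevalence, not from case-control
    sampling fractions), and risks reported as posterior probabilities.

    Parameters
    ----------
    prior : float
        Prior probability of the affected class, default the trisomy-18
        newborn prevalence 1/5000.
    use_correlations : bool
        Use the full covariance (``True``) or treat markers as
        independent given the class (``False``, the default: published
        correlations are rounded and partly non-significant).
    threshold : float
        Posterior risk at or above which a subject screens positive.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; the larger label is treated as affected.
    affected_params_, unaffected_params_ : GroupParams
        Estimated (or supplied) per-class Gaussian parameters.
    """

    def __init__(
        self,
        prior: float = DEFAULT_PRIORS["T18"],
        use_correlations: bool = False,
        threshold: float = 0.01,
    ) -> None:
        self.prior = prior
        self.use_correlations = use_correlations
        self.threshold = threshold

    def fit(self, X, y) -> "GaussianRiskClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (subjects x markers)")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes are required")
        markers = tuple(f"m{j}" for j in range(X.shape[1]))
        frames = {}
        for label in self.classes_:
            sub = X[y == label]
            if len(sub) < 2:
                raise ValueError(f"class {label!r} needs at least 2 subjects")
            frame = pd.DataFrame(
                {f"{m}_log10_mom": sub[:, j] for j, m in enumerate(markers)}
            )
            for m in markers:  # summarize_group also wants MoM columns
                frame[f"{m}_mom"] = 10.0 ** frame[f"{m}_log10_mom"]
            frames[label] = summarize_group(frame, str(label), markers)
        self.unaffected_params_ = frames[self.classes_[0]]
        self.affected_params_ = frames[self.classes_[1]]
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_group_params(
        cls,
        affected: GroupParams,
        unaffected: GroupParams,
        prior: float = DEFAULT_PRIORS["T18"],
        use_correlations: bool = False,
        threshold: float = 0.01,
    ) -> "GaussianRiskClassifier":
        """Build a ready-to-use screener from published group parameters."""
        est = cls(prior=prior, use_correlations=use_correlations, threshold=threshold)
        est.classes_ = np.array([0, 1])
        est.unaffected_params_ = unaffected
        est.affected_params_ = affected
        est.n_features_in_ = len(affected.mean_log10_mom)
        return est

    def likelihood_ratio(self, X) -> np.ndarray:
        check_is_fitted(self, "affected_params_")
        X = np.asarray(X, dtype=float)
        return np.atleast_1d(
            likelihood_ratio(
                np.atleast_2d(X),
                self.affected_params_,
                self.unaffected_params_,
                self.use_correlations,
            )
        )

    def decision_function(self, X) -> np.ndarray:
        """Log likelihood ratio (monotone in the posterior risk)."""
        return np.log(self.likelihood_ratio(X))

    def predict_proba(self, X) -> np.ndarray:
        post = posterior_risk(self.prior, self.likelihood_ratio(X))
        post = np.atleast_1d(post)
        return np.column_stack([1.0 - post, post])

    def predict(self, X) -> np.ndarray:
        post = self.predict_proba(X)[:, 1]
        return np.where(post >= self.threshold, self.classes_[1], self.classes_[0])


def score_cohort(
    cohort: pd.DataFrame,
    curve: MedianCurve,
    params_by_group: dict[str, GroupParams],
    prior_model: PriorModel | dict[str, PriorModel] | None = None,
    threshold: float = 0.01,
    use_correlations: bool = False,
    trisomies: tuple[str, ...] = ("T21", "T18"),
    markers: tuple[str, ...] = MARKERS,
) -> pd.DataFrame:
    """Score every subject for every trisomy.

    Returns a long DataFrame with columns ``subject_id, trisomy, prior,
    lr, posterior, screen_positive``.  ``prior_model`` may be one model
    for all trisomies, a per-trisomy mapping, or None for the default
    flat priors.
    """
    missing = [m for m in markers if m not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks marker columns {missing}")
    mom = compute_mom(cohort, curve, markers)
    x = mom[[f"{m}_log10_mom" for m in markers]].to_numpy(dtype=float)
    control = params_by_group["control"]
    out_frames = []
    for trisomy in trisomies:
        if trisomy not in params_by_group:
            raise KeyError(f"no parameters for group {trisomy!r}")
        if isinstance(prior_model, dict):
            pm = prior_model[trisomy]
        elif prior_model is None:
            pm = PriorModel(flat_prior=DEFAULT_PRIORS.get(trisomy, 1.0 / 1000.0))
        else:
            pm = prior_model
        priors = np.array([pm.prior_for(a) for a in cohort["age"]])
        lr = likelihood_ratio(x, params_by_group[trisomy], control, use_correlations)
        post = posterior_risk(priors, lr)
        out_frames.append(
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"].to_numpy(),
                    "trisomy": trisomy,
                    "prior": priors,
                    "lr": lr,
                    "posterior": post,
                    "screen_positive": post >= threshold,
                }
            )
        )
    return pd.concat(out_frames, ignore_index=True)
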