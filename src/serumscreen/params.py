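"""Per-group distribution parameters for the four-analyte marker panel.

The screening model treats each pregnancy group (unaffected controls,
trisomy 21, trisomy 18) as multivariate Gaussian on the log10 MoM scale.
A :class:`GroupParams` bundles the mean vector, SD vector and pairwise
correlation matrix of log10 MoM for one group, plus the per-marker median
MoM and the group size.  The packaged default parameter file transcribes
the published second-trimester reference population (797 controls, 139
T21, 83 T18 pregnancies) with AFP, free beta-hCG, uE3 and sHLA-G.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Canonical marker order used by every matrix/vector in the package.
MARKERS: tuple[str, ...] = ("afp", "free_bhcg", "ue3", "shla_g")

#: Recognised group labels.
GROUPS: tuple[str, ...] = ("control", "T21", "T18")

_PD_EPS = 1e-10


class CovarianceError(ValueError):
    """Raised when a covariance matrix cannot be made positive definite."""


def nearest_positive_definite(matrix: np.ndarray, eps: float = _PD_EPS) -> np.ndarray:
    """Return the nearest symmetric positive-definite matrix.

    Symmetrises, then clips eigenvalues from below at ``eps``.  Rounded
    published correlations can produce matrices that are indefinite by a
    hair; this repairs them while leaving valid matrices untouched.
    """
    sym = (matrix + matrix.T) / 2.0
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() >= eps:
        return sym
    clipped = np.clip(eigval, eps, None)
    return (eigvec * clipped) @ eigvec.T


@dataclass
class GroupParams:
    """Gaussian log10 MoM parameters for one pregnancy group.

    Parameters
    ----------
    group : str
        Group label (``control``, ``T21`` or ``T18``, or any string for
        ad-hoc groups).
    mean_log10_mom, sd_log10_mom : array-like of shape (n_markers,)
        Mean and sample SD of log10 MoM per marker, in :data:`MARKERS`
        order.
    correlation : array-like of shape (n_markers, n_markers)
        Pairwise Pearson correlations of log10 MoM.
    median_mom : array-like, optional
        Observed median MoM per marker (reporting only; not used by the
        risk model).
    n : int, optional
        Number of subjects the parameters were estimated from.
    """

    group: str
    mean_log10_mom: np.ndarray
    sd_log10_mom: np.ndarray
    correlation: np.ndarray
    median_mom: np.ndarray | None = None
    n: int | None = None
    markers: tuple[str, ...] = field(default=MARKERS)

    def __post_init__(self) -> None:
        self.mean_log10_mom = np.asarray(self.mean_log10_mom, dtype=float)
        self.sd_log10_mom = np.asarray(self.sd_log10_mom, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.median_mom is not None:
            self.median_mom = np.asarray(self.median_mom, dtype=float)
        k = len(self.markers)
        if self.mean_log10_mom.shape != (k,) or self.sd_log10_mom.shape != (k,):
            raise ValueError(
                f"group {self.group!r}: mean/sd must have shape ({k},)"
            )
        if not np.all(np.isfinite(self.mean_log10_mom)):
            raise ValueError(f"group {self.group!r}: non-finite mean")
        # SD 0 is tolerated for degenerate estimated groups (the affected
        # correlations are then NaN); covariance() still requires SD > 0.
        if np.any(self.sd_log10_mom < 0):
            raise ValueError(f"group {self.group!r}: SDs must be >= 0")
        if self.correlation.shape != (k, k):
            raise ValueError(
                f"group {self.group!r}: correlation must be {k}x{k}"
            )
        if not np.allclose(
            self.correlation, self.correlation.T, atol=1e-12, equal_nan=True
        ):
            raise ValueError(f"group {self.group!r}: correlation not symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0, atol=1e-12):
            raise ValueError(f"group {self.group!r}: correlation diagonal != 1")
        finite = self.correlation[np.isfinite(self.correlation)]
        if np.any(np.abs(finite) > 1 + 1e-12):
            raise ValueError(
                f"group {self.group!r}: correlation entries outside [-1, 1]"
            )

    def covariance(self, use_correlations: bool = True) -> np.ndarray:
        """Covariance of log10 MoM, ``D R D`` (or ``diag(sd**2)``).

        If ``D R D`` is not positive definite it is repaired by eigenvalue
        clipping with a warning; if the repair still fails a
        :class:`CovarianceError` names the group.
        """
        if np.any(self.sd_log10_mom <= 0):
            raise CovarianceError(
                f"group {self.group!r}: covariance needs all SDs > 0"
            )
        if not use_correlations:
            return np.diag(self.sd_log10_mom**2)
        if not np.all(np.isfinite(self.correlation)):
            raise CovarianceError(
                f"group {self.group!r}: covariance needs finite correlations"
            )
        d = np.diag(self.sd_log10_mom)
        cov = d @ self.correlation @ d
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            warnings.warn(
                f"covariance for group {self.group!r} not positive definite; "
                "applying nearest-PD repair",
                RuntimeWarning,
                stacklevel=2,
            )
        cov = nearest_positive_definite(cov)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise CovarianceError(
                f"covariance for group {self.group!r} not positive definite "
                "after nearest-PD repair"
            ) from exc
        return cov

    def to_dict(self) -> dict:
        out = {
            "group": self.group,
            "mean_log10_mom": self.mean_log10_mom.tolist(),
            "sd_log10_mom": self.sd_log10_mom.tolist(),
            "correlation": self.correlation.tolist(),
            "markers": list(self.markers),
        }
        if self.median_mom is not None:
            out["median_mom"] = self.median_mom.tolist()
        if self.n is not None:
            out["n"] = self.n
        return out

    @classmethod
    def from_dict(cls, group: str, payload: dict) -> "GroupParams":
        return cls(
            group=group,
            mean_log10_mom=payload["mean_log10_mom"],
            sd_log10_mom=payload["sd_log10_mom"],
            correlation=payload["correlation"],
            median_mom=payload.get("median_mom"),
            n=payload.get("n"),
            markers=tuple(payload.get("markers", MARKERS)),
        )


def _default_payload() -> dict:
    with resources.files("serumscreen.data").joinpath(
        "default_cohort_params.json"
    ).open("r", encoding="utf-8") as fh:
        return json.load(fh)


def load_default_params() -> dict[str, GroupParams]:
    """Load the packaged reference-population parameters, one per group."""
    payload = _default_payload()
    return {
        group: GroupParams.from_dict(group, block)
        for group, block in payload["groups"].items()
    }


def load_default_payload() -> dict:
    """Raw packaged defaults (group sizes, medians, demographics)."""
    return _default_payload()
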