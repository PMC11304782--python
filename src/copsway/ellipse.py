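"""Probability (error) ellipse evaluation of a COP trajectory.

The trajectory is modeled as draws from a bivariate normal distribution.
The probability ellipse at coverage level :math:`p` is the level set of the
fitted density containing probability mass :math:`p`: with sample mean
:math:`\\mu` and sample covariance :math:`\\Sigma` (denominator ``n-1``),
its semi-axes are :math:`\\sqrt{q\\,\\lambda_i}` along the eigenvectors of
:math:`\\Sigma`, where :math:`q` is the :math:`\\chi^2_2` quantile at
:math:`p` (``q = 4.605`` at the default 0.900).

Four scalar descriptors summarize the fitted ellipse:

* long diameter ``delta`` (full major-axis length, mm),
* declination ``theta`` — the signed angle of the major axis from the
  anterior–posterior midline (+y), in degrees, leftward (+x) tilt positive,
  range (−90, 90];
* eccentricity ``eps = sqrt((a^2 − b^2)/a^2)`` for long/short diameters
  ``a >= b`` (ratio-invariant: full or semi diameters give the same value);
* lateral sway component ``psi = sin(theta) * delta/2`` (signed, mm) —
  the laterally directed share of the sway radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import DegenerateTrajectoryError, ValidationError
from .trajectory import CopTrajectory

__all__ = [
    "ProbabilityEllipse",
    "ProbabilityEllipseModel",
    "fit_probability_ellipse",
    "eccentricity",
    "declination_from_axis",
    "lateral_component",
    "coverage_fraction",
    "chi2_scale",
    "descriptors_from_covariance",
]

# Relative eigenvalue gap below which the orientation is unidentifiable.
_ISOTROPY_RTOL = 1e-12


def chi2_scale(coverage: float) -> float:
    """Chi-square(2 d.o.f.) quantile used to scale eigenvalues to semi-axes."""
    if not 0.0 < coverage < 1.0:
        raise ValidationError(f"coverage must be in (0, 1), got {coverage}")
    return float(stats.chi2.ppf(coverage, df=2))


def eccentricity(long_diameter: float, short_diameter: float) -> float:
    """Eccentricity ``sqrt((a^2 - b^2)/a^2)`` of an ellipse.

    ``a`` and ``b`` may be full or semi diameters — the ratio is what counts.
    0 for a circle, 1 for a degenerate segment.
    """
    a, b = float(long_diameter), float(short_diameter)
    if a <= 0:
        raise ValidationError(f"long diameter must be positive, got {a}")
    if b < 0 or b > a:
        raise ValidationError(f"need long >= short >= 0, got ({a}, {b})")
    return float(np.sqrt((a * a - b * b) / (a * a)))


def declination_from_axis(axis) -> float:
    """Signed angle (degrees) of an axis direction from the +y midline.

    The argument is an (x, y) direction vector for the major axis; it is an
    axis, not a ray, so ``v`` and ``-v`` give the same answer.  Leftward
    (+x) tilt is positive; the result lies in (−90, 90], with an exactly
    lateral axis reported as +90.
    """
    v = np.asarray(axis, dtype=float)
    if v.shape != (2,):
        raise ValidationError(f"axis must be a 2-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)) or np.allclose(v, 0.0):
        raise ValidationError("axis must be a finite nonzero vector")
    vx, vy = v
    # canonical representative: nonnegative y, and +x when y == 0
    if vy < 0 or (vy == 0 and vx < 0):
        vx, vy = -vx, -vy
    theta = float(np.degrees(np.arctan2(vx, vy)))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    if theta == -90.0:  # boundary collapses to +90
        theta = 90.0
    return theta


@dataclass(frozen=True)
class ProbabilityEllipse:
    """A fitted probability ellipse and its scalar descriptors.

    ``covariance`` is the sample covariance the ellipse was built from; it is
    retained so containment can be tested via Mahalanobis distance.
    """

    center: tuple[float, float]
    long_diameter: float
    short_diameter: float
    declination: float
    eccentricity: float
    lateral_component: float
    coverage: float
    covariance: np.ndarray
    degenerate: bool = False
    degenerate_orientation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage < 1.0:
            raise ValidationError("coverage must be in (0, 1)")
        if not self.long_diameter >= self.short_diameter >= 0.0:
            raise ValidationError("need long_diameter >= short_diameter >= 0")
        if not -90.0 < self.declination <= 90.0:
            raise ValidationError("declination must lie in (-90, 90]")
        if abs(self.lateral_component) > self.long_diameter / 2 + 1e-12:
            raise ValidationError("|lateral_component| cannot exceed the semi-diameter")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValidationError("covariance must be 2x2")
        cov.setflags(write=False)
        object.__setattr__(self, "covariance", cov)

    @property
    def scale(self) -> float:
        """Squared-Mahalanobis radius of the ellipse boundary."""
        return chi2_scale(self.coverage)


def lateral_component(ellipse: ProbabilityEllipse) -> float:
    """Signed lateral sway component ``sin(declination) * long_diameter/2``."""
    return float(
        np.sin(np.radians(ellipse.declination)) * ellipse.long_diameter / 2.0
    )


class ProbabilityEllipseModel(BaseEstimator):
    """Bivariate-normal probability-ellipse estimator for planar sway data.

    Scikit-learn style: ``fit(X)`` with ``X`` of shape (n_samples, 2) holding
    (lateral, anterior–posterior) displacements; fitted attributes carry a
    trailing underscore.  ``predict`` labels points +1 inside the ellipse and
    -1 outside (the inlier convention of ``sklearn.covariance.EllipticEnvelope``).

    Parameters
    ----------
    coverage : float, default 0.900
        Probability mass the ellipse is scaled to contain under the fitted
        bivariate normal.

    Attributes
    ----------
    center_ : ndarray, shape (2,)
        Sample mean.
    covariance_ : ndarray, shape (2, 2)
        Sample covariance (denominator n-1).
    eigenvalues_ : ndarray, shape (2,)
        Covariance eigenvalues, descending.
    major_axis_ : ndarray, shape (2,)
        Unit eigenvector of the leading eigenvalue, canonicalized to
        nonnegative y (and +x when y = 0).
    long_diameter_, short_diameter_ : float
        Full axis lengths, ``2 * sqrt(q * eigenvalue)``.
    declination_ : float
        Major-axis angle from the +y midline, degrees in (-90, 90].
    eccentricity_ : float
    lateral_component_ : float
    degenerate_ : bool
        True when the covariance is rank-1 (short diameter 0, eccentricity 1).
    degenerate_orientation_ : bool
        True when the covariance is isotropic; the orientation is then
        unidentifiable and reported as the midline (declination 0).
    """

    def __init__(self, coverage: float = 0.900):
        self.coverage = coverage

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None) -> "ProbabilityEllipseModel":
        X = self._validate_points(X)
        if X.shape[0] < 3:
            raise ValidationError(
                f"need at least 3 points to fit an ellipse, got {X.shape[0]}"
            )
        q = chi2_scale(self.coverage)
        center = X.mean(axis=0)
        cov = np.cov(X, rowvar=False, ddof=1)
        if not np.all(np.isfinite(cov)):
            raise ValidationError("sample covariance is not finite")
        if np.allclose(cov, 0.0):
            raise DegenerateTrajectoryError(
                "all points identical: zero total variance, no ellipse exists"
            )
        evals, evecs = np.linalg.eigh(cov)  # ascending
        evals = np.clip(evals[::-1], 0.0, None)
        evecs = evecs[:, ::-1]
        lam1, lam2 = float(evals[0]), float(evals[1])

        isotropic = (lam1 - lam2) <= _ISOTROPY_RTOL * lam1
        if isotropic:
            # orientation unidentifiable; report the physiologically neutral
            # midline
            major = np.array([0.0, 1.0])
            declination = 0.0
        else:
            major = evecs[:, 0].copy()
            if major[1] < 0 or (major[1] == 0 and major[0] < 0):
                major = -major
            declination = declination_from_axis(major)

        a = float(np.sqrt(q * lam1))
        b = float(np.sqrt(q * lam2))

        self.n_features_in_ = 2
        self.n_samples_ = int(X.shape[0])
        self.scale_ = q
        self.center_ = center
        self.covariance_ = cov
        self.eigenvalues_ = evals
        self.major_axis_ = major
        self.long_diameter_ = 2.0 * a
        self.short_diameter_ = 2.0 * b
        self.declination_ = declination
        self.eccentricity_ = eccentricity(2.0 * a, 2.0 * b)
        self.degenerate_ = lam2 <= _ISOTROPY_RTOL * lam1
        self.degenerate_orientation_ = isotropic
        self.lateral_component_ = (
            0.0 if isotropic else float(np.sin(np.radians(declination)) * a)
        )
        self.ellipse_ = ProbabilityEllipse(
            center=(float(center[0]), float(center[1])),
            long_diameter=self.long_diameter_,
            short_diameter=self.short_diameter_,
            declination=self.declination_,
            eccentricity=self.eccentricity_,
            lateral_component=self.lateral_component_,
            coverage=self.coverage,
            covariance=cov,
            degenerate=self.degenerate_,
            degenerate_orientation=self.degenerate_orientation_,
        )
        return self

    # -- inference -------------------------------------------------------

    def mahalanobis(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each point from the fitted center."""
        self._check_fitted()
        if self.degenerate_:
            raise DegenerateTrajectoryError(
                "covariance is singular; Mahalanobis distance undefined"
            )
        X = self._validate_points(X)
        diff = X - self.center_
        sol = np.linalg.solve(self.covariance_, diff.T)
        return np.einsum("ij,ji->i", diff, sol)

    def contains(self, X) -> np.ndarray:
        """Boolean mask of points inside or on the fitted ellipse."""
        return self.mahalanobis(X) <= self.scale_

    def predict(self, X) -> np.ndarray:
        """+1 for points inside the ellipse, -1 outside."""
        return np.where(self.contains(X), 1, -1)

    def score_samples(self, X) -> np.ndarray:
        """Negative squared Mahalanobis distance (higher = more central)."""
        return -self.mahalanobis(X)

    # -- export ----------------------------------------------------------

    def boundary(self, n: int = 256) -> np.ndarray:
        """(n, 2) polyline tracing the ellipse boundary, for plotting."""
        self._check_fitted()
        ang = np.linspace(0.0, 2.0 * np.pi, n)
        circ = np.column_stack([np.cos(ang), np.sin(ang)])
        lam = np.sqrt(self.scale_ * self.eigenvalues_)
        evecs = np.column_stack(
            [self.major_axis_, [-self.major_axis_[1], self.major_axis_[0]]]
        )
        return self.center_ + circ * lam @ evecs.T

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _validate_points(X) -> np.ndarray:
        if isinstance(X, CopTrajectory):
            return X.xy
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValidationError(f"expected (n, 2) points, got shape {X.shape}")
        if not np.all(np.isfinite(X)):
            raise ValidationError("points contain non-finite values")
        return X

    def _check_fitted(self) -> None:
        if not hasattr(self, "covariance_"):
            raise ValidationError("model is not fitted; call fit(X) first")


def fit_probability_ellipse(
    traj: CopTrajectory | np.ndarray, coverage: float = 0.900
) -> ProbabilityEllipse:
    """Fit the probability ellipse to a trajectory (or raw (n, 2) points)."""
    return ProbabilityEllipseModel(coverage=coverage).fit(traj).ellipse_


def descriptors_from_covariance(
    covariance, coverage: float = 0.900
) -> dict[str, float]:
    """Ellipse descriptors implied by a known (population) covariance.

    Useful for computing exact ground-truth metrics of a simulated process
    whose covariance is known in closed form, bypassing estimation noise.
    Returns a dict with ``long_diameter``, ``short_diameter``,
    ``declination``, ``eccentricity`` and ``lateral_component``.
    """
    cov = np.asarray(covariance, dtype=float)
    if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
        raise ValidationError("covariance must be a finite 2x2 matrix")
    q = chi2_scale(coverage)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals[::-1], 0.0, None)
    evecs = evecs[:, ::-1]
    lam1, lam2 = float(evals[0]), float(evals[1])
    if lam1 <= 0:
        raise DegenerateTrajectoryError("zero covariance has no ellipse")
    if (lam1 - lam2) <= _ISOTROPY_RTOL * lam1:
        declination = 0.0
    else:
        declination = declination_from_axis(evecs[:, 0])
    a, b = np.sqrt(q * lam1), np.sqrt(q * lam2)
    return {
        "long_diameter": float(2 * a),
        "short_diameter": float(2 * b),
        "declination": declination,
        "eccentricity": eccentricity(2 * a, 2 * b),
        "lateral_component": float(np.sin(np.radians(declination)) * a),
    }


def coverage_fraction(
    traj: CopTrajectory | np.ndarray, ellipse: ProbabilityEllipse
) -> float:
    """Fraction of trajectory points inside (or on) the given ellipse.

    Containment is judged by squared Mahalanobis distance from the ellipse
    center with respect to its generating covariance, compared against the
    chi-square scale of its coverage level — identical to evaluating the
    geometric ellipse equation in principal-axis coordinates.
    """
    if ellipse.degenerate:
        raise DegenerateTrajectoryError(
            "degenerate ellipse: coverage fraction undefined"
        )
    X = ProbabilityEllipseModel._validate_points(traj)
    diff = X - np.asarray(ellipse.center)
    sol = np.linalg.solve(ellipse.covariance, diff.T)
    d2 = np.einsum("ij,ji->i", diff, sol)
    return float(np.mean(d2 <= ellipse.scale))
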