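"""Classical computer-vision detectors for the glottal midline.

Every detector maps a non-negative weighted image (a binary mask is the
weight-1 special case; summed temporal-context images carry integer
weights) to a :class:`Midline` — the symmetry axis of the glottal area
given by its posterior (P, smaller y) and anterior (A) endpoints.

Detectors
---------
``tb``       top/bottom-most support rows (row-wise centers of mass)
``lr``       least squares minimizing residuals transverse to the axis
             (image transposed so the near-vertical axis becomes a
             function, then inverted back)
``odr``      orthogonal distance regression (total least squares),
             numerically via ODRPACK
``pca``      first principal component of the weighted pixel cloud
``moments``  centroid + orientation from second-order central image
             moments, tan(2a) = 2*mu11 / (mu20 - mu02)
``ellipse``  least-squares ellipse fit to the outer support contour;
             the major axis is the midline

ODR, PCA and image moments are all principal-axis estimators and agree
to numerical precision; they are kept as independent routes (iterative
optimizer, eigendecomposition, closed-form angle) and cross-checked in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

with warnings.catch_warnings():
    warnings.simplefilter("ignore", DeprecationWarning)
    from scipy import odr as _scipy_odr

from skimage.measure import EllipseModel, find_contours

__all__ = [
    "Midline",
    "DetectorError",
    "EmptyImageError",
    "DegenerateShapeError",
    "LineMissesSupportError",
    "midline_tb",
    "midline_lr",
    "midline_odr",
    "midline_pca",
    "midline_moments",
    "midline_ellipse",
    "line_to_endpoints",
    "image_moments",
    "DETECTORS",
]


class DetectorError(ValueError):
    """A detector could not produce a midline on this input."""


class EmptyImageError(DetectorError):
    """No foreground (all weights zero)."""


class DegenerateShapeError(DetectorError):
    """Orientation undefined (e.g. circular support, isotropic moments)."""


class LineMissesSupportError(DetectorError):
    """The fitted line does not intersect the image support."""


@dataclass(frozen=True)
class Midline:
    """Posterior-anterior axis in pixel coordinates (P.y <= A.y)."""

    P: tuple
    A: tuple

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        A = np.asarray(self.A, dtype=float)
        if np.allclose(P, A):
            raise ValueError("midline endpoints coincide")
        if P[1] > A[1]:
            raise ValueError("posterior point must have the smaller y")
        object.__setattr__(self, "P", tuple(P))
        object.__setattr__(self, "A", tuple(A))

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from P to A."""
        d = np.asarray(self.A) - np.asarray(self.P)
        return d / np.linalg.norm(d)

    @property
    def angle(self) -> float:
        """Axis angle in radians, mapped to (-pi/2, pi/2] about vertical
        symmetry: the undirected angle of the axis against the x-axis."""
        d = self.direction
        a = np.arctan2(d[1], d[0])
        if a <= -np.pi / 2:
            a += np.pi
        elif a > np.pi / 2:
            a -= np.pi
        return a

    def slope_intercept(self) -> tuple[float, float]:
        """(m, b) of y = m x + b; raises for a vertical axis."""
        d = self.direction
        if abs(d[0]) < 1e-12:
            raise ValueError("vertical midline has no finite slope")
        m = d[1] / d[0]
        b = self.P[1] - m * self.P[0]
        return m, b


def _weights_and_coords(image: np.ndarray, largest_component: bool = True):
    """Flattened (x, y, w) of the strictly positive support.

    With ``largest_component`` (default) only the largest 8-connected
    support component is kept — contour noise or a posterior gap can
    split the glottal area into fragments.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DetectorError("image must be 2-D")
    if np.any(img < 0):
        raise DetectorError("weights must be non-negative")
    support = img > 0
    if not support.any():
        raise EmptyImageError("image has no foreground")
    if largest_component:
        labels, n = ndimage.label(support, structure=np.ones((3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(support, labels, index=np.arange(1, n + 1))
            support = labels == (1 + np.argmax(sizes))
    ys, xs = np.nonzero(support)
    return xs.astype(float), ys.astype(float), img[support]


def midline_tb(image: np.ndarray, largest_component: bool = True) -> Midline:
    """Top/bottom-most rule: P and A are the centers of mass of the
    first and last occupied row of the support."""
    xs, ys, w = _weights_and_coords(image, largest_component)
    y_top, y_bot = ys.min(), ys.max()
    if y_top == y_bot:
        raise DegenerateShapeError("support occupies a single row")

    def row_com(y):
        sel = ys == y
        return float(np.average(xs[sel], weights=w[sel]))

    return Midline(P=(row_com(y_top), float(y_top)),
                   A=(row_com(y_bot), float(y_bot)))


def _wls_x_of_y(xs, ys, w):
    """Weighted normal equations for x = t0 + t1 * y."""
    W = np.sum(w)
    my, mx = np.sum(w * ys) / W, np.sum(w * xs) / W
    cyy = np.sum(w * (ys - my) ** 2)
    cxy = np.sum(w * (ys - my) * (xs - mx))
    if cyy == 0:
        raise DegenerateShapeError("support has no vertical extent")
    t1 = cxy / cyy
    t0 = mx - t1 * my
    return t0, t1


def midline_lr(image: np.ndarray, largest_component: bool = True) -> Midline:
    """Transposed linear regression.

    Fits ``x = t0 + t1 * y`` by weighted least squares (residuals
    minimized in x, i.e. the image is transposed so the near-vertical
    midline is single-valued) and inverts back.
    """
    xs, ys, w = _weights_and_coords(image, largest_component)
    t0, t1 = _wls_x_of_y(xs, ys, w)
    point = np.array([t0, 0.0])
    direction = np.array([t1, 1.0])
    direction /= np.linalg.norm(direction)
    return line_to_endpoints(point, direction, image, largest_component)


def odr_axis(image: np.ndarray,
             largest_component: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Exact ODR line as ``(point, unit direction)``.

    Minimizes the weighted sum of squared perpendicular distances via
    ODRPACK (modified Levenberg-Marquardt), initialised from the
    transposed ordinary fit.  Works in the transposed frame
    ``x = t0 + t1 * y`` so near-vertical midlines are well-posed.
    """
    xs, ys, w = _weights_and_coords(image, largest_component)
    beta0 = _wls_x_of_y(xs, ys, w)
    data = _scipy_odr.Data(ys, xs, wd=w, we=w)
    model = _scipy_odr.Model(lambda beta, y: beta[0] + beta[1] * y)
    fit = _scipy_odr.ODR(data, model, beta0=list(beta0),
                         sstol=1e-14, partol=1e-14, maxit=200).run()
    t0, t1 = fit.beta
    direction = np.array([t1, 1.0])
    return np.array([t0, 0.0]), direction / np.linalg.norm(direction)


def midline_odr(image: np.ndarray, largest_component: bool = True) -> Midline:
    """Orthogonal distance regression (total least squares)."""
    point, direction = odr_axis(image, largest_component)
    return line_to_endpoints(point, direction, image, largest_component)


def midline_pca(image: np.ndarray, largest_component: bool = True) -> Midline:
    """First principal component of the weighted pixel coordinates."""
    xs, ys, w = _weights_and_coords(image, largest_component)
    W = np.sum(w)
    mean = np.array([np.sum(w * xs), np.sum(w * ys)]) / W
    dx, dy = xs - mean[0], ys - mean[1]
    cov = np.array([[np.sum(w * dx * dx), np.sum(w * dx * dy)],
                    [np.sum(w * dx * dy), np.sum(w * dy * dy)]]) / W
    evals, evecs = np.linalg.eigh(cov)
    if np.isclose(evals[0], evals[1]):
        raise DegenerateShapeError("isotropic covariance: axis undefined")
    pc1 = evecs[:, np.argmax(evals)]
    return line_to_endpoints(mean, pc1, image, largest_component)


def image_moments(image: np.ndarray, largest_component: bool = True) -> dict:
    """Weighted raw and central image moments of the support.

    Returns m00 (area/total weight), centroid (x, y), central moments
    mu11/mu20/mu02 and the orientation angle alpha (radians) of the
    major axis, ``tan(2 alpha) = 2 mu11 / (mu20 - mu02)`` resolved with
    atan2 so alpha always points along the larger-variance direction.
    """
    xs, ys, w = _weights_and_coords(image, largest_component)
    m00 = np.sum(w)
    xbar = np.sum(w * xs) / m00
    ybar = np.sum(w * ys) / m00
    mu11 = np.sum(w * (xs - xbar) * (ys - ybar))
    mu20 = np.sum(w * (xs - xbar) ** 2)
    mu02 = np.sum(w * (ys - ybar) ** 2)
    if np.isclose(mu11, 0.0) and np.isclose(mu20, mu02):
        alpha = np.nan                 # isotropic: orientation undefined
    else:
        alpha = 0.5 * np.arctan2(2.0 * mu11, mu20 - mu02)
    return {"m00": m00, "centroid": (xbar, ybar), "mu11": mu11,
            "mu20": mu20, "mu02": mu02, "alpha": alpha}


def midline_moments(image: np.ndarray,
                    largest_component: bool = True) -> Midline:
    """Centroid + second-moment orientation."""
    mom = image_moments(image, largest_component)
    if np.isnan(mom["alpha"]):
        raise DegenerateShapeError("isotropic moments: axis undefined")
    direction = np.array([np.cos(mom["alpha"]), np.sin(mom["alpha"])])
    return line_to_endpoints(np.asarray(mom["centroid"]), direction, image,
                             largest_component)


def midline_ellipse(image: np.ndarray, largest_component: bool = True,
                    circle_tol: float = 1e-3) -> Midline:
    """Least-squares ellipse fit to the outer contour of the support.

    The midline is the major-axis line through the fitted center.
    Raises for underdetermined contours (< 5 points) and for circular
    fits (relative axis difference below ``circle_tol``), where the
    orientation is undefined.
    """
    img = np.asarray(image, dtype=float)
    support = (img > 0).astype(float)
    if not support.any():
        raise EmptyImageError("image has no foreground")
    if largest_component:
        labels, n = ndimage.label(support > 0, structure=np.ones((3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(support > 0, labels,
                                       index=np.arange(1, n + 1))
            support = (labels == (1 + np.argmax(sizes))).astype(float)
    contours = find_contours(support, 0.5)
    if not contours:
        raise DetectorError("no contour found")
    contour = max(contours, key=len)          # outer contour
    if len(contour) < 5:
        raise DetectorError("contour has fewer than 5 points; "
                            "ellipse underdetermined")
    pts = contour[:, ::-1]                    # (row, col) -> (x, y)
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise DetectorError("ellipse fit failed to converge")
    xc, yc = model.center
    a, b = model.axis_lengths                 # major first
    theta = model.theta                       # major-axis angle
    if a <= 0 or b <= 0:
        raise DetectorError("ellipse fit returned non-positive axes")
    if (a - b) / a < circle_tol:
        raise DegenerateShapeError("near-circular fit: axis undefined")
    direction = np.array([np.cos(theta), np.sin(theta)])
    return line_to_endpoints(np.array([xc, yc]), direction, image,
                             largest_component)


def line_to_endpoints(point: np.ndarray, direction: np.ndarray,
                      image: np.ndarray, largest_component: bool = True,
                      step: float = 0.25) -> Midline:
    """Clip an infinite line to the image support.

    Walks the line across the image in sub-pixel steps; P is the first
    and A the last point whose nearest pixel belongs to the support
    (holes along the way are ignored).  Entry/exit positions are
    refined to the midpoint of the bracketing samples.  The endpoint
    with the smaller y becomes P.
    """
    img = np.asarray(image, dtype=float)
    support = img > 0
    if not support.any():
        raise EmptyImageError("image has no foreground")
    if largest_component:
        labels, n = ndimage.label(support, structure=np.ones((3, 3)))
        if n > 1:
            sizes = ndimage.sum_labels(support, labels,
                                       index=np.arange(1, n + 1))
            support = labels == (1 + np.argmax(sizes))
    H, W = support.shape
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    d = d / norm
    # canonical orientation (y-positive) so the sample grid, and hence
    # the refined endpoints, do not depend on the sign of `direction`
    if d[1] < 0 or (d[1] == 0 and d[0] < 0):
        d = -d
    p0 = np.asarray(point, dtype=float)

    # parameter range where the line crosses the canvas
    s_bounds = []
    for dim, lim in ((0, W - 1), (1, H - 1)):
        if abs(d[dim]) > 1e-12:
            s_bounds.append(((-0.5 - p0[dim]) / d[dim],
                             (lim + 0.5 - p0[dim]) / d[dim]))
    if not s_bounds:
        raise ValueError("direction must be non-zero")
    lo = max(min(a, b) for a, b in s_bounds)
    hi = min(max(a, b) for a, b in s_bounds)
    if hi <= lo:
        raise LineMissesSupportError("line does not cross the canvas")

    s = np.arange(lo, hi + step, step)
    pts = p0[None, :] + s[:, None] * d[None, :]
    cols = np.rint(pts[:, 0]).astype(int)
    rows = np.rint(pts[:, 1]).astype(int)
    ok = (cols >= 0) & (cols < W) & (rows >= 0) & (rows < H)
    hit = np.zeros(len(s), dtype=bool)
    hit[ok] = support[rows[ok], cols[ok]]
    if not hit.any():
        raise LineMissesSupportError("line does not intersect the support")
    first, last = np.flatnonzero(hit)[[0, -1]]

    def refine(i, side):
        j = i + side                      # bracketing outside sample
        if 0 <= j < len(s) and not hit[j]:
            return 0.5 * (pts[i] + pts[j])
        return pts[i]

    e1 = refine(first, -1)
    e2 = refine(last, +1)
    e1 = np.clip(e1, [0, 0], [W - 1, H - 1])
    e2 = np.clip(e2, [0, 0], [W - 1, H - 1])
    if (e1[1], e1[0]) <= (e2[1], e2[0]):
        return Midline(P=tuple(e1), A=tuple(e2))
    return Midline(P=tuple(e2), A=tuple(e1))


#: Registry of detector callables keyed by their short names.
DETECTORS = {
    "tb": midline_tb,
    "lr": midline_lr,
    "odr": midline_odr,
    "pca": midline_pca,
    "moments": midline_moments,
    "ellipse": midline_ellipse,
}
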