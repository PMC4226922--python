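"""Non-linear 2D B-spline registration with SSD and NGF similarity.

The transform is a cubic-B-spline displacement field optimized coarse to
fine over a multi-resolution pyramid, with a second-order (bending-energy)
regularizer. Two optimizers honour the configured breaking conditions: a
limited-memory quasi-Newton (L-BFGS-B) and a backtracking gradient-descent
used by the quasi-periodic pipeline.

All gradients are analytic (image sampling via exact tensor-spline
derivatives; penalty via the adjoint of its finite-difference stencils) and
are checked against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from scipy.optimize import minimize

from .errors import PerfmocoError
from .transforms import TransformField, basis_matrix, n_knots_for

__all__ = [
    "RegistrationConfig",
    "ssd",
    "ngf",
    "curvature_penalty",
    "register",
    "apply_transform",
]


@dataclass
class RegistrationConfig:
    measure: str = "ssd"            # 'ssd' | 'ngf'
    kappa: float = 10.0             # regularization weight
    knot_spacing: float = 16.0      # px at working resolution
    working_scale: float = 1.0      # image pre-scale factor
    levels: int = 3                 # multi-resolution levels
    optimizer: str = "lbfgs"        # 'lbfgs' | 'gd'
    max_iter: int = 300
    x_tol: float = 1e-3
    f_tol: float = 1e-3
    gd_start_step: float = 0.01
    gd_epsilon: float = 0.01
    ngf_eta: float | None = None    # None -> noise estimate per image
    #: bound on knot coefficients (working-resolution px). The cubic
    #: B-spline basis is a partition of unity, so this also bounds the
    #: displacement; it keeps the field physical where the image is flat
    #: and the similarity term has no signal.
    max_displacement_px: float | None = 12.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.levels < 1:
            raise ValueError("need at least one resolution level")
        if self.measure not in ("ssd", "ngf"):
            raise ValueError(f"unknown measure {self.measure!r}")


# ---------------------------------------------------------------------------
# Similarity measures (image-pair form, used directly by subset selection)
# ---------------------------------------------------------------------------

def ssd(moving: np.ndarray, reference: np.ndarray) -> float:
    """0.5 * mean squared intensity difference."""
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("image shapes differ")
    diff = moving - reference
    return 0.5 * float(np.mean(diff * diff))


def estimate_eta(image: np.ndarray) -> float:
    """Noise scale for NGF, tied to the image's edge strength.

    Half the 90th percentile of the gradient magnitude: gradients well
    below real edges (noise in flat regions) are damped, edges keep unit
    normalized length.
    """
    gr, gc = np.gradient(np.asarray(image, dtype=float))
    mag = np.hypot(gr, gc)
    return float(max(0.5 * np.percentile(mag, 90), 1e-6))


def _ngf_fields(image: np.ndarray, eta: float):
    gr, gc = np.gradient(np.asarray(image, dtype=float))
    rho = np.sqrt(gr * gr + gc * gc + eta * eta)
    return gr, gc, rho


def ngf(moving: np.ndarray, reference: np.ndarray, eta: float | None = None) -> float:
    """Normalized-gradient-field distance, insensitive to monotone
    intensity rescaling; 0 when gradients align everywhere.

    d(x) = (g_m . g_r + eta_m * eta_r) / (rho_m * rho_r); cost = mean(1 - d^2).
    ``eta`` overrides the per-image noise estimate for both images.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("image shapes differ")
    eta_m = eta if eta is not None else estimate_eta(moving)
    eta_r = eta if eta is not None else estimate_eta(reference)
    gmr, gmc, rho_m = _ngf_fields(moving, eta_m)
    grr, grc, rho_r = _ngf_fields(reference, eta_r)
    d = (gmr * grr + gmc * grc + eta_m * eta_r) / (rho_m * rho_r)
    return float(np.mean(1.0 - d * d))


# ---------------------------------------------------------------------------
# Regularizer
# ---------------------------------------------------------------------------

def _second_diffs(u: np.ndarray):
    urr = u[:-2, :] - 2.0 * u[1:-1, :] + u[2:, :]
    ucc = u[:, :-2] - 2.0 * u[:, 1:-1] + u[:, 2:]
    urc = u[1:, 1:] - u[1:, :-1] - u[:-1, 1:] + u[:-1, :-1]
    return urr, ucc, urc

def _second_diffs_adjoint(urr, ucc, urc, shape):
    g = np.zeros(shape)
    g[:-2, :] += urr
    g[1:-1, :] -= 2.0 * urr
    g[2:, :] += urr
    g[:, :-2] += ucc
    g[:, 1:-1] -= 2.0 * ucc
    g[:, 2:] += ucc
    g[1:, 1:] += urc
    g[1:, :-1] -= urc
    g[:-1, 1:] -= urc
    g[:-1, :-1] += urc
    return g


def curvature_penalty(field: np.ndarray, with_gradient: bool = False):
    """Discrete bending energy of a displacement field (2, rows, cols).

    Zero for any affine displacement (constant and linear parts lie in the
    stencils' null space). Returns the scalar energy, plus its gradient
    with respect to the field when requested.
    """
    field = np.asarray(field, dtype=float)
    n = field[0].size
    cost = 0.0
    grad = np.zeros_like(field) if with_gradient else None
    for d in range(2):
        urr, ucc, urc = _second_diffs(field[d])
        cost += (np.sum(urr * urr) + np.sum(ucc * ucc) + 2.0 * np.sum(urc * urc)) / n
        if with_gradient:
            grad[d] = _second_diffs_adjoint(2.0 * urr / n, 2.0 * ucc / n,
                                            4.0 * urc / n, field[d].shape)
    return (cost, grad) if with_gradient else cost


# ---------------------------------------------------------------------------
# Cost functions on knot coefficients
# ---------------------------------------------------------------------------

class _LevelProblem:
    """SSD or NGF + curvature cost over knot coefficients at one level.

    ``br``/``bc`` map knot coefficients to a displacement sampled on this
    level's pixel grid (values in working-resolution pixels); ``axis_scale``
    converts them into level pixels.
    """

    def __init__(self, moving, reference, br, bc, axis_scale, kappa,
                 measure="ssd", eta=None):
        self.reference = np.asarray(reference, dtype=float)
        self.moving = np.asarray(moving, dtype=float)
        self.br, self.bc = br, bc
        self.sr, self.sc = axis_scale
        self.kappa = kappa
        self.measure = measure
        nr, nc = self.moving.shape
        self.spline = RectBivariateSpline(
            np.arange(nr), np.arange(nc), self.moving, kx=3, ky=3, s=0
        )
        self.grid_r, self.grid_c = np.meshgrid(
            np.arange(nr, dtype=float), np.arange(nc, dtype=float), indexing="ij"
        )
        if measure == "ngf":
            eta_r = eta if eta is not None else estimate_eta(self.reference)
            self.eta_m = eta if eta is not None else estimate_eta(self.moving)
            grr, grc, rho_r = _ngf_fields(self.reference, eta_r)
            self.ref_nr = grr / rho_r
            self.ref_nc = grc / rho_r
            self.ref_ne = eta_r / rho_r

    def _warp(self, coeffs):
        ur = (self.br @ coeffs[0] @ self.bc.T) * self.sr
        uc = (self.br @ coeffs[1] @ self.bc.T) * self.sc
        rr = self.grid_r + ur
        cc = self.grid_c + uc
        nr, nc = self.moving.shape
        rrc = np.clip(rr, 0.0, nr - 1.0)
        ccc = np.clip(cc, 0.0, nc - 1.0)
        inside_r = (rr == rrc).astype(float)
        inside_c = (cc == ccc).astype(float)
        warped = self.spline.ev(rrc, ccc)
        return warped, rrc, ccc, inside_r, inside_c

    def cost_and_grad(self, flat_coeffs):
        shape = (2, self.br.shape[1], self.bc.shape[1])
        coeffs = flat_coeffs.reshape(shape)
        warped, rrc, ccc, inside_r, inside_c = self._warp(coeffs)
        n = warped.size

        if self.measure == "ssd":
            res = warped - self.reference
            sim_cost = 0.5 * float(np.sum(res * res)) / n
            d_warped = res / n
        else:
            sim_cost, d_warped = self._ngf_cost(warped)

        # chain to displacement via the moving image's spline derivatives
        gr_img = self.spline.ev(rrc, ccc, dx=1, dy=0) * inside_r
        gc_img = self.spline.ev(rrc, ccc, dx=0, dy=1) * inside_c
        g_ur = d_warped * gr_img * self.sr
        g_uc = d_warped * gc_img * self.sc
        grad = np.empty(shape)
        grad[0] = self.br.T @ g_ur @ self.bc
        grad[1] = self.br.T @ g_uc @ self.bc

        cost = sim_cost
        if self.kappa > 0:
            field = np.stack(
                [(self.br @ coeffs[0] @ self.bc.T) * self.sr,
                 (self.br @ coeffs[1] @ self.bc.T) * self.sc]
            )
            p_cost, p_grad = curvature_penalty(field, with_gradient=True)
            cost += self.kappa * p_cost
            grad[0] += self.kappa * self.sr * (self.br.T @ p_grad[0] @ self.bc)
            grad[1] += self.kappa * self.sc * (self.br.T @ p_grad[1] @ self.bc)
        if not np.isfinite(cost):
            raise PerfmocoError(
                f"non-finite registration cost (measure={self.measure}, "
                f"max|coeff|={np.abs(coeffs).max():.3g})"
            )
        return cost, grad.ravel()

    def _ngf_cost(self, warped):
        """NGF cost and its gradient w.r.t. the warped image."""
        n = warped.size
        gr, gc = np.gradient(warped)
        rho = np.sqrt(gr * gr + gc * gc + self.eta_m * self.eta_m)
        d = (gr * self.ref_nr + gc * self.ref_nc + self.eta_m * self.ref_ne) / rho
        cost = float(np.mean(1.0 - d * d))
        # d cost/d g = -2 d/n * (h - d * g / rho) / rho, h = (ref_nr, ref_nc)
        common = -2.0 * d / (n * rho)
        dgr = common * (self.ref_nr - d * gr / rho)
        dgc = common * (self.ref_nc - d * gc / rho)
        return cost, _gradient_adjoint(dgr, dgc)


def _gradient_adjoint(dgr, dgc):
    """Adjoint of np.gradient (central differences, one-sided borders)."""
    out = np.zeros_like(dgr)
    # axis 0
    a = dgr
    out[0, :] += -a[0, :]
    out[1, :] += a[0, :]
    out[-2, :] += -a[-1, :]
    out[-1, :] += a[-1, :]
    out[:-2, :] += -0.5 * a[1:-1, :]
    out[2:, :] += 0.5 * a[1:-1, :]
    # axis 1
    a = dgc
    out[:, 0] += -a[:, 0]
    out[:, 1] += a[:, 0]
    out[:, -2] += -a[:, -1]
    out[:, -1] += a[:, -1]
    out[:, :-2] += -0.5 * a[:, 1:-1]
    out[:, 2:] += 0.5 * a[:, 1:-1]
    return out


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

def _optimize_lbfgs(problem, x0, config):
    bounds = None
    if config.max_displacement_px is not None:
        b = config.max_displacement_px
        bounds = [(-b, b)] * x0.size
    result = minimize(
        problem.cost_and_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": config.max_iter,
            "ftol": config.f_tol,
            "gtol": 1e-12,
            "maxcor": 10,
        },
    )
    f0 = problem.cost_and_grad(x0)[0]
    return result.x if result.fun <= f0 else x0


def _optimize_gd(problem, x0, config):
    """Adaptive-step gradient descent on the infinity-normalized gradient.

    The step (maximum coefficient change per iteration) starts at
    ``gd_start_step``, doubles after an accepted step and halves after a
    rejected one; optimization stops once the step drops below
    ``gd_epsilon`` or the iteration budget is exhausted.
    """
    x = x0.copy()
    cost, grad = problem.cost_and_grad(x)
    step = config.gd_start_step
    for _ in range(config.max_iter):
        gmax = np.abs(grad).max()
        if gmax == 0:
            break
        trial = x - step * grad / gmax
        if config.max_displacement_px is not None:
            np.clip(trial, -config.max_displacement_px,
                    config.max_displacement_px, out=trial)
        t_cost, t_grad = problem.cost_and_grad(trial)
        if t_cost < cost:
            x, cost, grad = trial, t_cost, t_grad
            step *= 2.0
        else:
            step *= 0.5
            if step < config.gd_epsilon:
                break
    return x


# ---------------------------------------------------------------------------
# Multi-resolution driver
# ---------------------------------------------------------------------------

def _resample(image, shape):
    zoom = (shape[0] / image.shape[0], shape[1] / image.shape[1])
    if min(zoom) < 1.0:       # antialias before downsampling
        sigma = [max(np.sqrt((1.0 / z) ** 2 - 1.0) / 2.0, 0.0) for z in zoom]
        image = ndimage.gaussian_filter(image, sigma)
    return ndimage.zoom(image, zoom, order=1, mode="nearest")


def register(
    moving: np.ndarray,
    reference: np.ndarray,
    config: RegistrationConfig | None = None,
) -> TransformField:
    """Register ``moving`` to ``reference``; returns the optimized field.

    Images are pre-scaled by ``working_scale``; knot spacing applies at
    that resolution. Optimization runs coarse to fine over
    ``config.levels`` pyramid levels sharing one knot grid. The result
    never has a higher cost than the identity transform (descent contract).
    """
    config = config or RegistrationConfig()
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError("image shapes differ")
    domain_shape = moving.shape

    ws = config.working_scale
    if ws != 1.0:
        work_shape = tuple(max(int(round(s * ws)), 8) for s in domain_shape)
        moving_w = _resample(moving, work_shape)
        reference_w = _resample(reference, work_shape)
    else:
        work_shape = domain_shape
        moving_w, reference_w = moving, reference

    kr = n_knots_for(work_shape[0], config.knot_spacing)
    kc = n_knots_for(work_shape[1], config.knot_spacing)
    coeffs = np.zeros((2, kr, kc))

    for level in range(config.levels - 1, -1, -1):
        factor = 0.5 ** level
        shape_l = tuple(max(int(round(s * factor)), 8) for s in work_shape)
        mov_l = _resample(moving_w, shape_l) if shape_l != work_shape else moving_w
        ref_l = _resample(reference_w, shape_l) if shape_l != work_shape else reference_w
        sr = shape_l[0] / work_shape[0]
        sc = shape_l[1] / work_shape[1]
        br = basis_matrix(np.arange(shape_l[0]) / sr, config.knot_spacing, kr)
        bc = basis_matrix(np.arange(shape_l[1]) / sc, config.knot_spacing, kc)
        problem = _LevelProblem(
            mov_l, ref_l, br, bc, (sr, sc), config.kappa,
            measure=config.measure, eta=config.ngf_eta,
        )
        x0 = coeffs.ravel()
        if config.optimizer == "gd":
            x = _optimize_gd(problem, x0, config)
        else:
            x = _optimize_lbfgs(problem, x0, config)
        coeffs = x.reshape(coeffs.shape)

    return TransformField(
        domain_shape,
        knot_coefficients=coeffs,
        knot_spacing=config.knot_spacing,
        working_shape=work_shape,
        working_scale=ws,
    )


def apply_transform(transform: TransformField, target, kind: str | None = None):
    """Apply a transform to an image, mask, or point array.

    ``kind`` is inferred when omitted: boolean arrays are warped as masks
    (nearest neighbour; may come back empty), (n, 2) float arrays as
    points, everything else as images (cubic interpolation).
    """
    target = np.asarray(target)
    if kind is None:
        if target.dtype == bool:
            kind = "mask"
        elif target.ndim == 2 and target.shape[1] == 2 and target.shape != transform.domain_shape:
            kind = "points"
        else:
            kind = "image"
    if kind == "image":
        return transform.apply_to_image(target)
    if kind == "mask":
        return transform.apply_to_mask(target)
    if kind == "points":
        return transform.apply_to_points(target)
    raise ValueError(f"unknown kind {kind!r}")
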