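"""2D displacement fields: dense or cubic-B-spline parameterized.

A :class:`TransformField` maps output-grid coordinates ``x`` to sampling
coordinates ``x + u(x)`` (pull-back convention): warping an image samples
the input at ``x + u(x)``, and applying the transform to a point returns
``p + u(p)``.

B-spline fields store a knot-coefficient grid defined on a *working*
resolution (``working_scale`` times the full domain); displacements are in
working-resolution pixels and are rescaled on evaluation.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import ndimage


def bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support (-2, 2)."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1.0
    m2 = (t >= 1.0) & (t < 2.0)
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


def n_knots_for(length: int, spacing: float) -> int:
    """Knot count covering ``length`` samples at ``spacing`` px per knot."""
    return int(np.ceil((length - 1) / spacing)) + 3


def basis_matrix(coords: np.ndarray, spacing: float, n_knots: int) -> np.ndarray:
    """Rows: evaluation coordinates; columns: cubic B-spline knot functions.

    Knot ``k`` sits at position ``(k - 1) * spacing`` so the spline support
    covers the domain with one margin knot at each side.
    """
    coords = np.asarray(coords, dtype=float)
    k = np.arange(n_knots)
    return bspline3(coords[:, None] / spacing - (k[None, :] - 1.0))


class TransformField:
    """A dense or B-spline 2D displacement on a fixed domain."""

    def __init__(
        self,
        domain_shape: tuple[int, int],
        *,
        knot_coefficients: np.ndarray | None = None,
        knot_spacing: float | None = None,
        working_shape: tuple[int, int] | None = None,
        working_scale: float = 1.0,
        dense: np.ndarray | None = None,
    ):
        self.domain_shape = tuple(int(v) for v in domain_shape)
        self.working_scale = float(working_scale)
        if (dense is None) == (knot_coefficients is None):
            raise ValueError("provide exactly one of dense / knot_coefficients")
        if dense is not None:
            dense = np.asarray(dense, dtype=float)
            if dense.shape != (2, *self.domain_shape):
                raise ValueError("dense field must have shape (2, rows, cols)")
            self.dense = dense
            self.knot_coefficients = None
            self.knot_spacing = None
            self.working_shape = self.domain_shape
        else:
            self.dense = None
            self.knot_coefficients = np.asarray(knot_coefficients, dtype=float)
            if self.knot_coefficients.ndim != 3 or self.knot_coefficients.shape[0] != 2:
                raise ValueError("knot coefficients must have shape (2, Kr, Kc)")
            self.knot_spacing = float(knot_spacing)
            if working_shape is None:
                working_shape = tuple(
                    max(int(round(s * self.working_scale)), 4) for s in self.domain_shape
                )
            self.working_shape = tuple(int(v) for v in working_shape)

    # -- constructors ------------------------------------------------------

    @classmethod
    def identity(cls, domain_shape) -> "TransformField":
        return cls(domain_shape, dense=np.zeros((2, *domain_shape)))

    @classmethod
    def from_dense(cls, displacement: np.ndarray) -> "TransformField":
        displacement = np.asarray(displacement, dtype=float)
        return cls(displacement.shape[1:], dense=displacement)

    @classmethod
    def translation(cls, domain_shape, d_row: float, d_col: float) -> "TransformField":
        dense = np.zeros((2, *domain_shape))
        dense[0] += d_row
        dense[1] += d_col
        return cls(domain_shape, dense=dense)

    # -- evaluation --------------------------------------------------------

    def displacement(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Dense displacement (2, rows, cols) in target-grid pixel units."""
        if shape is None:
            shape = self.domain_shape
        shape = tuple(int(v) for v in shape)
        if self.dense is not None:
            if shape == self.domain_shape:
                return self.dense.copy()
            zr = shape[0] / self.domain_shape[0]
            zc = shape[1] / self.domain_shape[1]
            out = np.stack(
                [ndimage.zoom(self.dense[d], (zr, zc), order=1, mode="nearest")
                 for d in range(2)]
            )
            out[0] *= zr
            out[1] *= zc
            return out
        # B-spline: evaluate basis at working coordinates of target pixels
        sr = self.working_shape[0] / shape[0]
        sc = self.working_shape[1] / shape[1]
        br = basis_matrix(np.arange(shape[0]) * sr, self.knot_spacing,
                          self.knot_coefficients.shape[1])
        bc = basis_matrix(np.arange(shape[1]) * sc, self.knot_spacing,
                          self.knot_coefficients.shape[2])
        out = np.stack([br @ self.knot_coefficients[d] @ bc.T for d in range(2)])
        out[0] /= sr  # working px -> target px
        out[1] /= sc
        return out

    def max_displacement(self) -> float:
        u = self.displacement()
        return float(np.max(np.hypot(u[0], u[1]))) if u.size else 0.0

    # -- application -------------------------------------------------------

    def _sample_coords(self, shape):
        u = self.displacement(shape)
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        return rr + u[0], cc + u[1]

    def apply_to_image(self, image: np.ndarray, order: int = 3) -> np.ndarray:
        """Warp an image by spline interpolation (constant border)."""
        image = np.asarray(image, dtype=float)
        rr, cc = self._sample_coords(image.shape)
        return ndimage.map_coordinates(image, [rr, cc], order=order, mode="nearest")

    def apply_to_mask(self, mask: np.ndarray) -> np.ndarray:
        """Warp a binary mask with nearest-neighbour sampling.

        The result may be empty (a valid, caller-checked outcome).
        """
        mask = np.asarray(mask)
        rr, cc = self._sample_coords(mask.shape)
        out = ndimage.map_coordinates(
            mask.astype(np.uint8), [rr, cc], order=0, mode="constant", cval=0
        )
        return out.astype(bool)

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        """Map points (n, 2) of (row, col) to ``p + u(p)``."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        u = self.displacement()
        ur = ndimage.map_coordinates(u[0], points.T, order=1, mode="nearest")
        uc = ndimage.map_coordinates(u[1], points.T, order=1, mode="nearest")
        return points + np.column_stack([ur, uc])

    # -- algebra -----------------------------------------------------------

    def compose_after(self, previous: "TransformField") -> "TransformField":
        """Transform equivalent to applying ``previous`` then ``self``.

        In pull-back convention: warping the original image by the result
        equals warping by ``previous`` first and the warped image by
        ``self`` afterwards, i.e. ``u(x) = u_self(x) + u_prev(x + u_self(x))``.
        """
        u_new = self.displacement(self.domain_shape)
        u_prev = previous.displacement(self.domain_shape)
        rr, cc = np.meshgrid(
            np.arange(self.domain_shape[0]), np.arange(self.domain_shape[1]), indexing="ij"
        )
        sr, sc = rr + u_new[0], cc + u_new[1]
        total = np.stack(
            [
                u_new[0] + ndimage.map_coordinates(u_prev[0], [sr, sc], order=1, mode="nearest"),
                u_new[1] + ndimage.map_coordinates(u_prev[1], [sr, sc], order=1, mode="nearest"),
            ]
        )
        return TransformField(self.domain_shape, dense=total)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        if self.dense is not None:
            return {
                "kind": "dense",
                "domain_shape": list(self.domain_shape),
                "displacement": self.dense.tolist(),
            }
        return {
            "kind": "bspline",
            "domain_shape": list(self.domain_shape),
            "working_shape": list(self.working_shape),
            "working_scale": self.working_scale,
            "knot_spacing": self.knot_spacing,
            "knot_coefficients": self.knot_coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TransformField":
        if data["kind"] == "dense":
            return cls(tuple(data["domain_shape"]),
                       dense=np.asarray(data["displacement"]))
        return cls(
            tuple(data["domain_shape"]),
            knot_coefficients=np.asarray(data["knot_coefficients"]),
            knot_spacing=data["knot_spacing"],
            working_shape=tuple(data["working_shape"]),
            working_scale=data.get("working_scale", 1.0),
        )

    def save(self, path: str):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "TransformField":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
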