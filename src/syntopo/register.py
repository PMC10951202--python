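"""Section-to-atlas registration: landmark affine fit plus exact-interpolating
anchor refinement, and mapping of detected cells into atlas coordinates.

The registration geometry mirrors the manual plate-alignment workflow used for
section quantification: a linear (affine) alignment fitted from corresponding
landmark points, refined by anchor points that the composite warp must map
exactly onto their targets. Intensity-based automatic registration is out of
scope — landmarks and anchors are inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RBFInterpolator

from .atlas import AtlasPlate


class RegistrationError(ValueError):
    pass


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean pooling over ``factor`` × ``factor`` tiles.

    Trailing partial blocks are averaged over the pixels they actually
    contain, so output shape is ``ceil(shape / factor)`` and a constant image
    stays constant. Block means (not decimation) preserve intensity
    statistics at the reduced scale.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return np.asarray(image, dtype=float).copy()
    img = np.asarray(image, dtype=float)
    rows, cols = img.shape
    ridx = np.arange(0, rows, factor)
    cidx = np.arange(0, cols, factor)
    sums = np.add.reduceat(np.add.reduceat(img, ridx, axis=0), cidx, axis=1)
    rcount = np.diff(np.append(ridx, rows))
    ccount = np.diff(np.append(cidx, cols))
    return sums / np.outer(rcount, ccount)


def fit_affine_from_landmarks(
    src: np.ndarray, dst: np.ndarray
) -> np.ndarray:
    """Least-squares 2×3 affine mapping source points onto target points.

    Exact when the pairs are affine-consistent. Raises
    :class:`RegistrationError` for fewer than 3 pairs or a collinear /
    degenerate source configuration (no silent pseudo-solution).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise RegistrationError("src and dst must both be (n, 2) point arrays")
    n = src.shape[0]
    if n < 3:
        raise RegistrationError("need at least 3 landmark pairs")
    design = np.column_stack([src, np.ones(n)])
    # collinear sources make the 3-column design rank-deficient
    scale = max(1.0, float(np.abs(src).max()))
    if np.linalg.matrix_rank(design, tol=1e-9 * scale * n) < 3:
        raise RegistrationError("degenerate (collinear) landmark configuration")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return coef.T  # 2x3: [[a, b, tx], [c, d, ty]]


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts @ np.asarray(matrix)[:, :2].T + np.asarray(matrix)[:, 2]


class DisplacementField:
    """Exact-interpolating 2D displacement field over scattered nodes.

    Thin-plate-spline interpolation (zero smoothing: nodes are reproduced
    exactly) when at least 3 non-collinear nodes are given; with 1–2 nodes a
    TPS is underdetermined, so a Gaussian-kernel interpolant is used instead —
    still exact at the nodes, with displacements that decay away from them.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        displacements: np.ndarray,
        gaussian_scale: float = 64.0,
    ):
        self.nodes = np.atleast_2d(np.asarray(nodes, dtype=float))
        self.displacements = np.atleast_2d(np.asarray(displacements, dtype=float))
        if self.nodes.shape != self.displacements.shape:
            raise RegistrationError("nodes and displacements must match in shape")
        uniq, counts = np.unique(self.nodes, axis=0, return_counts=True)
        if (counts > 1).any():
            # duplicate sources are only legal if their displacements agree
            for node in uniq[counts > 1]:
                sel = np.all(self.nodes == node, axis=1)
                if not np.allclose(
                    self.displacements[sel], self.displacements[sel][0]
                ):
                    raise RegistrationError(
                        f"duplicate anchor source {node.tolist()} with "
                        "conflicting targets"
                    )
            keep = np.sort(np.unique(self.nodes, axis=0, return_index=True)[1])
            self.nodes = self.nodes[keep]
            self.displacements = self.displacements[keep]
        n = self.nodes.shape[0]
        rank = np.linalg.matrix_rank(
            np.column_stack([self.nodes, np.ones(n)]), tol=1e-9
        )
        if n >= 3 and rank == 3:
            self.kind = "thin_plate_spline"
            self._rbf = RBFInterpolator(
                self.nodes, self.displacements, kernel="thin_plate_spline", smoothing=0.0
            )
        else:
            self.kind = "gaussian"
            self._scale = float(gaussian_scale)
            K = self._gauss_kernel(self.nodes, self.nodes)
            # jitter-free solve: K is symmetric positive definite for distinct nodes
            self._weights = np.linalg.solve(K, self.displacements)

    def _gauss_kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-d2 / (2.0 * self._scale**2))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "thin_plate_spline":
            return self._rbf(pts)
        return self._gauss_kernel(pts, self.nodes) @ self._weights


@dataclass
class SectionRegistration:
    """Composite warp: section pixel coordinates → atlas pixel coordinates.

    ``warp(p) = affine(p) + D(p)`` where ``D`` interpolates the anchor
    residuals ``target − affine(source)`` at the anchor sources, so every
    anchor source maps exactly to its target. With no anchors the warp is
    the affine alone.
    """

    linear: np.ndarray
    anchors_src: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    anchors_dst: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    downsample_factor: int = 1
    _field: DisplacementField | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        if self.linear.shape != (2, 3):
            raise RegistrationError("linear part must be a 2x3 matrix")
        if abs(np.linalg.det(self.linear[:, :2])) < 1e-12:
            raise RegistrationError("affine 2x2 part is singular")
        self.anchors_src = np.asarray(self.anchors_src, dtype=float).reshape(-1, 2)
        self.anchors_dst = np.asarray(self.anchors_dst, dtype=float).reshape(-1, 2)
        if self.anchors_src.shape != self.anchors_dst.shape:
            raise RegistrationError("anchor source/target counts differ")
        if len(self.anchors_src) and self._field is None:
            residuals = self.anchors_dst - apply_affine(self.linear, self.anchors_src)
            self._field = DisplacementField(self.anchors_src, residuals)

    @property
    def nonlinear_kind(self) -> str:
        return "none" if self._field is None else self._field.kind

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = apply_affine(self.linear, pts)
        if self._field is not None:
            out = out + self._field(pts)
        return out

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "linear": self.linear.tolist(),
            "anchors": [
                {"src": s.tolist(), "dst": d.tolist()}
                for s, d in zip(self.anchors_src, self.anchors_dst)
            ],
            "nonlinear_kind": self.nonlinear_kind,
            "downsample_factor": self.downsample_factor,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1))
        return payload

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SectionRegistration":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        anchors = source.get("anchors", [])
        return cls(
            linear=np.asarray(source["linear"], dtype=float),
            anchors_src=np.asarray([a["src"] for a in anchors], dtype=float).reshape(
                -1, 2
            ),
            anchors_dst=np.asarray([a["dst"] for a in anchors], dtype=float).reshape(
                -1, 2
            ),
            downsample_factor=int(source.get("downsample_factor", 1)),
        )


def refine_with_anchors(
    linear: np.ndarray, anchors: list[tuple] | np.ndarray
) -> SectionRegistration:
    """Refine an affine with anchor pairs ``(source, target)``.

    The composite warp interpolates the anchor residuals exactly (zero
    regularization); with an empty anchor list it reduces to the affine.
    """
    if anchors is None or len(anchors) == 0:
        return SectionRegistration(linear=np.asarray(linear, dtype=float))
    src = np.asarray([a[0] for a in anchors], dtype=float)
    dst = np.asarray([a[1] for a in anchors], dtype=float)
    return SectionRegistration(linear=np.asarray(linear, dtype=float),
                               anchors_src=src, anchors_dst=dst)


def rescale_affine(matrix: np.ndarray, factor: int) -> np.ndarray:
    """Lift an affine fitted at ``factor``-fold downsampled scale to full
    resolution (linear part unchanged, translation scaled)."""
    out = np.asarray(matrix, dtype=float).copy()
    out[:, 2] *= factor
    return out


def load_landmarks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read ``{"pairs": [{"src": [x, y], "dst": [x, y]}, ...]}``."""
    data = json.loads(Path(path).read_text())
    pairs = data["pairs"]
    src = np.asarray([p["src"] for p in pairs], dtype=float)
    dst = np.asarray([p["dst"] for p in pairs], dtype=float)
    return src, dst


def save_landmarks(src: np.ndarray, dst: np.ndarray, path: str | Path) -> None:
    pairs = [
        {"src": [float(a), float(b)], "dst": [float(c), float(d)]}
        for (a, b), (c, d) in zip(np.asarray(src), np.asarray(dst))
    ]
    Path(path).write_text(json.dumps({"pairs": pairs}, indent=1))


def map_cells_to_atlas(cells, registration: SectionRegistration, atlas: AtlasPlate):
    """Warp cell centroids into atlas coordinates and look up the region label
    at the nearest pixel.

    Cells landing outside the plate (or on label 0) get ``region_id`` 0 and
    are flagged ``unassigned`` — retained, never dropped. Returns the same
    cell container with ``region_id``/``unassigned`` columns set.
    """
    df = cells.df if hasattr(cells, "df") else cells
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if len(pts):
        warped = registration.transform_points(pts)
        cols = np.rint(warped[:, 0]).astype(int)
        rows = np.rint(warped[:, 1]).astype(int)
        inside = (
            (rows >= 0)
            & (rows < atlas.labels.shape[0])
            & (cols >= 0)
            & (cols < atlas.labels.shape[1])
        )
        region = np.zeros(len(pts), dtype=int)
        region[inside] = atlas.labels[rows[inside], cols[inside]]
        df["atlas_x"] = warped[:, 0]
        df["atlas_y"] = warped[:, 1]
    else:
        region = np.zeros(0, dtype=int)
        df["atlas_x"] = np.empty(0)
        df["atlas_y"] = np.empty(0)
    df["region_id"] = region
    df["unassigned"] = region == 0
    return cells
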