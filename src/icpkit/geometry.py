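"""Channel geometry and structured rectilinear meshing.

The simulated device is a shallow straight microchannel (default
1 cm x 17 um) with a cation-permselective membrane printed as a band on
the *top* wall (default 400 um x 6 um, centred in x).  The coordinate
convention is x in [0, L] with the anodic inlet at x = 0, and
y in [0, H] with y = 0 the polystyrene bottom wall; the membrane
occupies the band y in [H - t_m, H].

Meshes are structured and rectilinear.  Cell faces are always placed
exactly on the membrane edges and on the membrane bottom interface, so
membrane cells tile the membrane rectangle exactly and tagging is a pure
point-in-rectangle test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised when geometric dimensions violate an invariant."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Validated channel/membrane geometry (SI units, metres).

    The membrane is attached to the top wall and must be strictly
    thinner than the channel and fully inside the channel x-extent.
    """

    channel_length: float = 1.0e-2
    channel_height: float = 17.0e-6
    membrane_length: float = 400.0e-6
    membrane_thickness: float = 6.0e-6
    membrane_x_center: float = 0.5e-2

    def __post_init__(self) -> None:
        for name in (
            "channel_length",
            "channel_height",
            "membrane_length",
            "membrane_thickness",
        ):
            if getattr(self, name) <= 0.0:
                raise GeometryError(f"DeviceGeometry.{name} must be positive")
        if self.membrane_thickness >= self.channel_height:
            raise GeometryError(
                "membrane_thickness must be strictly less than channel_height "
                f"({self.membrane_thickness:g} >= {self.channel_height:g})"
            )
        x_lo, x_hi = self.membrane_x_extent
        if x_lo <= 0.0 or x_hi >= self.channel_length:
            raise GeometryError(
                "membrane must lie strictly inside the channel x-extent: "
                f"[{x_lo:g}, {x_hi:g}] vs [0, {self.channel_length:g}]"
            )

    @property
    def membrane_x_extent(self) -> tuple[float, float]:
        half = 0.5 * self.membrane_length
        return (self.membrane_x_center - half, self.membrane_x_center + half)

    @property
    def interface_y(self) -> float:
        """Height of the membrane bottom surface above the channel floor."""
        return self.channel_height - self.membrane_thickness


def build_geometry(config: dict | None = None, **kwargs: float) -> DeviceGeometry:
    """Build a validated :class:`DeviceGeometry` from a parameter mapping.

    Unknown keys are rejected.  With no arguments the defaults reproduce
    the reference device: 1 cm x 17 um channel, 400 um x 6 um membrane
    centred in x.
    """
    params = dict(config or {})
    params.update(kwargs)
    valid = {f for f in DeviceGeometry.__dataclass_fields__}
    unknown = set(params) - valid
    if unknown:
        raise GeometryError(f"unknown geometry keys: {sorted(unknown)}")
    if "membrane_x_center" not in params and "channel_length" in params:
        params["membrane_x_center"] = 0.5 * float(params["channel_length"])
    return DeviceGeometry(**{k: float(v) for k, v in params.items()})


def _geometric_segment(length: float, n: int, ratio: float, refine: str) -> np.ndarray:
    """Cell widths of a geometric grading over one segment.

    ``refine`` picks where the fine cells sit: "left", "right", "both"
    (fine at both ends, coarse in the middle is *not* what we want here -
    "both" refines towards both ends symmetrically) or "none".
    Widths are rescaled so they sum exactly to ``length``; rescaling
    preserves the adjacent-cell ratio.
    """
    if n < 1:
        raise GeometryError("segment needs at least one cell")
    if ratio < 1.0:
        raise GeometryError("grading ratio must be >= 1")
    if ratio == 1.0 or n == 1 or refine == "none":
        return np.full(n, length / n)
    if refine == "left":
        w = ratio ** np.arange(n, dtype=float)
    elif refine == "right":
        w = ratio ** np.arange(n - 1, -1, -1, dtype=float)
    elif refine == "both":
        half = n // 2
        left = ratio ** np.arange(half, dtype=float)
        right = left[::-1] if n % 2 == 0 else np.concatenate([[ratio ** half], left[::-1]])
        w = np.concatenate([left, right])
    else:  # pragma: no cover - internal misuse
        raise GeometryError(f"unknown refine mode {refine!r}")
    return w * (length / w.sum())


@dataclass(frozen=True)
class Mesh:
    """Structured rectilinear mesh with membrane-cell tagging.

    ``x_faces``/``y_faces`` are strictly increasing face coordinates in
    metres; ``membrane_mask`` is a boolean (ny, nx) array marking cells
    inside the membrane rectangle.
    """

    x_faces: np.ndarray
    y_faces: np.ndarray
    membrane_mask: np.ndarray
    geometry: DeviceGeometry | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for arr, name in ((self.x_faces, "x_faces"), (self.y_faces, "y_faces")):
            if np.any(np.diff(arr) <= 0.0):
                raise GeometryError(f"{name} must be strictly increasing (no zero-area cells)")
        if self.membrane_mask.shape != (self.ny, self.nx):
            raise GeometryError("membrane_mask shape must be (ny, nx)")

    @property
    def nx(self) -> int:
        return len(self.x_faces) - 1

    @property
    def ny(self) -> int:
        return len(self.y_faces) - 1

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_faces)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_faces)

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.x_faces[:-1] + self.x_faces[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.y_faces[:-1] + self.y_faces[1:])

    @property
    def cell_areas(self) -> np.ndarray:
        """(ny, nx) per-cell areas (unit depth), m^2."""
        return np.outer(self.dy, self.dx)

    @property
    def extent(self) -> tuple[float, float]:
        return (self.x_faces[-1] - self.x_faces[0], self.y_faces[-1] - self.y_faces[0])

    @classmethod
    def from_extents(
        cls,
        length: float,
        height: float,
        nx: int,
        ny: int,
        membrane_box: tuple[float, float, float, float] | None = None,
    ) -> "Mesh":
        """Uniform mesh over [0, length] x [0, height] with an optional
        explicit membrane rectangle (x_lo, x_hi, y_lo, y_hi).

        Used for oracle/test configurations (e.g. a quasi-1D channel with
        a membrane spanning the full outlet) that the device geometry
        type deliberately forbids.  Faces are snapped onto the membrane
        rectangle edges when a box is given.
        """
        xf = np.linspace(0.0, length, nx + 1)
        yf = np.linspace(0.0, height, ny + 1)
        if membrane_box is not None:
            x_lo, x_hi, y_lo, y_hi = membrane_box
            for v in (x_lo, x_hi):
                if 0.0 < v < length:
                    xf[np.argmin(np.abs(xf - v))] = v
            for v in (y_lo, y_hi):
                if 0.0 < v < height:
                    yf[np.argmin(np.abs(yf - v))] = v
        xc = 0.5 * (xf[:-1] + xf[1:])
        yc = 0.5 * (yf[:-1] + yf[1:])
        mask = np.zeros((ny, nx), dtype=bool)
        if membrane_box is not None:
            x_lo, x_hi, y_lo, y_hi = membrane_box
            mask = (
                (xc[None, :] > x_lo) & (xc[None, :] < x_hi)
                & (yc[:, None] > y_lo) & (yc[:, None] < y_hi)
            )
        return cls(x_faces=xf, y_faces=yf, membrane_mask=mask)


def build_mesh(
    geometry: DeviceGeometry,
    nx: int = 200,
    ny: int = 40,
    grading: float = 1.0,
) -> Mesh:
    """Mesh the channel with faces on the membrane edges.

    ``nx``/``ny`` are target cell counts per dimension (the realised
    counts may differ by the rounding needed to place faces exactly on
    the membrane rectangle).  ``grading`` >= 1 is the adjacent-cell width
    ratio of the geometric refinement: in x the side segments refine
    towards the membrane edges, in y the fluid band refines towards the
    bottom wall and the membrane interface.  ``grading`` == 1 gives
    uniform spacing.

    Requires at least 8 cells across the channel height and at least 2
    (defaults give >= 4) across the membrane thickness.
    """
    if ny < 8:
        raise GeometryError("need at least 8 cells across the channel height")
    L = geometry.channel_length
    H = geometry.channel_height
    x_lo, x_hi = geometry.membrane_x_extent
    t_m = geometry.membrane_thickness

    # --- x faces: [0, x_lo], [x_lo, x_hi], [x_hi, L] -------------------
    seg_len = np.array([x_lo, x_hi - x_lo, L - x_hi])
    counts = np.maximum(np.round(nx * seg_len / L).astype(int), 1)
    counts[1] = max(counts[1], 4)
    widths = [
        _geometric_segment(seg_len[0], counts[0], grading, "right"),
        _geometric_segment(seg_len[1], counts[1], 1.0, "none"),
        _geometric_segment(seg_len[2], counts[2], grading, "left"),
    ]
    xf = np.concatenate([[0.0], np.cumsum(np.concatenate(widths))])
    xf[-1] = L
    xf[counts[0]] = x_lo
    xf[counts[0] + counts[1]] = x_hi

    # --- y faces: fluid band [0, H - t_m], membrane band [H - t_m, H] --
    n_mem = int(round(ny * t_m / H))
    if n_mem < 2:
        raise GeometryError(
            "membrane thinner than 2 cells at this resolution; increase ny"
        )
    n_fluid = ny - n_mem
    if n_fluid < 4:
        raise GeometryError("need at least 4 cells below the membrane")
    w_fluid = _geometric_segment(H - t_m, n_fluid, grading, "both")
    w_mem = _geometric_segment(t_m, n_mem, 1.0, "none")
    yf = np.concatenate([[0.0], np.cumsum(np.concatenate([w_fluid, w_mem]))])
    yf[-1] = H
    yf[n_fluid] = H - t_m

    xc = 0.5 * (xf[:-1] + xf[1:])
    yc = 0.5 * (yf[:-1] + yf[1:])
    mask = (
        (xc[None, :] > x_lo) & (xc[None, :] < x_hi)
        & (yc[:, None] > H - t_m) & (yc[:, None] < H)
    )
    return Mesh(x_faces=xf, y_faces=yf, membrane_mask=mask, geometry=geometry)
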