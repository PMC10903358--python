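"""Simulated habitat landscapes and covariate lookup.

The habitat covariate is a scalar field ``Z`` on a regular grid over a
rectangular spatial domain.  For simulation studies the field is a draw from a
stationary zero-mean Gaussian random field with an exponential covariance
function ``Cov(d) = sigma^2 * exp(-d / range)``.  Because simulated animals are
kept on the domain by toroidal wrapping, the field is simulated directly on the
torus with an exact circulant (FFT) factorisation of its covariance: the field
is then stationary with respect to toroidal distance and continuous across the
domain edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GRFConfig",
    "CovariateField",
    "OutOfDomainError",
    "simulate_grf",
    "covariate_at",
    "read_grid",
    "write_grid",
]


class OutOfDomainError(ValueError):
    """A query point lies outside the spatial domain."""


@dataclass(frozen=True)
class GRFConfig:
    """Configuration of the Gaussian-random-field landscape.

    Parameters
    ----------
    nx, ny : int
        Grid dimensions in cells (x and y direction).
    variance : float
        Marginal variance sigma^2 of the field.
    corr_range : float
        Correlation range (distance at which the correlation has dropped to
        ``exp(-1)`` under the exponential model), in coordinate units.
    covariance_model : {"exponential", "gaussian"}
        Covariance family; the exponential model (Matern, smoothness 1/2) is
        the default.
    resolution : float
        Cell size in coordinate units.
    origin : (float, float)
        Coordinates of the lower-left grid corner.
    """

    nx: int = 100
    ny: int = 100
    variance: float = 1.0
    corr_range: float = 10.0
    covariance_model: str = "exponential"
    resolution: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2x2 cells")
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if self.corr_range <= 0:
            raise ValueError("corr_range must be > 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.covariance_model not in ("exponential", "gaussian"):
            raise ValueError(f"unknown covariance model {self.covariance_model!r}")


@dataclass
class CovariateField:
    """A gridded scalar habitat covariate over a rectangular domain.

    ``values[iy, ix]`` is the covariate of the cell whose centre is at
    ``origin + ((ix + 0.5) * resolution, (iy + 0.5) * resolution)``.  Lookup is
    nearest-cell (raster semantics).  The boundary policy decides what happens
    for points outside the domain: ``"wrap"`` maps them onto the torus,
    ``"error"`` raises :class:`OutOfDomainError`.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    resolution: float = 1.0
    boundary: str = "wrap"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("values must be a 2-D grid of at least 2x2 cells")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.boundary not in ("wrap", "error"):
            raise ValueError(f"unknown boundary policy {self.boundary!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # (ny, nx)

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the domain in coordinate units."""
        ny, nx = self.values.shape
        return nx * self.resolution, ny * self.resolution

    def value_at(self, points) -> np.ndarray:
        """Covariate value of the grid cell containing each point.

        Parameters
        ----------
        points : array-like, shape (n, 2)
            Continuous (x, y) coordinates.

        Returns
        -------
        ndarray, shape (n,)
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[-1] != 2:
            raise ValueError("points must have shape (n, 2)")
        ny, nx = self.values.shape
        ix = np.floor((pts[:, 0] - self.origin[0]) / self.resolution).astype(np.int64)
        iy = np.floor((pts[:, 1] - self.origin[1]) / self.resolution).astype(np.int64)
        if self.boundary == "wrap":
            ix %= nx
            iy %= ny
        else:
            bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
            if np.any(bad):
                j = int(np.flatnonzero(bad)[0])
                raise OutOfDomainError(
                    f"point ({pts[j, 0]:g}, {pts[j, 1]:g}) lies outside the domain"
                )
        return self.values[iy, ix]


def covariate_at(field: CovariateField, points) -> np.ndarray:
    """Functional alias for :meth:`CovariateField.value_at`."""
    return field.value_at(points)


def _toroidal_covariance_kernel(config: GRFConfig) -> np.ndarray:
    """First row of the circulant covariance on the (ny, nx) torus.

    The planar covariance function is periodized (summed over periodic
    images), which preserves positive semi-definiteness, and rescaled so the
    marginal variance is exactly sigma^2.
    """
    res = config.resolution
    lx, ly = config.nx * res, config.ny * res
    # enough images that the truncated tail is below 1e-14
    n_img = int(np.ceil(33.0 * config.corr_range / min(lx, ly)))
    if n_img > 60:
        raise ValueError(
            "correlation range is too large relative to the domain "
            f"({config.corr_range:g} vs extent {min(lx, ly):g})"
        )
    offs = np.arange(-n_img, n_img + 1)
    dx = (np.arange(config.nx)[:, None] * res + offs[None, :] * lx).ravel()  # (nx * I,)
    dy = (np.arange(config.ny)[:, None] * res + offs[None, :] * ly).ravel()
    d = np.hypot(dy[:, None], dx[None, :])
    if config.covariance_model == "exponential":
        rho = np.exp(-d / config.corr_range)
    else:  # gaussian
        rho = np.exp(-((d / config.corr_range) ** 2))
    n_off = offs.size
    kernel = rho.reshape(config.ny, n_off, config.nx, n_off).sum(axis=(1, 3))
    return config.variance * kernel / kernel[0, 0]


def simulate_grf(config: GRFConfig, seed: int | None = None) -> CovariateField:
    """Draw one realisation of the Gaussian-random-field landscape.

    The covariance is diagonalised by the 2-D discrete Fourier transform
    (block-circulant on the torus), so the draw is exact: the simulated field
    has covariance ``sigma^2 * exp(-d_torus / range)`` between cell centres.
    Deterministic for a fixed seed.
    """
    if config.variance == 0.0:
        values = np.zeros((config.ny, config.nx))
        return CovariateField(values, origin=config.origin, resolution=config.resolution)
    kernel = _toroidal_covariance_kernel(config)
    lam = np.fft.fft2(kernel).real
    if lam.min() < -1e-8 * lam.max():
        raise np.linalg.LinAlgError(
            "toroidal covariance is not positive semi-definite "
            f"(min eigenvalue {lam.min():.3e}); decrease the correlation range "
            "relative to the domain or enlarge the grid"
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((config.ny, config.nx))
    # real symmetric square root of the circulant covariance applied by FFT
    values = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real
    return CovariateField(values, origin=config.origin, resolution=config.resolution)


def write_grid(field: CovariateField, path) -> None:
    """Write a field to the plain-text grid format.

    Header line: ``nx ny origin_x origin_y resolution``; then ``ny`` rows of
    ``nx`` whitespace-separated values (row ``iy = 0`` first).
    """
    ny, nx = field.values.shape
    header = f"{nx} {ny} {field.origin[0]!r} {field.origin[1]!r} {field.resolution!r}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, field.values, fmt="%.17g")


def read_grid(path, boundary: str = "wrap") -> CovariateField:
    """Read a field from the plain-text grid format written by :func:`write_grid`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 5:
            raise ValueError(f"{path}: line 1: expected 'nx ny origin_x origin_y resolution'")
        try:
            nx, ny = int(header[0]), int(header[1])
            ox, oy, res = float(header[2]), float(header[3]), float(header[4])
        except ValueError as exc:
            raise ValueError(f"{path}: line 1: malformed header ({exc})") from None
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (ny, nx):
        raise ValueError(
            f"{path}: expected {ny} rows of {nx} values, got grid of shape {values.shape}"
        )
    return CovariateField(values, origin=(ox, oy), resolution=res, boundary=boundary)
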