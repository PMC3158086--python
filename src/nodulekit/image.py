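"""Image containers and TIFF/CSV serialization.

``CultureImage`` holds co-registered named intensity channels on a shared
pixel grid; ``HyperspectralCube`` holds a stack of planes indexed by
emission-band center. Both are plain in-memory containers with physical
pixel size attached; writers emit 16-bit grayscale TIFF (one page per
channel, channel name in the page description) so the files round-trip
through any standard reader.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "CultureImage",
    "HyperspectralCube",
    "STANDARD_BAND_CENTERS",
    "STANDARD_BANDWIDTH",
    "write_culture_image",
    "read_culture_image",
    "write_label_map",
    "read_label_map",
    "write_cube",
    "read_cube",
    "write_float_image",
]

#: The acquisition band axis: 550-800 nm at 5 nm intervals, 10 nm bandwidth.
STANDARD_BAND_CENTERS = np.arange(550.0, 805.0, 5.0)
STANDARD_BANDWIDTH = 10.0


@dataclass
class CultureImage:
    """Named, co-registered 2D intensity channels.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Non-negative 2D float arrays, all of identical shape.
    pixel_size : float
        Physical pixel pitch in micrometres per pixel.
    background_level : float
        Constant intensity offset present in every channel.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("at least one channel required")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2D")
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


@dataclass
class HyperspectralCube:
    """Stack of 2D planes over a strictly increasing wavelength axis."""

    planes: np.ndarray  # (n_bands, ny, nx)
    band_centers: np.ndarray  # nm
    bandwidth: float = STANDARD_BANDWIDTH
    pixel_size: float = 2.0

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        self.band_centers = np.asarray(self.band_centers, dtype=float)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (band, y, x) stack")
        if len(self.band_centers) != self.planes.shape[0]:
            raise ValueError("band axis length does not match plane count")
        steps = np.diff(self.band_centers)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("band_centers must be strictly increasing and uniform")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    """Clip to the 16-bit range and round; saturates rather than wraps."""
    return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)


def write_culture_image(image: CultureImage, path: str | Path) -> Path:
    """Write one 16-bit grayscale page per channel, names in descriptions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for name, ch in image.channels.items():
            tif.write(
                _to_uint16(ch),
                description=name,
                resolution=(10000.0 / image.pixel_size, 10000.0 / image.pixel_size),
                resolutionunit="CENTIMETER",
            )
    return path


def read_culture_image(path: str | Path, pixel_size: float) -> CultureImage:
    channels: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            name = page.description or f"channel_{i}"
            channels[name] = page.asarray().astype(float)
    return CultureImage(channels=channels, pixel_size=pixel_size)


def write_label_map(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _to_uint16(labels))
    return path


def read_label_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_float_image(arr: np.ndarray, path: str | Path) -> Path:
    """Write a 32-bit floating-point TIFF (used for pH maps)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    return path


def write_cube(cube: HyperspectralCube, path: str | Path) -> tuple[Path, Path]:
    """Write a multi-page TIFF plus a sidecar band-axis CSV.

    The sidecar has two columns, ``band_center_nm`` and ``bandwidth_nm``,
    one row per plane, and lives next to the TIFF with a ``.bands.csv``
    suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tif:
        for plane, center in zip(cube.planes, cube.band_centers):
            tif.write(_to_uint16(plane), description=f"{center:g} nm")
    sidecar = path.with_suffix(".bands.csv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["band_center_nm", "bandwidth_nm"])
        for center in cube.band_centers:
            writer.writerow([f"{center:g}", f"{cube.bandwidth:g}"])
    return path, sidecar


def read_cube(path: str | Path, pixel_size: float = 2.0) -> HyperspectralCube:
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        planes = np.stack([page.asarray().astype(float) for page in tif.pages])
    sidecar = path.with_suffix(".bands.csv")
    centers = []
    bandwidth = STANDARD_BANDWIDTH
    with open(sidecar, newline="") as fh:
        for row in csv.DictReader(fh):
            centers.append(float(row["band_center_nm"]))
            bandwidth = float(row["bandwidth_nm"])
    return HyperspectralCube(
        planes=planes,
        band_centers=np.asarray(centers),
        bandwidth=bandwidth,
        pixel_size=pixel_size,
    )
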