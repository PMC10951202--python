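"""Section image container and raster I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


MODALITIES = ("IF", "ISH", "DAB")


@dataclass
class SectionImage:
    """A multi-channel 2D section.

    ``channels`` maps a channel name (e.g. ``"nuclear"``, ``"signal"``) to a
    nonnegative float raster; all channels share one shape. Rasters are
    indexed (row, column); points (x, y) have x = column, y = row.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    modality: str = "IF"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("a SectionImage needs at least one channel")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        self.channels = {
            name: np.asarray(arr, dtype=float) for name, arr in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape  # type: ignore[return-value]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"unknown channel {name!r}; have {sorted(self.channels)}"
            )
        return self.channels[name]

    def save(self, path: str | Path) -> None:
        """Write channels as a multi-page float32 TIFF; channel names go in
        the page descriptions."""
        path = Path(path)
        with tifffile.TiffWriter(path) as tif:
            for name, arr in self.channels.items():
                tif.write(arr.astype(np.float32), description=name)

    @classmethod
    def load(
        cls,
        path: str | Path,
        channel_names: list[str] | None = None,
        pixel_size_um: float = 1.0,
        modality: str = "IF",
    ) -> "SectionImage":
        path = Path(path)
        channels: dict[str, np.ndarray] = {}
        with tifffile.TiffFile(path) as tif:
            for i, page in enumerate(tif.pages):
                if channel_names is not None:
                    name = channel_names[i]
                else:
                    name = (page.description or "").strip() or f"ch{i}"
                channels[name] = page.asarray().astype(float)
        return cls(channels=channels, pixel_size_um=pixel_size_um, modality=modality)


def save_label_raster(labels: np.ndarray, path: str | Path) -> None:
    """Persist an atlas label raster as 16-bit single-channel TIFF/PNG."""
    path = Path(path)
    arr = np.asarray(labels)
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("label values exceed 16-bit range")
    arr16 = arr.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr16)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, arr16)


def load_label_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr).astype(np.int64)
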