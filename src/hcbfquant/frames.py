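"""Core image container shared by the simulator and the quantification core."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = ["Channel", "ImageFrame", "DEFOCUS_Z_UM"]


class Channel(str, Enum):
    """Imaging channel of a well frame.

    ``CELL_DEFOCUS``: negatively defocused brightfield in which single
    cells act as lenses and appear as bright spots (cell counting).
    ``MYO_DEFOCUS``: extra-defocused brightfield that highlights the
    larger myotubes as bright ridges (myotube-area quantification).
    ``NUCLEI_FLUOR``: Hoechst-type nuclear fluorescence (ground-truth
    comparison channel).
    """

    CELL_DEFOCUS = "CELL_DEFOCUS"
    MYO_DEFOCUS = "MYO_DEFOCUS"
    NUCLEI_FLUOR = "NUCLEI_FLUOR"


#: Defocus z-offsets (µm below focus) used per format and channel.
#: Metadata only -- the rendering rule, not an optics model, defines
#: channel appearance.
DEFOCUS_Z_UM = {
    ("P96", Channel.CELL_DEFOCUS): 2400.0,
    ("P96", Channel.MYO_DEFOCUS): 2070.0,
    ("P384", Channel.CELL_DEFOCUS): 2285.0,
    ("P384", Channel.MYO_DEFOCUS): 1580.0,
}


@dataclass
class ImageFrame:
    """One well's 2-D intensity grid with physical scale and metadata."""

    pixels: np.ndarray
    um_per_px: float
    channel: Channel = Channel.CELL_DEFOCUS
    defocus_z_um: float = 0.0
    well_id: str = ""
    t_h: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 65535):
            raise ValueError("pixel values must lie in [0, 65535]")
        self.channel = Channel(self.channel)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def px_area_um2(self) -> float:
        return self.um_per_px**2
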