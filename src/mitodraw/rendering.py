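"""Rasterize layouts and encode them with physical-resolution metadata.

The logical canvas is defined at 100 dpi; rendering at ``dpi`` scales pixel
dimensions linearly (an 800x800 logical canvas is 8x8 inches, so 2400x2400
pixels at 300 dpi) while text keeps its physical point size.  Supported
containers are TIFF, JPEG, PNG, and BMP, each carrying the dpi in its
native resolution field (TIFF resolution tags, JFIF density, PNG pHYs,
BMP pixels-per-meter); resolutions outside 100-1000 dpi are rejected.

Rendering goes through matplotlib's Agg backend with no global state, so a
fixed layout + style + dpi always produces the same pixel array, and PNG /
BMP / TIFF encodes are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import BytesIO
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from matplotlib.patches import Polygon
from PIL import Image

from .errors import DpiOutOfRange, UnsupportedFormat
from .layout_engine import LOGICAL_DPI, Layout, Style, glyph_polygon
from .model import Topology

MIN_DPI = 100
MAX_DPI = 1000

IMAGE_FORMATS = ("tiff", "jpeg", "png", "bmp")

_PIL_FORMATS = {"tiff": "TIFF", "jpeg": "JPEG", "png": "PNG", "bmp": "BMP"}

_SUFFIX_TO_FORMAT = {
    ".tif": "tiff",
    ".tiff": "tiff",
    ".jpg": "jpeg",
    ".jpeg": "jpeg",
    ".png": "png",
    ".bmp": "bmp",
}


@dataclass(frozen=True)
class ImageBuffer:
    """A rasterized map: RGB pixel array plus its physical resolution."""

    pixels: np.ndarray  # (height, width, 3) uint8
    dpi: int

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def _check_dpi(dpi: int) -> int:
    dpi = int(dpi)
    if not MIN_DPI <= dpi <= MAX_DPI:
        raise DpiOutOfRange(
            f"resolution must be between {MIN_DPI} and {MAX_DPI} dpi, got {dpi}"
        )
    return dpi


def _rgb01(color) -> tuple:
    return tuple(c / 255.0 for c in color)


def render_layout(layout: Layout, style: Style, dpi: int = 300) -> ImageBuffer:
    """Draw a layout onto a white canvas at the requested resolution."""
    dpi = _check_dpi(dpi)
    W, H = layout.canvas_size
    fig = Figure(figsize=(W / LOGICAL_DPI, H / LOGICAL_DPI), dpi=dpi)
    canvas = FigureCanvasAgg(fig)
    fig.patch.set_facecolor("white")
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
    ax.set_xlim(0, W)
    ax.set_ylim(H, 0)  # canvas y grows downward
    ax.set_axis_off()
    ax.set_facecolor("white")

    if layout.kind is Topology.linear:
        # baseline between the two strand rows
        ax.plot(
            [style.margin, W - style.margin],
            [H / 2.0, H / 2.0],
            color="0.55",
            linewidth=0.8,
            zorder=1,
        )

    for glyph in layout.glyphs:
        pts = glyph_polygon(glyph, style)
        ax.add_patch(
            Polygon(
                pts,
                closed=True,
                facecolor=_rgb01(glyph.color),
                edgecolor="black",
                linewidth=0.6,
                zorder=2,
            )
        )

    for label in layout.labels:
        ax.text(
            label.x,
            label.y,
            label.text,
            rotation=label.rotation,
            rotation_mode="anchor",
            ha=label.ha,
            va=label.va,
            fontsize=style.font_size,
            color=_rgb01(label.color),
            zorder=3,
        )

    canvas.draw()
    pixels = np.asarray(canvas.buffer_rgba())[:, :, :3].copy()
    return ImageBuffer(pixels=pixels, dpi=dpi)


def encode_image(buffer: ImageBuffer, image_format: str) -> bytes:
    """Encode an :class:`ImageBuffer` as TIFF, JPEG, PNG, or BMP bytes,
    embedding the dpi in the container's resolution metadata."""
    fmt = str(image_format).lower().lstrip(".")
    if fmt == "tif":
        fmt = "tiff"
    if fmt == "jpg":
        fmt = "jpeg"
    if fmt not in _PIL_FORMATS:
        raise UnsupportedFormat(
            f"unsupported image format {image_format!r}; choose one of {IMAGE_FORMATS}"
        )
    img = Image.fromarray(buffer.pixels, mode="RGB")
    out = BytesIO()
    kwargs: dict = {"dpi": (buffer.dpi, buffer.dpi)}
    if fmt == "jpeg":
        kwargs["quality"] = 95
    img.save(out, format=_PIL_FORMATS[fmt], **kwargs)
    return out.getvalue()


def save_image(
    layout: Layout,
    style: Style,
    path,
    dpi: int = 300,
    image_format: str | None = None,
) -> Path:
    """Render a layout and write it to *path*; the container is inferred
    from the filename suffix unless *image_format* is given."""
    path = Path(path)
    if image_format is None:
        try:
            image_format = _SUFFIX_TO_FORMAT[path.suffix.lower()]
        except KeyError:
            raise UnsupportedFormat(
                f"cannot infer image format from suffix {path.suffix!r}"
            )
    buffer = render_layout(layout, style, dpi)
    path.write_bytes(encode_image(buffer, image_format))
    return path
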