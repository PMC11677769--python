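"""Deterministic raster snapshots of the simulation domain.

Dipoles are drawn as oriented two-tone glyphs (red positive end, blue
negative end, grey axis); dopants as filled discs scaled by their diameter
and colored by the sign of their charge (orange positive, purple negative,
grey neutral).  Pixel output is a pure function of the state and scale, so
frames can be regression-tested byte for byte.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Optional

from PIL import Image, ImageDraw

from .model import SystemConfig, SystemState

__all__ = ["render_bitmap", "save_bitmap"]

_BG = (255, 255, 255)
_AXIS = (120, 120, 120)
_POS_END = (200, 30, 30)
_NEG_END = (30, 60, 200)
_DOPANT = {1: (235, 140, 20), -1: (130, 30, 160), 0: (150, 150, 150)}


def render_bitmap(state: SystemState, cfg: SystemConfig, scale: int = 16,
                  draw_callback: Optional[Callable[[str, int], None]] = None
                  ) -> Image.Image:
    """Render one frame; image size is (cols*scale) x (rows*scale) pixels.

    ``draw_callback(kind, index)`` is invoked once per drawn glyph with
    kind "dipole" or "dopant" (a hook for tests and progress reporting).
    """
    if scale < 1:
        raise ValueError("scale must be >= 1")
    w = cfg.lattice_cols * scale
    h = cfg.lattice_rows * scale
    img = Image.new("RGB", (w, h), _BG)
    draw = ImageDraw.Draw(img)
    x0, y0, x1, y1 = cfg.box

    def to_px(p):
        return ((p[0] - x0) / (x1 - x0) * (w - 1),
                (p[1] - y0) / (y1 - y0) * (h - 1))

    nm_to_px = (w - 1) / (x1 - x0)

    for idx, d in enumerate(state.dipoles):
        pe, ne = d.end_positions
        draw.line([to_px(ne), to_px(pe)], fill=_AXIS, width=1)
        r = max(1.0, 0.08 * d.arm_length * nm_to_px * 2)
        for end, color in ((pe, _POS_END), (ne, _NEG_END)):
            ex, ey = to_px(end)
            draw.ellipse([ex - r, ey - r, ex + r, ey + r], fill=color)
        if draw_callback is not None:
            draw_callback("dipole", idx)

    for idx, p in enumerate(state.dopants):
        cx, cy = to_px(p.position)
        r = max(1.0, 0.5 * p.size * nm_to_px)
        color = _DOPANT[0 if p.charge == 0 else (1 if p.charge > 0 else -1)]
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color,
                     outline=(60, 60, 60))
        if draw_callback is not None:
            draw_callback("dopant", idx)
    return img


def save_bitmap(img: Image.Image, path: Path | str) -> None:
    """Write a PNG with fixed encoder settings (byte-deterministic)."""
    img.save(Path(path), format="PNG", optimize=False, compress_level=6)
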