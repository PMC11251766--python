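"""The 89-marker chest-wall template.

A documented stand-in for the standard optoelectronic-plethysmography marker
set: 8 circumferential rows of 11 markers each on an elliptical-cross-section
torso surface (rows A1-A4 abdominal, T1-T4 thoracic, caudal to cranial) plus a
single cranial apex marker at the suprasternal pole, 8 x 11 + 1 = 89 markers.
Column 0 sits on the ventral midline (sternal line); columns advance towards
the subject's left when seen from above.

Axes: +z cranial, +y ventral, +x subject's left, millimetres.
"""
from __future__ import annotations

import numpy as np

from .datatypes import LandmarkConfiguration
from .errors import InvalidParameterError

__all__ = [
    "N_ROWS",
    "N_COLS",
    "N_MARKERS",
    "APEX_ID",
    "make_template",
    "template_marker_ids",
    "thoracic_marker_ids",
    "abdominal_marker_ids",
]

N_ROWS = 8
N_COLS = 11
N_MARKERS = N_ROWS * N_COLS + 1  # 89
APEX_ID = "APEX"

_ROW_NAMES = ("A1", "A2", "A3", "A4", "T1", "T2", "T3", "T4")
_THORACIC_ROWS = frozenset({"T1", "T2", "T3", "T4"})


def template_marker_ids(n_rows: int = N_ROWS, n_cols: int = N_COLS) -> tuple[str, ...]:
    """Marker names in template (row-major, caudal-to-cranial) order."""
    if n_rows == N_ROWS:
        row_names = _ROW_NAMES
    else:
        row_names = tuple(f"R{i + 1}" for i in range(n_rows))
    ids = [f"{row}_{col:02d}" for row in row_names for col in range(n_cols)]
    ids.append(APEX_ID)
    return tuple(ids)


def thoracic_marker_ids() -> tuple[str, ...]:
    """Markers of the thoracic compartment (rows T1-T4 and the apex)."""
    return tuple(
        m for m in template_marker_ids() if m.split("_")[0] in _THORACIC_ROWS
    ) + (APEX_ID,)


def abdominal_marker_ids() -> tuple[str, ...]:
    """Markers of the abdominal compartment (rows A1-A4)."""
    thoracic = set(thoracic_marker_ids())
    return tuple(m for m in template_marker_ids() if m not in thoracic)


def _radius_taper(z_frac: np.ndarray) -> np.ndarray:
    """Smooth taper of the elliptical cross-section along the torso axis.

    z_frac in [0, 1] caudal to cranial; widest slightly below mid-torso,
    narrowing towards shoulders and pelvis, never below 55% of the nominal
    semi-axis so the surface stays star-shaped around the axis.
    """
    return 0.55 + 0.45 * np.sin(np.pi * (0.15 + 0.7 * z_frac))


def make_template(
    n_rows: int = N_ROWS,
    n_cols: int = N_COLS,
    torso_dims: tuple[float, float, float] = (300.0, 220.0, 500.0),
) -> LandmarkConfiguration:
    """Build the torso marker template.

    Parameters
    ----------
    n_rows, n_cols : int
        Circumferential row/column counts; defaults give the 89-marker set.
    torso_dims : (width, depth, height) in mm
        Full mediolateral width, dorsoventral depth and caudocranial height.
    """
    if n_rows < 2 or n_cols < 3:
        raise InvalidParameterError("template needs n_rows >= 2 and n_cols >= 3")
    width, depth, height = torso_dims
    if width <= 0 or depth <= 0 or height <= 0:
        raise InvalidParameterError("torso dimensions must be positive")

    a, b = width / 2.0, depth / 2.0
    z_rows = np.linspace(0.06 * height, 0.90 * height, n_rows)
    taper = _radius_taper(z_rows / height)
    # column 0 on the ventral midline; angle increases towards subject's left
    theta = np.pi / 2 + 2 * np.pi * np.arange(n_cols) / n_cols

    coords = np.empty((n_rows * n_cols + 1, 3))
    idx = 0
    for zi, ti in zip(z_rows, taper):
        coords[idx : idx + n_cols, 0] = a * ti * np.cos(theta)
        coords[idx : idx + n_cols, 1] = b * ti * np.sin(theta)
        coords[idx : idx + n_cols, 2] = zi
        idx += n_cols
    coords[idx] = (0.0, 0.0, height)  # cranial apex pole

    return LandmarkConfiguration(
        coords=coords, marker_ids=template_marker_ids(n_rows, n_cols)
    )
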