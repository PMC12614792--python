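"""Polar-plot rendering of visual fingerprints (presentation utility)."""

from __future__ import annotations

import numpy as np

from .schema import DEFAULT_SCHEMA, Fingerprint

__all__ = ["plot_fingerprint"]


def plot_fingerprint(fp: Fingerprint, ax=None, band: np.ndarray | None = None,
                     color="tab:blue", label: str | None = None):
    """Draw one fingerprint as a closed polar contour.

    Attributes are placed azimuthally in schema order; high values sit near
    the boundary, low values near the centre. ``band`` (16 non-negative
    values, e.g. standard errors) draws a shaded thickness around the contour.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(fp.values)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    radius = fp.values + 1.0  # map [-1, 1] onto [0, 2]
    t = np.append(theta, theta[0])
    r = np.append(radius, radius[0])
    ax.plot(t, r, color=color, label=label or fp.material_id)
    if band is not None:
        b = np.append(band, band[0])
        ax.fill_between(t, np.clip(r - b, 0, None), r + b, color=color, alpha=0.25)
    ax.set_xticks(theta)
    ax.set_xticklabels([a.name for a in DEFAULT_SCHEMA.attributes], fontsize=7)
    ax.set_ylim(0, 2.1)
    ax.set_yticklabels([])
    return ax
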