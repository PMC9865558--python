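"""Optional matplotlib figures: SPD curves, fold metrics, distance
histograms.  Matplotlib is imported lazily so the core package has no
hard plotting dependency."""

from __future__ import annotations

import numpy as np

from .spectral import SPD, SubLightSet

__all__ = [
    "plot_spd",
    "plot_sublights",
    "plot_fold_metrics",
    "plot_distance_histograms",
]


def _get_ax(ax):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    return ax


def plot_spd(spd: SPD, ax=None, label=None, **kwargs):
    """Line plot of one SPD against wavelength."""
    ax = _get_ax(ax)
    ax.plot(spd.grid.values, spd.intensity, label=label, **kwargs)
    ax.set_xlabel("wavelength [nm]")
    ax.set_ylabel("relative power")
    if label:
        ax.legend()
    return ax


def plot_sublights(sublights: SubLightSet, ax=None, **kwargs):
    """All sub-light SPDs on one axis."""
    ax = _get_ax(ax)
    for i in range(sublights.n_lights):
        ax.plot(sublights.grid.values, sublights.Q[:, i], **kwargs)
    ax.set_xlabel("wavelength [nm]")
    ax.set_ylabel("relative power")
    return ax


def plot_fold_metrics(results, ax=None, metric: str = "f1"):
    """Bar chart of a per-fold metric from cross-validation results."""
    ax = _get_ax(ax)
    vals = [getattr(r, metric) for r in results]
    ax.bar([r.fold_id for r in results], vals)
    ax.set_xlabel("fold")
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.05)
    return ax


def plot_distance_histograms(reports: dict, ax=None, bins: int = 30):
    """Overlaid histograms of Mahalanobis distances, one per condition.

    ``reports`` maps a condition label to a MahalanobisReport.
    """
    ax = _get_ax(ax)
    all_d = np.concatenate([r.distances for r in reports.values()])
    edges = np.histogram_bin_edges(all_d, bins=bins)
    for label, rep in reports.items():
        ax.hist(rep.distances, bins=edges, alpha=0.5, label=label)
    ax.set_xlabel("squared Mahalanobis distance")
    ax.set_ylabel("count")
    ax.legend()
    return ax
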