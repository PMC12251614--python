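"""Minimal matplotlib views: radial density profiles and Rg(t) traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_density_profile(profile, ax=None, label=None):
    """Hydrophilic shell density rho(r); vesicles show the two-peak shape."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(profile.centers, profile.density, "-o", ms=3, label=label)
    ax.set_xlabel(r"r ($\sigma$)")
    ax.set_ylabel(r"$\rho_B(r)$ ($\sigma^{-3}$)")
    if label:
        ax.legend(frameon=False)
    return ax


def plot_rg_series(steps, rg, dt=1e-4, ax=None, label=None):
    """Largest-cluster radius of gyration against time; plateaus signal a
    kinetically stable aggregate."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    import numpy as np

    ax.plot(np.asarray(steps) * dt, rg, label=label)
    ax.set_xlabel(r"t ($\tau$)")
    ax.set_ylabel(r"$R_g$ ($\sigma$)")
    if label:
        ax.legend(frameon=False)
    return ax
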