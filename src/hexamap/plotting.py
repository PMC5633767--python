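"""Simple per-chromosome coverage and LOD figures (matplotlib)."""

from __future__ import annotations

import numpy as np

from .coverage import CoverageSegment, CoverageTrack
from .qtl import LODProfile

__all__ = ["plot_coverage", "plot_lod"]

_CLS_COLOR = {"deletion": "tab:red", "duplication": "tab:blue", "normal": "0.7"}


def plot_coverage(track: CoverageTrack, segments: list[CoverageSegment] | None = None,
                  ax=None):
    """Binned depth along one chromosome with classified segments overlaid."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 2.5))
    x = (np.arange(track.n_bins) + 0.5) * track.bin_size / 1e6
    y = np.where(track.gap, np.nan, track.values)
    ax.plot(x, y, ".", ms=1.5, color="0.4", rasterized=True)
    for s in segments or []:
        ax.hlines(s.mean_cov, s.start / 1e6, s.end / 1e6,
                  color=_CLS_COLOR.get(s.cls, "k"), lw=2.5)
    ax.set_xlabel(f"{track.chrom} position (Mb)")
    ax.set_ylabel("depth")
    return ax


def plot_lod(profile: LODProfile, threshold: float = 5.0, ax=None):
    """LOD curve of one linkage group with the reporting threshold."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    ax.plot(profile.grid, profile.lod, color="tab:green")
    ax.axhline(threshold, color="0.5", ls="--", lw=1)
    ax.set_xlabel(f"{profile.group} (cM)")
    ax.set_ylabel("LOD")
    return ax
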