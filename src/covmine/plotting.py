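"""Static genome-fragment plots: coverage panels, a splicing-index panel,
and mined regions drawn as bars under the signal they were mined from."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coverage import CoverageTrack
from .errors import DomainError
from .mining import IrreducibleRegion


def plot_region(
    tracks: Sequence[CoverageTrack],
    regions: Iterable[IrreducibleRegion] = (),
    path: str | Path = "region.png",
    si_track: CoverageTrack | None = None,
    dpi: int = 110,
) -> Path:
    """Render stacked panels for one genomic region.

    One panel with all coverage samples overlaid, an optional
    splicing-index panel, and (when regions are given) a panel with mined
    regions as horizontal bars.  Rendering is deterministic for fixed
    inputs: fixed figure geometry, no timestamps.
    """
    tracks = list(tracks)
    regions = list(regions)
    if not tracks:
        raise DomainError("at least one track is required")
    region = tracks[0].region
    for t in tracks[1:]:
        if t.region != region:
            raise DomainError("all tracks must share one region")

    n_panels = 1 + (si_track is not None) + (len(regions) > 0)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(9, 2.2 * n_panels), sharex=True, squeeze=False
    )
    axes = axes.ravel()
    x = np.arange(region.start, region.end)

    ax = axes[0]
    for t in tracks:
        for sample in t.samples:
            ax.plot(x, t.sample_values(sample), lw=0.8, label=sample)
    ax.set_ylabel("coverage")
    ax.legend(fontsize=7, loc="upper right")
    ax.set_title(str(region), fontsize=9)

    panel = 1
    if si_track is not None:
        ax = axes[panel]
        for sample in si_track.samples:
            ax.plot(x, si_track.sample_values(sample), lw=0.8, color="purple")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel("splicing index")
        panel += 1

    if regions:
        ax = axes[panel]
        for k, r in enumerate(regions):
            ax.barh(
                y=k % 4,
                width=r.interval.length(),
                left=r.interval.start,
                height=0.8,
                color="tab:green",
            )
        ax.set_ylabel("mined regions")
        ax.set_yticks([])

    axes[-1].set_xlabel(f"{region.chrom} position")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=dpi, metadata=_no_metadata(path))
    plt.close(fig)
    return path


def _no_metadata(path: Path) -> dict:
    # strip creation dates so identical inputs give identical bytes
    if path.suffix.lower() == ".svg":
        return {"Date": None}
    if path.suffix.lower() == ".png":
        return {"Software": None}
    return {}
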