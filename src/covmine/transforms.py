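"""Coverage-track transformations.

Library-size normalisation, lowess smoothing, per-nucleotide fold change and
the nucleotide-level splicing index.  Each transform maps a
``CoverageTrack`` to a new track with the appropriate value-kind tag, so the
miner and the writers can be pointed at any stage of a pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .coverage import CoverageTrack, TrackKind
from .errors import DomainError
from .mining import IrreducibleRegion, MiningParams, find_irreducible_regions


@dataclass(frozen=True)
class SmoothingParams:
    """Lowess settings: span fraction ``f`` in (0, 1] and number of
    robustness iterations.  ``f = 0.1`` with 3 iterations flattens
    over-amplification spikes without erasing exon-scale structure."""

    f: float = 0.1
    iterations: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.f <= 1:
            raise DomainError(f"lowess span f must be in (0, 1]: {self.f}")
        if self.iterations < 1:
            raise DomainError("iterations must be >= 1")


def normalize_library_size(track: CoverageTrack, total_reads: int) -> CoverageTrack:
    """Scale to reads-per-million: values * 1e6 / total mapped reads."""
    if total_reads <= 0:
        raise DomainError(f"total_reads must be positive: {total_reads}")
    return track.with_values(track.values * (1e6 / total_reads), TrackKind.NORMALIZED)


def lowess_smooth(
    track: CoverageTrack, params: SmoothingParams = SmoothingParams()
) -> CoverageTrack:
    """Locally-weighted regression of coverage against position, per sample.

    Smoothing before mining stabilises region boundaries: it damps isolated
    artifact peaks and fills in small non-expressed gaps.  Negative fitted
    values are clipped to 0 so a smoothed track remains a valid coverage
    signal.  Regions shorter than 10 nt carry too few points for a local
    fit and are rejected.
    """
    n = track.region.length()
    if n < 10:
        raise DomainError(f"region too short for lowess: {n} < 10 nt")
    x = np.arange(n, dtype=float)
    rows = []
    for row in track.values:
        y = np.asarray(row, dtype=float)
        base = _sm_lowess(y, x, frac=params.f, it=0, return_sorted=False)
        # robustness weights use 6 * median(|residual|); when the median
        # residual is (near) zero the weights degenerate and every local fit
        # collapses onto the raw data, so keep the unweighted fit instead —
        # the same early exit R's lowess takes
        mad6 = 6.0 * np.median(np.abs(y - base))
        if mad6 > 1e-9 * max(1.0, float(np.abs(y).max())):
            fitted = _sm_lowess(
                y, x, frac=params.f, it=params.iterations, return_sorted=False
            )
        else:
            fitted = base
        rows.append(np.clip(fitted, 0.0, None))
    return track.with_values(np.vstack(rows), TrackKind.SMOOTHED)


def fold_change(
    t1: CoverageTrack, t2: CoverageTrack, pseudocount: float = 1.0
) -> CoverageTrack:
    """Per-position log2((v1 + p) / (v2 + p)).

    The pseudocount keeps zero-coverage positions finite; fold change is
    antisymmetric under swapping the two tracks.
    """
    if t1.region != t2.region:
        raise DomainError(f"region mismatch: {t1.region} vs {t2.region}")
    if pseudocount <= 0:
        raise DomainError("pseudocount must be positive")
    vals = np.log2((t1.values + pseudocount) / (t2.values + pseudocount))
    return CoverageTrack(
        t1.region, t1.samples, vals.reshape(t1.values.shape), TrackKind.FOLD_CHANGE
    )


@dataclass(frozen=True)
class SplicingInputs:
    """Inputs of the nucleotide-level splicing index.

    ``E1``/``E2`` are per-nucleotide coverages of the two conditions over
    the same interval; ``G1``/``G2`` the read counts of the enclosing gene
    or region in each condition, used to normalise away overall expression
    differences.  ``pseudocount`` keeps zero-coverage positions finite.
    """

    E1: CoverageTrack
    E2: CoverageTrack
    G1: int
    G2: int
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.E1.region != self.E2.region:
            raise DomainError(
                f"region mismatch: {self.E1.region} vs {self.E2.region}"
            )
        if self.G1 <= 0 or self.G2 <= 0:
            raise DomainError(
                "gene read counts must be positive; a zero count signals an "
                "unexpressed gene — filter such genes before computing the index"
            )
        if self.pseudocount <= 0:
            raise DomainError("pseudocount must be positive")


def splicing_index(inputs: SplicingInputs) -> CoverageTrack:
    """Per-nucleotide splicing index between two conditions.

    SI_n = log2( ((E1_n + p) / G1) / ((E2_n + p) / G2) )

    Coverage at each nucleotide is normalised by the read count of the
    enclosing gene, so the index isolates *relative* inclusion changes
    (alternative exon usage) from overall expression level changes.
    Positions in constitutively included exons sit near 0; |SI| >= 1 marks
    a two-fold or larger relative inclusion change.
    """
    p = inputs.pseudocount
    vals = np.log2(
        ((inputs.E1.values + p) / inputs.G1) / ((inputs.E2.values + p) / inputs.G2)
    )
    samples = [
        f"{s1}/{s2}" for s1, s2 in zip(inputs.E1.samples, inputs.E2.samples)
    ]
    return CoverageTrack(inputs.E1.region, samples, vals, TrackKind.SPLICING_INDEX)


DEFAULT_MU_SI = 1.0


def splicing_regions(
    si_track: CoverageTrack,
    sample: str | None = None,
    mu_si: float = DEFAULT_MU_SI,
    minsup: int = 51,
    strict: bool = False,
) -> list[tuple[IrreducibleRegion, int]]:
    """Mine significant regions of a splicing-index track.

    The miner needs a non-negative magnitude, so |SI| is mined at threshold
    ``mu_si`` (default 1.0 = two-fold relative change); each region is
    returned with the sign of its mean SI (+1: higher relative inclusion in
    condition 1, -1: in condition 2).
    """
    if si_track.kind is not TrackKind.SPLICING_INDEX:
        raise DomainError(f"expected a SPLICING_INDEX track, got {si_track.kind}")
    if sample is None:
        if len(si_track.samples) != 1:
            raise DomainError("sample must be given for a multi-sample track")
        sample = si_track.samples[0]
    si = si_track.sample_values(sample)
    abs_track = CoverageTrack(
        si_track.region, [sample], np.abs(si)[None, :], TrackKind.SPLICING_INDEX
    )
    params = MiningParams(mu=mu_si, minsup=minsup, strict=strict)
    out = []
    for region in find_irreducible_regions(abs_track, sample, params):
        lo = region.interval.start - si_track.region.start
        hi = region.interval.end - si_track.region.start
        sign = 1 if float(np.mean(si[lo:hi])) >= 0 else -1
        out.append((region, sign))
    return out
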