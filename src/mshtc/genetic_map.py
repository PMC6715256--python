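"""Physical-to-genetic coordinate conversion and the msh event statistic.

A ``GeneticMap`` is a monotone piecewise-linear map from base-pair position
to cumulative genetic position in Morgans, with a local per-base rate given
by the slope of the containing interval.  It feeds the arbitrary-map
likelihood through ``compose_chi``, which folds the 5' and 3' msh tract
lengths into the composite event statistic

    chi  = mu * (msh_5 + msh_3) + c_5 + c_3
    beta = (mu + rho_5) * (mu + rho_3)

where c_5/c_3 are the Morgans spanned by the tracts and rho_5/rho_3 the
per-base recombination rates at the tract ends.  When one direction runs
off the end of the assayed region without a mismatch the end-of-chromosome
forms chi_eoc = mu*(msh + msh_eoc) + c + c_eoc and beta_eoc = mu + rho are
used instead.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

#: Per-copy likelihood kernels (see mshtc.likelihood).
TWO_SIDED = 0      #: both msh tracts end at an observed mismatch
ONE_SIDED = 1      #: one tract truncated at the end of the chromosome
DOUBLE_TRUNCATED = 2  #: both tracts truncated (low-information observation)


class GeneticMap:
    """Piecewise-linear genetic map, or a uniform per-base rate.

    In map mode, interpolation between anchors is linear in cumulative
    Morgans and queries beyond the map ends extrapolate at the terminal
    interval's rate.  ``local_rho`` at an interior anchor returns the slope
    of the right-hand interval (deterministic tie-break).
    """

    def __init__(self, positions_bp=None, cum_morgans=None, *, rho=None):
        if rho is not None:
            if positions_bp is not None:
                raise ValueError("give either anchors or a uniform rho")
            if rho < 0:
                raise ValueError("uniform rho must be >= 0")
            self._rho = float(rho)
            self._pos = self._cum = self._slopes = None
            return
        pos = np.asarray(positions_bp, dtype=float)
        cum = np.asarray(cum_morgans, dtype=float)
        if pos.size < 2:
            raise ValueError("a genetic map needs at least 2 anchors")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("anchor positions must be strictly increasing")
        if np.any(np.diff(cum) < 0):
            raise ValueError("cumulative genetic positions must be "
                             "non-decreasing")
        self._rho = None
        self._pos, self._cum = pos, cum
        self._slopes = np.diff(cum) / np.diff(pos)  # Morgans per bp

    @classmethod
    def uniform(cls, rho: float) -> "GeneticMap":
        """Uniform map with constant per-base rate ``rho`` (Morgans/bp)."""
        return cls(rho=rho)

    @property
    def is_uniform(self) -> bool:
        return self._rho is not None

    def genetic_position(self, bp):
        """Cumulative genetic position (Morgans) at physical position bp."""
        bp = np.asarray(bp, dtype=float)
        if self._rho is not None:
            out = self._rho * (bp - 1.0)
            return out if out.ndim else float(out)
        out = np.interp(bp, self._pos, self._cum)
        below = bp < self._pos[0]
        above = bp > self._pos[-1]
        out = np.where(below, self._cum[0] - (self._pos[0] - bp) * self._slopes[0], out)
        out = np.where(above, self._cum[-1] + (bp - self._pos[-1]) * self._slopes[-1], out)
        return out if out.ndim else float(out)

    def local_rho(self, bp):
        """Per-base rate (Morgans/bp) of the interval containing bp."""
        bp = np.asarray(bp, dtype=float)
        if self._rho is not None:
            out = np.full(bp.shape, self._rho)
            return out if out.ndim else self._rho
        # right=True puts an exact anchor hit into the right-hand interval
        idx = np.searchsorted(self._pos, bp, side="right") - 1
        idx = np.clip(idx, 0, self._slopes.size - 1)
        out = self._slopes[idx]
        return out if out.ndim else float(out)


def read_genetic_map(path_or_buffer) -> GeneticMap:
    """Read a HapMap- or deCODE-style genetic map text file.

    Accepts whitespace/tab-delimited files with an auto-detected header and
    either 4 columns (chrom, bp, rate cM/Mb, cumulative cM), 3 columns
    (bp, rate, cumulative cM) or 2 columns (bp, cumulative cM).
    Centimorgans are converted to Morgans internally.
    """
    import pandas as pd

    if isinstance(path_or_buffer, str) and "\n" in path_or_buffer:
        path_or_buffer = io.StringIO(path_or_buffer)
    df = pd.read_csv(path_or_buffer, sep=r"\s+", comment="#", header=None,
                     skip_blank_lines=True)
    # header detection: first row non-numeric in the last column
    try:
        float(df.iloc[0, -1])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] == 2:
        bp, cm = df.iloc[:, 0], df.iloc[:, 1]
    elif df.shape[1] == 3:
        bp, cm = df.iloc[:, 0], df.iloc[:, 2]
    elif df.shape[1] >= 4:
        bp, cm = df.iloc[:, 1], df.iloc[:, 3]
    else:
        raise ValueError("unrecognized genetic map layout")
    return GeneticMap(np.asarray(bp, dtype=float),
                      np.asarray(cm, dtype=float) / 100.0)


@dataclass
class ChiStat:
    """Composite event statistic for one variant copy."""

    chi: float
    beta: float
    kind: int  # TWO_SIDED, ONE_SIDED or DOUBLE_TRUNCATED


def compose_chi(obs, gmap: GeneticMap, mu: float,
                start_bp: int | None = None,
                end_bp: int | None = None) -> ChiStat:
    """Fold an MshObservation into (chi, beta) for the likelihood.

    ``start_bp``/``end_bp`` are the physical bounds used for the truncated
    (end-of-chromosome) distances; they default to the observation's own
    recorded distances.  A doubly truncated observation is still usable:
    it yields a pure no-event statistic (kind = DOUBLE_TRUNCATED, beta
    unused) and should be flagged low-information downstream.
    """
    pos = obs.focal_pos
    g_focal = gmap.genetic_position(pos)

    def _side(msh_bp, term_pos, trunc, is_five):
        if trunc:
            edge = (start_bp if is_five else end_bp)
            if edge is not None:
                msh_bp = abs(pos - edge)
                term = edge
            else:
                term = pos - msh_bp if is_five else pos + msh_bp
            c = abs(g_focal - gmap.genetic_position(term))
            return msh_bp, c, None
        c = abs(g_focal - gmap.genetic_position(term_pos))
        return msh_bp, c, gmap.local_rho(term_pos)

    msh5, c5, rho5 = _side(obs.msh5_bp, obs.term5_pos, obs.trunc5, True)
    msh3, c3, rho3 = _side(obs.msh3_bp, obs.term3_pos, obs.trunc3, False)
    chi = mu * (msh5 + msh3) + c5 + c3

    if not obs.trunc5 and not obs.trunc3:
        return ChiStat(chi, (mu + rho5) * (mu + rho3), TWO_SIDED)
    if obs.trunc5 and obs.trunc3:
        return ChiStat(chi, 1.0, DOUBLE_TRUNCATED)
    rho_complete = rho3 if obs.trunc5 else rho5
    return ChiStat(chi, mu + rho_complete, ONE_SIDED)
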