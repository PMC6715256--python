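"""Maximum-shared-haplotype extraction with the positional Burrows-Wheeler
transform.

For every variant copy the estimator needs, in each direction along the
chromosome, the longest tract of sequence identity between the carrier
chromosome and any chromosome not carrying the variant.  The PBWT prefix
(``a``) and divergence (``d``) arrays of Durbin's algorithm 2 deliver these
tracts in time linear in rows x sites; a direct brute-force scan is kept
alongside as an independent testing oracle.

Conventions
-----------
* ``a[k]``/``d[k]`` describe the ordering by reversed prefixes of columns
  ``0..k-1``; ``d[k][i]`` is the first column on which the consecutive
  (in ``a``-order) rows ``a[k][i-1]`` and ``a[k][i]`` agree through column
  ``k-1``; ``d[k][0] == k`` is a sentinel (zero-length match).
* The start of the longest match between ``a[k][i]`` and ``a[k][j]``
  (``i < j``) is ``max(d[k][i+1..j])``.
* An msh tract is the run of identical sites flanking the focal base.
  Two length conventions are supported: ``mismatch`` (default) measures
  to the first *mismatching* site — the first base observably not
  identical — while ``match`` measures one interval shorter, to the
  farthest matching site (the tract start read directly off the
  divergence array).  The terminating event lies between the two
  endpoints; the interval censoring only matters once tracts shrink
  toward the inter-SNP spacing.
* The focal variant's own column is never compared: the mutation being
  dated is not a terminator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import HaplotypeMatrix


@dataclass
class PbwtArrays:
    """Stacked prefix and divergence arrays, one row per column boundary."""

    a: np.ndarray  # (n_sites + 1, n_rows) int32
    d: np.ndarray  # (n_sites + 1, n_rows) int32

    @property
    def n_rows(self) -> int:
        return self.a.shape[1]

    @property
    def n_sites(self) -> int:
        return self.a.shape[0] - 1


def build_pbwt(alleles: np.ndarray) -> PbwtArrays:
    """Durbin algorithm 2 over all columns (vectorized per column).

    To index the reverse direction, call with ``alleles[:, ::-1]``.
    """
    alleles = np.asarray(alleles)
    n_rows, n_sites = alleles.shape
    A = np.empty((n_sites + 1, n_rows), dtype=np.int32)
    D = np.empty((n_sites + 1, n_rows), dtype=np.int32)
    a = np.arange(n_rows, dtype=np.int32)
    d = np.zeros(n_rows, dtype=np.int32)
    A[0], D[0] = a, d
    for k in range(n_sites):
        vals = alleles[a, k]
        zeros = np.flatnonzero(vals == 0)
        ones = np.flatnonzero(vals != 0)

        def _group(idx):
            # segment maxima of d over (previous group member, this one]
            if idx.size == 0:
                return idx.astype(np.int32)
            starts = np.empty(idx.size, dtype=np.intp)
            starts[0] = 0
            starts[1:] = idx[:-1] + 1
            seg = np.maximum.reduceat(d[: idx[-1] + 1], starts)
            seg = seg.astype(np.int32, copy=False)
            seg[0] = k + 1  # sentinel: first of group has no predecessor
            return seg

        d = np.concatenate([_group(zeros), _group(ones)])
        a = np.concatenate([a[zeros], a[ones]])
        A[k + 1], D[k + 1] = a, d
    return PbwtArrays(A, D)


@dataclass
class MshObservation:
    """Per-copy msh tract endpoints in both directions.

    ``msh5_bp``/``msh3_bp`` are tract lengths (bp) from the focal base on
    each side (see the module docstring for the two endpoint
    conventions; ``term*_pos`` is the endpoint used); when a side is
    truncated
    (``trunc5``/``trunc3``) the distance runs to the chromosome bound and
    ``term*_pos`` is None.  ``partner*`` is the lowest-index chromosome row
    realizing the tract (ties broken to the lowest row; the two directions
    may be realized against different chromosomes).
    """

    row: int
    focal_pos: int
    msh5_bp: float
    trunc5: bool
    term5_pos: int | None
    msh3_bp: float
    trunc3: bool
    term3_pos: int | None
    partner5: int | None = None
    partner3: int | None = None
    k: int = 1
    site_index: int | None = None

    def __post_init__(self) -> None:
        if self.msh5_bp < 0 or self.msh3_bp < 0:
            raise ValueError("msh distances must be >= 0")


def _scan_direction(a_col, d_col, j, allowed):
    """Best (smallest) match start against any allowed row, scanning both
    ways from sorted position ``j``.  Returns (start, partner_row) or None.
    """
    n = a_col.size
    best = None
    run = 0
    for i in range(j - 1, -1, -1):
        if d_col[i + 1] > run:
            run = d_col[i + 1]
        if allowed[a_col[i]]:
            best = (run, int(a_col[i]))
            break
    run = 0
    for i in range(j + 1, n):
        if d_col[i] > run:
            run = d_col[i]
        if allowed[a_col[i]]:
            if best is None or run < best[0] or \
                    (run == best[0] and a_col[i] < best[1]):
                best = (run, int(a_col[i]))
            break
    return best


def _msh_from_pbwt(matrix, fwd: PbwtArrays, rev: PbwtArrays,
                   row: int, pos: int, allowed: np.ndarray,
                   site_index=None, k=1,
                   convention: str = "mismatch") -> MshObservation:
    if convention not in ("match", "mismatch"):
        raise ValueError("convention must be 'match' or 'mismatch'")
    positions = matrix.positions
    n_sites = matrix.n_sites
    col_f = int(np.searchsorted(positions, pos, side="left"))
    col_r = n_sites - int(np.searchsorted(positions, pos, side="right"))

    a_col, d_col = fwd.a[col_f], fwd.d[col_f]
    j = int(np.flatnonzero(a_col == row)[0])
    hit = _scan_direction(a_col, d_col, j, allowed)
    if hit is None or hit[0] == 0:
        trunc5, term5 = True, None
        msh5 = pos - matrix.start_bp
        partner5 = None if hit is None else hit[1]
    else:
        s, partner5 = hit
        trunc5 = False
        if convention == "mismatch":
            term5 = int(positions[s - 1])
        else:
            term5 = int(positions[s]) if s < col_f else pos
        msh5 = pos - term5

    a_col, d_col = rev.a[col_r], rev.d[col_r]
    j = int(np.flatnonzero(a_col == row)[0])
    hit = _scan_direction(a_col, d_col, j, allowed)
    if hit is None or hit[0] == 0:
        trunc3, term3 = True, None
        msh3 = matrix.end_bp - pos
        partner3 = None if hit is None else hit[1]
    else:
        s, partner3 = hit
        trunc3 = False
        if convention == "mismatch":
            term3 = int(positions[n_sites - s])
        else:
            term3 = int(positions[n_sites - 1 - s]) if s < col_r else pos
        msh3 = term3 - pos

    return MshObservation(row=row, focal_pos=int(pos),
                          msh5_bp=float(msh5), trunc5=trunc5, term5_pos=term5,
                          msh3_bp=float(msh3), trunc3=trunc3, term3_pos=term3,
                          partner5=partner5, partner3=partner3,
                          k=k, site_index=site_index)


def msh_singleton(matrix: HaplotypeMatrix, fwd: PbwtArrays, rev: PbwtArrays,
                  focal_row: int, site: int,
                  convention: str = "mismatch") -> MshObservation:
    """msh tracts for a singleton carrier at one of the matrix columns."""
    if matrix.alleles[focal_row, site] != 1:
        raise ValueError(f"row {focal_row} does not carry site {site}")
    allowed = np.ones(matrix.n_rows, dtype=bool)
    allowed[focal_row] = False
    return _msh_from_pbwt(matrix, fwd, rev, focal_row,
                          int(matrix.positions[site]), allowed,
                          site_index=site, k=1, convention=convention)


def msh_at_position(matrix: HaplotypeMatrix, fwd: PbwtArrays, rev: PbwtArrays,
                    row: int, pos: int, exclude_rows=(),
                    convention: str = "mismatch") -> MshObservation:
    """msh tracts for an arbitrary focal base (need not be a variant)."""
    allowed = np.ones(matrix.n_rows, dtype=bool)
    allowed[row] = False
    for r in exclude_rows:
        allowed[r] = False
    return _msh_from_pbwt(matrix, fwd, rev, row, int(pos), allowed,
                          convention=convention)


def msh_multicopy(matrix: HaplotypeMatrix, fwd: PbwtArrays, rev: PbwtArrays,
                  site: int, carriers=None,
                  convention: str = "mismatch") -> list[MshObservation]:
    """One msh observation per carrier of a k-copy variant.

    Each direction is independently maximized over all non-carriers.
    """
    if carriers is None:
        carriers = np.flatnonzero(matrix.alleles[:, site])
    carriers = np.asarray(carriers, dtype=np.int64)
    k = carriers.size
    if k >= matrix.n_rows:
        raise ValueError("variant has no non-carrier to compare against")
    allowed = np.ones(matrix.n_rows, dtype=bool)
    allowed[carriers] = False
    pos = int(matrix.positions[site])
    return [_msh_from_pbwt(matrix, fwd, rev, int(r), pos, allowed,
                           site_index=site, k=k, convention=convention)
            for r in carriers]


def brute_force_msh(matrix: HaplotypeMatrix, row: int, site: int,
                    exclude_rows=(), ignore_sites=(),
                    convention: str = "mismatch") -> MshObservation:
    """Direct O(rows x sites) oracle for the PBWT extraction path.

    Compares the focal row against every allowed row, recording the longest
    identity tract on each side of the focal site's position.  The focal
    column itself and any ``ignore_sites`` columns never terminate tracts.
    """
    if convention not in ("match", "mismatch"):
        raise ValueError("convention must be 'match' or 'mismatch'")
    alleles = matrix.alleles
    positions = matrix.positions
    pos = int(positions[site])
    skip = set(ignore_sites)
    skip.add(site)
    excluded = set(exclude_rows)
    excluded.add(row)

    best5 = best3 = None  # (mismatch site index or -1/n_sites, partner row)
    for r in range(matrix.n_rows):
        if r in excluded:
            continue
        mis5 = -1
        for j in range(site - 1, -1, -1):
            if j in skip:
                continue
            if alleles[row, j] != alleles[r, j]:
                mis5 = j
                break
        mis3 = matrix.n_sites
        for j in range(site + 1, matrix.n_sites):
            if j in skip:
                continue
            if alleles[row, j] != alleles[r, j]:
                mis3 = j
                break
        if best5 is None or mis5 < best5[0]:
            best5 = (mis5, r)
        if best3 is None or mis3 > best3[0]:
            best3 = (mis3, r)

    if best5 is None:
        raise ValueError("no comparison row available")
    mis5, p5 = best5
    mis3, p3 = best3
    if mis5 < 0:
        trunc5, term5, msh5 = True, None, pos - matrix.start_bp
    else:
        trunc5 = False
        if convention == "mismatch":
            term5 = int(positions[mis5])
        else:
            start = next((j for j in range(mis5 + 1, site)
                          if j not in skip), None)
            term5 = int(positions[start]) if start is not None else pos
        msh5 = pos - term5
    if mis3 >= matrix.n_sites:
        trunc3, term3, msh3 = True, None, matrix.end_bp - pos
    else:
        trunc3 = False
        if convention == "mismatch":
            term3 = int(positions[mis3])
        else:
            start = next((j for j in range(mis3 - 1, site, -1)
                          if j not in skip), None)
            term3 = int(positions[start]) if start is not None else pos
        msh3 = term3 - pos
    return MshObservation(row=row, focal_pos=pos,
                          msh5_bp=float(msh5), trunc5=trunc5, term5_pos=term5,
                          msh3_bp=float(msh3), trunc3=trunc3, term3_pos=term3,
                          partner5=p5, partner3=p3, site_index=site)


def extract_msh_all(matrix: HaplotypeMatrix, records,
                    include_masked=False, convention: str = "mismatch"):
    """msh observations for every copy of every (unmasked) variant.

    Returns a list parallel to ``records``; each element is the list of
    per-carrier MshObservations for that variant (empty for skipped
    records).  Builds one forward and one reverse PBWT and reuses them.
    """
    fwd = build_pbwt(matrix.alleles)
    rev = build_pbwt(matrix.alleles[:, ::-1])
    out = []
    allowed = np.empty(matrix.n_rows, dtype=bool)
    for rec in records:
        if rec.masked and not include_masked:
            out.append([])
            continue
        if rec.k == 0 or rec.k >= matrix.n_rows:
            out.append([])
            continue
        allowed[:] = True
        allowed[rec.carriers] = False
        pos = int(matrix.positions[rec.site_index])
        out.append([
            _msh_from_pbwt(matrix, fwd, rev, int(r), pos, allowed,
                           site_index=rec.site_index, k=rec.k,
                           convention=convention)
            for r in rec.carriers])
    return out
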