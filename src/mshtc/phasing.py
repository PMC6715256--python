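"""Singleton phasing by the dual-t_c rule.

For a diploid individual heterozygous at a singleton site, the variant sits
on one of the two chromosomes.  The chromosome carrying it has had a
mutation since its first coalescent time t_c; the other has not since its
own first coalescent time t_c*.  Because mutation probability is
proportional to branch length, assigning the singleton to the chromosome
with the larger estimated t_c is correct with probability
t_c / (t_c + t_c*).  Operationally the larger t_c belongs to the
chromosome with the *shorter* msh tracts.

All singleton columns are masked during msh extraction (they are exactly
the columns whose phase is in doubt); each decision is made independently
against the masked matrix and assignments are committed afterwards, so the
result does not depend on processing order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genetic_map import compose_chi
from .haplotype_io import HaplotypeMatrix
from .likelihood import EstimationParams, estimate_tc
from .pbwt import build_pbwt, msh_at_position

#: |delta log10 t_c| below which the two assignments are called a tie
#: (below the optimizer tolerance scale).
TIE_TOL_LOG10 = 1e-3


def phase_confidence(tc: float, tc_star: float) -> float:
    """Probability the larger-t_c assignment is correct."""
    if tc <= 0 or tc_star <= 0:
        raise ValueError("t_c values must be positive")
    return max(tc, tc_star) / (tc + tc_star)


@dataclass
class PhaseDecision:
    """Outcome of phasing one heterozygous singleton."""

    individual: int
    site_index: int
    pos: int
    chosen_row: int
    other_row: int
    tc_chosen: float
    tc_other: float
    confidence: float
    msh_ratio: float
    tie: bool = False


@dataclass
class _PhasingWorkspace:
    """Singleton-masked matrix plus its PBWT indexes, built once."""

    masked: HaplotypeMatrix
    fwd: object
    rev: object


def _build_workspace(matrix: HaplotypeMatrix, records) -> _PhasingWorkspace:
    singleton_sites = [r.site_index for r in records if r.k == 1]
    masked = matrix.drop_sites(singleton_sites) if singleton_sites else matrix
    return _PhasingWorkspace(masked, build_pbwt(masked.alleles),
                             build_pbwt(masked.alleles[:, ::-1]))


def _candidate_tc(ws: _PhasingWorkspace, row: int, pos: int,
                  params: EstimationParams):
    obs = msh_at_position(ws.masked, ws.fwd, ws.rev, row, pos)
    est = estimate_tc([obs], params)
    stat = compose_chi(obs, params.gmap, params.mu,
                       params.start_bp, params.end_bp)
    gp = params.gmap.genetic_position
    # genetic tract length (Morgans), truncated sides measured to the bound
    g5 = abs(gp(pos) - gp(obs.term5_pos if obs.term5_pos is not None
                          else ws.masked.start_bp))
    g3 = abs(gp(obs.term3_pos if obs.term3_pos is not None
                else ws.masked.end_bp) - gp(pos))
    return est, stat, g5 + g3


def phase_singleton(matrix: HaplotypeMatrix, individual: int, site: int,
                    params: EstimationParams, records=None,
                    _workspace: _PhasingWorkspace | None = None,
                    commit: bool = True) -> PhaseDecision:
    """Assign one heterozygous singleton to the higher-t_c chromosome.

    ``individual`` indexes the diploid sample (rows 2i and 2i+1).  Ties
    (|delta log10 t_c| < 1e-3) go to the first chromosome of the pair and
    are flagged.  With ``commit=True`` the matrix column is updated in
    place.
    """
    if matrix.ploidy != 2:
        raise ValueError("singleton phasing requires diploid data")
    col = matrix.alleles[:, site]
    carriers = np.flatnonzero(col)
    if carriers.size != 1:
        raise ValueError(f"site {site} is not a singleton (k={carriers.size})")
    rows = (2 * individual, 2 * individual + 1)
    if carriers[0] not in rows:
        raise ValueError(
            f"individual {individual} is not the carrier at site {site}")
    if _workspace is None:
        if records is None:
            from .haplotype_io import records_from_matrix
            records = records_from_matrix(matrix)
        _workspace = _build_workspace(matrix, records)

    params = replace(params,
                     start_bp=params.start_bp or _workspace.masked.start_bp,
                     end_bp=params.end_bp or _workspace.masked.end_bp)
    pos = int(matrix.positions[site])
    est_a, _, glen_a = _candidate_tc(_workspace, rows[0], pos, params)
    est_b, _, glen_b = _candidate_tc(_workspace, rows[1], pos, params)

    tie = abs(np.log10(est_a.tc) - np.log10(est_b.tc)) < TIE_TOL_LOG10
    if tie or est_a.tc >= est_b.tc:
        chosen, other = rows[0], rows[1]
        tc_c, tc_o = est_a.tc, est_b.tc
    else:
        chosen, other = rows[1], rows[0]
        tc_c, tc_o = est_b.tc, est_a.tc
    glo, ghi = sorted((max(glen_a, 0.0), max(glen_b, 0.0)))
    ratio = np.inf if glo == 0 else ghi / glo
    decision = PhaseDecision(
        individual=individual, site_index=site, pos=pos,
        chosen_row=chosen, other_row=other,
        tc_chosen=float(tc_c), tc_other=float(tc_o),
        confidence=0.5 if tie else phase_confidence(tc_c, tc_o),
        msh_ratio=float(ratio), tie=tie)
    if commit and carriers[0] != chosen:
        matrix.alleles[chosen, site] = 1
        matrix.alleles[other, site] = 0
    return decision


def phase_all_singletons(matrix: HaplotypeMatrix, records,
                         params: EstimationParams):
    """Phase every heterozygous singleton of a diploid matrix.

    Decisions are computed independently against the singleton-masked
    matrix, then committed together (order-invariant).  Returns the list
    of PhaseDecisions; the matrix is updated in place and record carrier
    lists are refreshed.
    """
    ws = _build_workspace(matrix, records)
    decisions = []
    for rec in records:
        if rec.k != 1 or rec.masked:
            continue
        individual = int(rec.carriers[0]) // 2
        decisions.append(phase_singleton(
            matrix, individual, rec.site_index, params,
            records=records, _workspace=ws, commit=False))
    for dec in decisions:
        matrix.alleles[dec.chosen_row, dec.site_index] = 1
        matrix.alleles[dec.other_row, dec.site_index] = 0
    for rec in records:
        if rec.k == 1:
            rec.carriers = np.flatnonzero(matrix.alleles[:, rec.site_index])
    return decisions
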