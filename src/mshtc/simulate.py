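"""Coalescent simulation harness: generate samples with recorded
genealogies, read per-variant truth, and score the estimator.

Three demographic scenarios mirror the validation conditions of the
method: a constant diploid population of N = 1e4; recent exponential
growth from N_a = 1e4 to N = 5e5 over the 200 generations before
sampling; and samples drawn from the European deme of the Gutenkunst
et al. (2009) out-of-Africa model.  Mutation uses a binary (0/1) model on
a discrete genome; sites hit by more than one mutation are dropped so
every retained variant has a single origin.

With single-origin mutations, the first coalescence of any carrier's
lineage with a lineage outside the carrier set is the parent node of the
edge the mutation sits on, so all k copies of a variant share one true
t_c, read directly from the tree sequence.  phi is the length of the
sister edge below that node.

Accuracy metrics follow the estimator's conventions: RMSE and mean signed
error (bias) of log10-transformed t_c, and Pearson's r between true and
estimated log10 values, overall and stratified by allele frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import GeneticMap
from .haplotype_io import HaplotypeMatrix, VariantRecord
from .likelihood import EstimationParams, estimate_all

GROWTH_DURATION = 200       # generations of recent growth
GROWTH_N_FINAL = 5e5
GROWTH_N_ANCESTRAL = 1e4
CONSTANT_N = 1e4


def _demography_constant(N=CONSTANT_N):
    import msprime

    demog = msprime.Demography()
    demog.add_population(name="pop0", initial_size=N)
    return demog, "pop0"


def _demography_growth(Na=GROWTH_N_ANCESTRAL, Nf=GROWTH_N_FINAL,
                       duration=GROWTH_DURATION):
    import msprime

    rate = math.log(Nf / Na) / duration
    demog = msprime.Demography()
    demog.add_population(name="pop0", initial_size=Nf, growth_rate=rate)
    demog.add_population_parameters_change(
        time=duration, population="pop0", initial_size=Na, growth_rate=0.0)
    return demog, "pop0"


def _demography_out_of_africa():
    """Gutenkunst et al. (2009) three-population model; sample Europeans.

    Times converted at 25 years/generation; migration rates are per
    generation.
    """
    import msprime

    T_AF = 220e3 / 25
    T_B = 140e3 / 25
    T_EU_AS = 21.2e3 / 25
    r_EU, r_AS = 0.004, 0.0055
    N_A, N_AF, N_B = 7300, 12300, 2100
    N_EU0, N_AS0 = 1000, 510
    N_EU = N_EU0 * math.exp(r_EU * T_EU_AS)
    N_AS = N_AS0 * math.exp(r_AS * T_EU_AS)

    demog = msprime.Demography()
    demog.add_population(name="AFR", initial_size=N_AF)
    demog.add_population(name="EUR", initial_size=N_EU, growth_rate=r_EU)
    demog.add_population(name="EAS", initial_size=N_AS, growth_rate=r_AS)
    demog.add_population(name="B", initial_size=N_B)
    demog.add_population(name="ANC", initial_size=N_A)
    demog.set_symmetric_migration_rate(["AFR", "EUR"], 3e-5)
    demog.set_symmetric_migration_rate(["AFR", "EAS"], 1.9e-5)
    demog.set_symmetric_migration_rate(["EUR", "EAS"], 9.6e-5)
    demog.add_population_split(time=T_EU_AS, derived=["EUR", "EAS"],
                               ancestral="B")
    demog.add_symmetric_migration_rate_change(
        time=T_EU_AS, populations=["AFR", "B"], rate=25e-5)
    demog.add_population_split(time=T_B, derived=["B"], ancestral="AFR")
    demog.add_population_parameters_change(
        time=T_AF, population="AFR", initial_size=N_A)
    return demog, "EUR"


_DEMOGRAPHIES = {
    "constant": _demography_constant,
    "growth": _demography_growth,
    "out_of_africa": _demography_out_of_africa,
}


@dataclass
class SimulatedSample:
    """Haplotype matrix with its generating tree sequence and truth table."""

    matrix: HaplotypeMatrix
    records: list
    ts: object
    truth: pd.DataFrame  # site, pos, k, tc_true, phi_true


def simulate_sample(demography="constant", n=100, L_bp=2_000_000,
                    mu=1e-8, rho=1e-8, seed=1) -> SimulatedSample:
    """Simulate n phased chromosomes over L_bp with recorded genealogy.

    ``demography`` is one of 'constant', 'growth', 'out_of_africa' or a
    prebuilt ``(msprime.Demography, population_name)`` pair.  ``n`` must be
    even (n/2 diploid individuals).  Deterministic for a given seed.
    """
    import msprime

    if n < 2 or L_bp < 1:
        raise ValueError("need n >= 2 and L_bp >= 1")
    if isinstance(demography, str):
        try:
            demog, pop = _DEMOGRAPHIES[demography]()
        except KeyError:
            raise ValueError(f"unknown demography {demography!r}") from None
    else:
        demog, pop = demography
    ts = msprime.sim_ancestry(
        samples={pop: n // 2}, demography=demog, sequence_length=L_bp,
        recombination_rate=rho, ploidy=2, random_seed=seed)
    ts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(),
        random_seed=seed + 1, discrete_genome=True)
    return _sample_from_ts(ts, n)


def _sample_from_ts(ts, n) -> SimulatedSample:
    keep_sites = np.array([len(s.mutations) == 1 for s in ts.sites()],
                          dtype=bool)
    if ts.num_sites and keep_sites.any():
        G = ts.genotype_matrix()[keep_sites].astype(np.uint8)
        positions = ts.sites_position[keep_sites].astype(np.int64) + 1
    else:
        G = np.zeros((0, n), dtype=np.uint8)
        positions = np.zeros(0, dtype=np.int64)

    # polymorphic in the sample (mutations above unary nodes can fix)
    counts = G.sum(axis=1)
    poly = (counts > 0) & (counts < n)
    G, positions = G[poly], positions[poly]

    matrix = HaplotypeMatrix(
        alleles=G.T, positions=positions,
        chrom_label="sim", sample_ids=[f"ind{i}" for i in range(n // 2)],
        chrom_start_bp=1, chrom_length_bp=int(ts.sequence_length))
    records = []
    for site, pos in enumerate(positions):
        carriers = np.flatnonzero(matrix.alleles[:, site])
        records.append(VariantRecord(site_index=site, pos=int(pos),
                                     ref="A", alt="T", k=int(carriers.size),
                                     carriers=carriers))

    truth = _truth_table(ts, positions, keep=set(positions.tolist()))
    truth = truth.set_index("pos").loc[positions].reset_index()
    truth["site"] = np.arange(len(truth))
    truth["k"] = [r.k for r in records]
    return SimulatedSample(matrix=matrix, records=records, ts=ts, truth=truth)


def _truth_table(ts, positions, keep) -> pd.DataFrame:
    node_time = ts.tables.nodes.time
    rows = []
    for tree in ts.trees():
        for site in tree.sites():
            pos = int(site.position) + 1
            if pos not in keep or len(site.mutations) != 1:
                continue
            child = site.mutations[0].node
            parent = tree.parent(child)
            sibs = [c for c in tree.children(parent) if c != child]
            phi = float(node_time[parent] -
                        max(node_time[c] for c in sibs)) if sibs else \
                float(node_time[parent])
            rows.append((pos, float(node_time[parent]), phi))
    return pd.DataFrame(rows, columns=["pos", "tc_true", "phi_true"])


def true_tc_phi(ts, focal_row, position, carriers=None):
    """(t_c, phi) for a focal chromosome at a position, from the genealogy.

    t_c is the time of the first node on the focal leaf's ancestral path
    whose subtree contains a leaf outside ``carriers`` (default: just the
    focal leaf); phi is the length of the sister edge below that node.
    When the sister subtree is a single leaf, phi equals t_c.
    """
    carriers = {focal_row} if carriers is None else set(carriers)
    tree = ts.at(position)
    node_time = ts.tables.nodes.time
    u = focal_row
    while True:
        p = tree.parent(u)
        if p == -1:
            raise ValueError("focal lineage never meets a non-carrier")
        if any(s not in carriers for s in tree.samples(p)):
            break
        u = p
    sibs = [c for c in tree.children(p) if c != u]
    tc = float(node_time[p])
    phi = tc - max(float(node_time[c]) for c in sibs) if sibs else tc
    return tc, phi


def extract_xas(ts, focal_row, position, window=None, site_positions=None):
    """Distances to the nearest mutation on branch A or S, per direction.

    Branch A is the focal leaf's edge, branch S the sister edge below
    their common node (singleton geometry; intended for recombination-free
    genealogies where edges span the whole window).  Censored distances
    (no qualifying mutation before the window bound) are flagged.
    ``site_positions`` restricts to mutations at assayed sites (so the
    bound is comparable to an msh measured on a filtered matrix).

    Returns ``(xas5, censored5, xas3, censored3)`` in bp.
    """
    tree = ts.at(position)
    parent = tree.parent(focal_row)
    sibs = [c for c in tree.children(parent) if c != focal_row]
    branch_nodes = np.array([focal_row, *sibs])
    mut_nodes = ts.tables.mutations.node
    mut_pos = ts.sites_position[ts.tables.mutations.site]
    on_branch = np.isin(mut_nodes, branch_nodes) & (mut_pos != position)
    if site_positions is not None:
        on_branch &= np.isin(mut_pos, np.asarray(site_positions))
    xs = mut_pos[on_branch]
    left = position - xs[xs < position]
    right = xs[xs > position] - position
    lo, hi = (0, ts.sequence_length) if window is None else window
    xas5, cens5 = (left.min(), False) if left.size else (position - lo, True)
    xas3, cens3 = (right.min(), False) if right.size else (hi - position, True)
    return float(xas5), cens5, float(xas3), cens3


def prob_msh_not_xas(tc, phi):
    """Probability that the msh falls short of x_AS for a two-sister clade.

    Closed form (phi - t_c)^2 / (t_c (3 t_c - phi)): the chance that two
    independent exponentials with rate mu (t_c - phi) both fall below
    x_AS.  Equals 1/3 at phi = 0, 1/10 at phi = t_c/2, and tends to 0 as
    phi -> t_c.
    """
    tc = np.asarray(tc, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(tc <= 0) or np.any(phi < 0) or np.any(phi > tc):
        raise ValueError("need 0 <= phi <= tc, tc > 0")
    out = (phi - tc) ** 2 / (tc * (3.0 * tc - phi))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# scoring


@dataclass
class PerformanceReport:
    """log10-scale accuracy metrics, overall and by frequency stratum."""

    rmse: float
    bias: float
    r: float
    n_variants: int
    strata: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(stratum="all", rmse=self.rmse, bias=self.bias,
                     r=self.r, n=self.n_variants)]
        rows += [dict(stratum=name, **vals)
                 for name, vals in self.strata.items()]
        return pd.DataFrame(rows)


def _metrics(err, lt, le):
    rmse = float(np.sqrt(np.mean(err ** 2)))
    bias = float(np.mean(err))
    r = float(np.corrcoef(lt, le)[0, 1]) if lt.size > 1 else np.nan
    return rmse, bias, r


def evaluate(estimates, truths, k=None, n_sample=None,
             scenario=None) -> PerformanceReport:
    """Score estimated against true t_c values (natural scale inputs).

    RMSE and bias are computed on log10(t_c); r is Pearson's correlation
    of the log10 values.  With ``k`` and ``n_sample`` given, metrics are
    also reported for the <=10%, <=1% and singleton frequency strata.
    """
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.size == 0 or est.size != tru.size:
        raise ValueError("need matched, non-empty estimate/truth arrays")
    le, lt = np.log10(est), np.log10(tru)
    err = le - lt
    rmse, bias, r = _metrics(err, lt, le)
    report = PerformanceReport(rmse=rmse, bias=bias, r=r,
                               n_variants=int(est.size),
                               scenario=scenario or {})
    if k is not None and n_sample is not None:
        k = np.asarray(k)
        for name, mask in [("le10pct", k <= 0.10 * n_sample),
                           ("le1pct", k <= 0.01 * n_sample),
                           ("singleton", k == 1)]:
            if mask.any():
                s_rmse, s_bias, s_r = _metrics(err[mask], lt[mask], le[mask])
                report.strata[name] = dict(rmse=s_rmse, bias=s_bias,
                                           r=s_r, n=int(mask.sum()))
    return report


def frequency_comparator(tc_true, k) -> pd.DataFrame:
    """Idealized frequency-based estimate tau_k per allele-count class.

    tau_k is the mean of the true log10(t_c) over variants at frequency k
    (the least-squares minimizer), the best any estimator that sees only
    allele frequency can do.  Within a single frequency class it explains
    zero variance by construction (r2_freq = 0).
    """
    df = pd.DataFrame({"k": np.asarray(k),
                       "log10_tc": np.log10(np.asarray(tc_true, dtype=float))})
    if df.empty:
        raise ValueError("empty truth set")
    out = df.groupby("k")["log10_tc"].agg(tau="mean", n="size").reset_index()
    out["r2_freq"] = 0.0
    return out


def r2_by_frequency(tc_true, tc_est, k) -> pd.DataFrame:
    """Within-class r^2 of the msh estimator next to the comparator's 0."""
    df = pd.DataFrame({"k": np.asarray(k),
                       "lt": np.log10(np.asarray(tc_true, dtype=float)),
                       "le": np.log10(np.asarray(tc_est, dtype=float))})
    rows = []
    for kk, grp in df.groupby("k"):
        r2 = np.corrcoef(grp["lt"], grp["le"])[0, 1] ** 2 \
            if len(grp) > 1 and grp["lt"].std() > 0 and grp["le"].std() > 0 \
            else np.nan
        rows.append(dict(k=int(kk), n=len(grp), r2_msh=r2, r2_freq=0.0))
    return pd.DataFrame(rows)


def run_recovery(demography="constant", n=100, L_bp=2_000_000, mu=1e-8,
                 rho=1e-8, seeds=(1,), N0=CONSTANT_N,
                 params: EstimationParams | None = None):
    """Simulate, estimate every variant with known phase, and pair with
    truth.  Returns (pairs DataFrame, PerformanceReport)."""
    frames = []
    for seed in seeds:
        sim = simulate_sample(demography=demography, n=n, L_bp=L_bp,
                              mu=mu, rho=rho, seed=seed)
        p = params or EstimationParams(mu=mu, gmap=GeneticMap.uniform(rho),
                                       n=n, N0=N0)
        est = estimate_all(sim.matrix, sim.records, p, pooled=True)
        merged = est.merge(sim.truth[["site", "tc_true", "phi_true"]],
                           on="site")
        merged["seed"] = seed
        frames.append(merged)
    pairs = pd.concat(frames, ignore_index=True)
    report = evaluate(pairs["tc_hat"], pairs["tc_true"], k=pairs["k"],
                      n_sample=n,
                      scenario=dict(demography=str(demography), n=n,
                                    L_bp=L_bp, mu=mu, rho=rho,
                                    seeds=list(seeds)))
    return pairs, report


def phasing_experiment(demography="constant", n=100, L_bp=2_000_000,
                       mu=1e-8, rho=1e-8, seed=1, N0=CONSTANT_N):
    """Scramble singleton assignments in a simulated diploid sample,
    re-phase them by the dual-t_c rule, and score against the truth.

    Non-singleton variants keep their true phase (emulating data whose
    common variants were phased correctly).  Returns a DataFrame with one
    row per singleton: msh_ratio (longer/shorter genetic tract length),
    correct (bool), tie flag and confidence.
    """
    from .haplotype_io import records_from_matrix
    from .phasing import phase_all_singletons

    sim = simulate_sample(demography=demography, n=n, L_bp=L_bp, mu=mu,
                          rho=rho, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    original = sim.matrix.alleles.copy()
    singleton_sites = [r.site_index for r in sim.records if r.k == 1]
    scrambled = scramble_phase(sim.matrix, rng, sites=singleton_sites)
    records = records_from_matrix(scrambled)
    params = EstimationParams(mu=mu, gmap=GeneticMap.uniform(rho),
                              n=n, N0=N0)
    decisions = phase_all_singletons(scrambled, records, params)
    rows = []
    for dec in decisions:
        true_row = int(np.flatnonzero(original[:, dec.site_index])[0])
        rows.append(dict(site=dec.site_index, pos=dec.pos,
                         msh_ratio=dec.msh_ratio,
                         correct=dec.chosen_row == true_row,
                         tie=dec.tie, confidence=dec.confidence,
                         tc_chosen=dec.tc_chosen, tc_other=dec.tc_other))
    return pd.DataFrame(rows)


def scramble_phase(matrix: HaplotypeMatrix, rng,
                   sites=None) -> HaplotypeMatrix:
    """Randomize the chromosome assignment at heterozygous sites of every
    diploid individual (keeps genotypes).

    ``sites`` restricts scrambling to those columns; the default scrambles
    every site.  Scrambling only the singleton columns emulates data whose
    non-singleton variants were phased correctly (as statistical phasing
    largely achieves) while singleton placement is unknown.
    """
    alleles = matrix.alleles.copy()
    touch = np.zeros(matrix.n_sites, dtype=bool)
    if sites is None:
        touch[:] = True
    else:
        touch[np.asarray(list(sites), dtype=int)] = True
    n_ind = matrix.n_rows // 2
    for i in range(n_ind):
        a, b = alleles[2 * i], alleles[2 * i + 1]
        het = (a != b) & touch
        flip = het & (rng.random(a.size) < 0.5)
        a[flip], b[flip] = b[flip].copy(), a[flip].copy()
    out = HaplotypeMatrix(alleles=alleles, positions=matrix.positions.copy(),
                          chrom_label=matrix.chrom_label,
                          sample_ids=list(matrix.sample_ids),
                          chrom_start_bp=matrix.chrom_start_bp,
                          chrom_length_bp=matrix.chrom_length_bp,
                          ploidy=matrix.ploidy)
    return out
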