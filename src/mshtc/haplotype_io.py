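"""Phased haplotype input/output and site filtering.

Reads a phased VCF (one chromosome at a time) into a binary haplotype
matrix whose rows are chromosomes and whose columns are ordered biallelic
SNP sites, applies CpG-transition masking, and exposes per-variant carrier
lists.  All physical coordinates are 1-based (VCF POS convention) and
distances are simple base-pair differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class HaplotypeIOError(ValueError):
    """Raised for malformed or unsupported genotype input."""


@dataclass
class HaplotypeMatrix:
    """Binary haplotype alignment: rows are chromosomes, columns are sites.

    Parameters
    ----------
    alleles
        uint8 array of shape (n_rows, n_sites); 0 = ancestral/reference,
        1 = derived/alternate.
    positions
        1-based physical position of each site, strictly increasing.
    chrom_label
        Chromosome identifier.
    sample_ids
        One identifier per individual; with ``ploidy == 2`` individual ``i``
        owns rows ``2i`` and ``2i + 1``.
    chrom_start_bp, chrom_length_bp
        Physical bounds used for end-of-chromosome distances.  When absent
        they default to the first and last variant positions: beyond the
        outermost observed variants no mismatch is observable anyway.
    """

    alleles: np.ndarray
    positions: np.ndarray
    chrom_label: str = "1"
    sample_ids: list[str] = field(default_factory=list)
    chrom_start_bp: int | None = None
    chrom_length_bp: int | None = None
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise HaplotypeIOError("alleles must be a 2-D (rows x sites) array")
        if self.alleles.shape[1] != self.positions.size:
            raise HaplotypeIOError("positions length must equal number of sites")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise HaplotypeIOError("positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise HaplotypeIOError("allele values must be 0 or 1")

    @property
    def n_rows(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def start_bp(self) -> int:
        if self.chrom_start_bp is not None:
            return int(self.chrom_start_bp)
        return int(self.positions[0]) if self.positions.size else 1

    @property
    def end_bp(self) -> int:
        if self.chrom_length_bp is not None:
            return int(self.chrom_length_bp)
        return int(self.positions[-1]) if self.positions.size else 1

    def drop_sites(self, site_indices) -> "HaplotypeMatrix":
        keep = np.ones(self.n_sites, dtype=bool)
        keep[np.asarray(site_indices, dtype=int)] = False
        return replace(self, alleles=self.alleles[:, keep],
                       positions=self.positions[keep])


@dataclass
class VariantRecord:
    """One retained biallelic SNP: its column, carriers and masking state."""

    site_index: int
    pos: int
    ref: str
    alt: str
    k: int
    carriers: np.ndarray
    masked: bool = False

    def __post_init__(self) -> None:
        self.carriers = np.asarray(self.carriers, dtype=np.int64)
        if self.k != self.carriers.size:
            raise HaplotypeIOError("k must equal the number of carriers")
        if self.carriers.size != np.unique(self.carriers).size:
            raise HaplotypeIOError("carrier indices must be unique")


def variant_carriers(matrix: HaplotypeMatrix, site: int):
    """Return (carrier row indices, derived allele count k) for a column.

    A monomorphic column (k == 0 or k == n_rows) is not a valid estimation
    target; callers should treat it as invalid, but the counts themselves
    are still returned.
    """
    if not 0 <= site < matrix.n_sites:
        raise IndexError(f"site {site} out of range")
    carriers = np.flatnonzero(matrix.alleles[:, site])
    return carriers, int(carriers.size)


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def mask_cpg_transitions(records, context_provider, chrom_label="1"):
    """Flag CpG/TpG transition SNPs, which have elevated mutation rates.

    A C->T SNP whose reference 3' neighbour is G, or a G->A SNP whose
    reference 5' neighbour is C, is flagged ``masked``.  ``context_provider``
    is a callable ``(chrom, pos_1based) -> base``.  Masking is idempotent
    and touches only transition SNPs in CpG context.
    """
    for rec in records:
        ref, alt = rec.ref.upper(), rec.alt.upper()
        if (ref, alt) not in {("C", "T"), ("G", "A")}:
            continue
        try:
            if (ref, alt) == ("C", "T"):
                neighbour = context_provider(chrom_label, rec.pos + 1)
                rec.masked = rec.masked or neighbour.upper() == "G"
            else:
                neighbour = context_provider(chrom_label, rec.pos - 1)
                rec.masked = rec.masked or neighbour.upper() == "C"
        except Exception as exc:  # noqa: BLE001 - re-raise with guidance
            raise HaplotypeIOError(
                f"reference context unavailable at {chrom_label}:{rec.pos}; "
                "supply a reference FASTA or disable CpG masking"
            ) from exc
    return records


class FastaContext:
    """Reference-base lookup backed by an indexed FASTA file."""

    def __init__(self, path: str):
        import pysam

        try:
            self._fasta = pysam.FastaFile(path)
        except OSError:
            pysam.faidx(path)
            self._fasta = pysam.FastaFile(path)

    def __call__(self, chrom: str, pos: int) -> str:
        return self._fasta.fetch(chrom, pos - 1, pos)


def apply_cpg_policy(matrix, records, policy="remove"):
    """Apply the masked-site policy.

    ``remove``
        Masked sites are dropped from the matrix entirely: they neither
        receive estimates nor terminate msh tracts (constant-rate model).
    ``terminator``
        Masked sites stay in the matrix (they still end msh tracts) but are
        skipped as estimation targets.
    """
    if policy == "terminator":
        return matrix, records
    if policy != "remove":
        raise ValueError(f"unknown CpG policy {policy!r}")
    drop = [r.site_index for r in records if r.masked]
    if not drop:
        return matrix, records
    matrix = matrix.drop_sites(drop)
    kept = [r for r in records if not r.masked]
    for new_index, rec in enumerate(kept):
        rec.site_index = new_index
    return matrix, kept


def _is_biallelic_snp(rec) -> bool:
    if rec.alts is None or len(rec.alts) != 1:
        return False
    return len(rec.ref) == 1 and len(rec.alts[0]) == 1 and \
        rec.ref.upper() in "ACGT" and rec.alts[0].upper() in "ACGT"


def read_haplotypes(vcf_source, chrom_label=None, *,
                    biallelic_snps_only=True,
                    missing_policy="error",
                    mask_cpg=False, context=None, cpg_policy="remove",
                    drop_monomorphic=True):
    """Read one chromosome of a phased VCF into a HaplotypeMatrix.

    Multiallelic and non-SNP records are dropped when
    ``biallelic_snps_only`` (otherwise they raise).  Any unphased diploid
    genotype raises, naming the record.  Missing genotypes raise by default;
    ``missing_policy='drop'`` instead removes the affected individual (both
    chromosomes) for the whole chromosome, since dropping single sites
    would distort msh tracts.

    Returns ``(HaplotypeMatrix, list[VariantRecord])`` with matrix columns
    in 1:1 correspondence with the records.
    """
    import pysam

    if missing_policy not in ("error", "drop"):
        raise ValueError("missing_policy must be 'error' or 'drop'")

    with pysam.VariantFile(str(vcf_source)) as vcf:
        samples = list(vcf.header.samples)
        columns, positions, refs, alts = [], [], [], []
        missing_individuals: set[int] = set()
        ploidy = None
        contig_len = None
        for rec in vcf:
            if chrom_label is None:
                chrom_label = rec.chrom
            if rec.chrom != chrom_label:
                continue
            if not _is_biallelic_snp(rec):
                if biallelic_snps_only:
                    continue
                raise HaplotypeIOError(
                    f"non-biallelic-SNP record at {rec.chrom}:{rec.pos}")
            col = []
            for s_idx, name in enumerate(samples):
                sample = rec.samples[name]
                gt = sample["GT"]
                if ploidy is None:
                    ploidy = len(gt)
                if len(gt) != ploidy:
                    raise HaplotypeIOError(
                        f"inconsistent ploidy at {rec.chrom}:{rec.pos}")
                if any(a is None for a in gt):
                    if missing_policy == "error":
                        raise HaplotypeIOError(
                            f"missing genotype for sample {name} at "
                            f"{rec.chrom}:{rec.pos}")
                    missing_individuals.add(s_idx)
                    col.extend([0] * ploidy)
                    continue
                if ploidy > 1 and not sample.phased:
                    raise HaplotypeIOError(
                        f"unphased genotype for sample {name} at "
                        f"{rec.chrom}:{rec.pos}")
                col.extend(int(a > 0) for a in gt)
            columns.append(col)
            positions.append(rec.pos)
            refs.append(rec.ref.upper())
            alts.append(rec.alts[0].upper())
        if chrom_label is not None and chrom_label in vcf.header.contigs:
            contig_len = vcf.header.contigs[chrom_label].length

    if not columns:
        raise HaplotypeIOError(f"no usable records for chromosome {chrom_label}")
    ploidy = ploidy or 2
    alleles = np.asarray(columns, dtype=np.uint8).T  # rows x sites

    if missing_individuals:
        keep_rows = np.ones(alleles.shape[0], dtype=bool)
        for s_idx in missing_individuals:
            keep_rows[s_idx * ploidy:(s_idx + 1) * ploidy] = False
        alleles = alleles[keep_rows]
        samples = [s for i, s in enumerate(samples)
                   if i not in missing_individuals]

    positions = np.asarray(positions, dtype=np.int64)
    keep = np.ones(alleles.shape[1], dtype=bool)
    if drop_monomorphic:
        counts = alleles.sum(axis=0)
        keep &= (counts > 0) & (counts < alleles.shape[0])
    alleles = alleles[:, keep]
    matrix = HaplotypeMatrix(
        alleles=alleles, positions=positions[keep],
        chrom_label=str(chrom_label), sample_ids=samples,
        chrom_length_bp=contig_len, ploidy=ploidy)

    kept_idx = np.flatnonzero(keep)
    records = []
    for new_index, old in enumerate(kept_idx):
        carriers = np.flatnonzero(alleles[:, new_index])
        records.append(VariantRecord(
            site_index=new_index, pos=int(positions[old]),
            ref=refs[old], alt=alts[old], k=int(carriers.size),
            carriers=carriers))
    if mask_cpg:
        if context is None:
            raise HaplotypeIOError(
                "CpG masking requested but no reference context supplied; "
                "pass context=FastaContext(path) or disable masking")
        mask_cpg_transitions(records, context, matrix.chrom_label)
        matrix, records = apply_cpg_policy(matrix, records, cpg_policy)
    return matrix, records


def records_from_matrix(matrix: HaplotypeMatrix, ref="A", alt="T"):
    """Build VariantRecords directly from a matrix (e.g. simulated data)."""
    records = []
    for site in range(matrix.n_sites):
        carriers, k = variant_carriers(matrix, site)
        records.append(VariantRecord(
            site_index=site, pos=int(matrix.positions[site]),
            ref=ref, alt=alt, k=k, carriers=carriers))
    return records


def write_haplotypes(matrix: HaplotypeMatrix, records, path) -> None:
    """Write the matrix back to a phased VCF (round-trip safe)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={matrix.chrom_label},"
                    f"length={max(matrix.end_bp, int(matrix.positions[-1]))}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    n_ind = matrix.n_rows // matrix.ploidy
    sample_ids = matrix.sample_ids or [f"S{i}" for i in range(n_ind)]
    for name in sample_ids:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=matrix.chrom_label, start=rec.pos - 1,
                stop=rec.pos, alleles=(rec.ref, rec.alt))
            col = matrix.alleles[:, rec.site_index]
            for i, name in enumerate(sample_ids):
                gt = tuple(int(col[i * matrix.ploidy + j])
                           for j in range(matrix.ploidy))
                vrec.samples[name]["GT"] = gt
                vrec.samples[name].phased = True
            out.write(vrec)
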