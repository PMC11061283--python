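"""Standard-format I/O and the coordinate conventions shared by every stage.

All internal coordinates are 1-based inclusive (the convention used for the
candidate-region tables this pipeline produces); BED output is 0-based
half-open and the conversion happens in exactly one place,
:func:`write_regions_bed` / :func:`read_regions_bed`.

The central in-memory container is :class:`HaplotypePanel`: a phased
haplotype-by-site 0/1 matrix polarized to an explicit ancestral allele
(0 = ancestral, 1 = derived), two rows per diploid sample.  Missing alleles
are coded -1 and are excluded from every frequency denominator rather than
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscan")

MISSING = -1

ROLE_TARGET = "target"
ROLE_REFERENCE = "reference"
ROLE_OUTGROUP = "outgroup"
ROLE_ARCHAIC = "archaic"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a set of diploid samples.

    Parameters
    ----------
    chrom
        Chromosome label, shared by all sites.
    positions
        1-based physical positions, strictly increasing, one per site.
    H
        ``(2 * n_samples, n_sites)`` int8 matrix; 0 = ancestral allele,
        1 = derived allele, -1 = missing.  Haplotype rows ``2i`` and
        ``2i + 1`` belong to sample ``i``.
    sample_ids
        One identifier per diploid sample.
    populations
        Population label per sample (same length as ``sample_ids``).
    ancestral, derived
        Optional allele strings per site (e.g. "A", "G").
    """

    chrom: str
    positions: np.ndarray
    H: np.ndarray
    sample_ids: list[str]
    populations: list[str]
    ancestral: np.ndarray | None = None
    derived: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.H = np.asarray(self.H, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.populations = list(self.populations)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.H.ndim != 2:
            raise ValueError("H must be 2-dimensional")
        if self.H.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"H has {self.H.shape[0]} rows for {len(self.sample_ids)} samples; "
                "expected two haplotype rows per diploid sample"
            )
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("populations and sample_ids lengths differ")
        if self.H.shape[1] != len(self.positions):
            raise ValueError("H column count does not match positions")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.H, (0, 1, MISSING))
        if bad.any():
            raise ValueError("H entries must be 0, 1 or -1 (missing)")

    # -- basic shape --------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_sites(self) -> int:
        return self.H.shape[1]

    # -- selection helpers --------------------------------------------------
    def sample_indices(self, population: str) -> np.ndarray:
        """Diploid sample indices belonging to ``population``."""
        pops = np.asarray(self.populations)
        return np.flatnonzero(pops == population)

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Haplotype row indices (2 per sample) for ``population``."""
        s = self.sample_indices(population)
        return np.sort(np.concatenate([2 * s, 2 * s + 1]))

    def submatrix(self, population: str) -> np.ndarray:
        return self.H[self.haplotype_rows(population)]

    def take_sites(self, site_idx: np.ndarray) -> "HaplotypePanel":
        """Panel restricted to the given site indices (kept sorted)."""
        site_idx = np.asarray(site_idx)
        return replace(
            self,
            positions=self.positions[site_idx],
            H=self.H[:, site_idx],
            ancestral=None if self.ancestral is None else np.asarray(self.ancestral)[site_idx],
            derived=None if self.derived is None else np.asarray(self.derived)[site_idx],
        )

    def copy(self) -> "HaplotypePanel":
        return replace(
            self,
            positions=self.positions.copy(),
            H=self.H.copy(),
            sample_ids=list(self.sample_ids),
            populations=list(self.populations),
            ancestral=None if self.ancestral is None else np.asarray(self.ancestral).copy(),
            derived=None if self.derived is None else np.asarray(self.derived).copy(),
        )

    # -- frequencies --------------------------------------------------------
    def derived_counts(self, population: str | None = None):
        """Per-site derived-allele count and non-missing allele total.

        Returns ``(k, n)`` arrays; missing alleles reduce ``n`` rather than
        being imputed.
        """
        H = self.H if population is None else self.submatrix(population)
        k = (H == 1).sum(axis=0)
        n = (H != MISSING).sum(axis=0)
        return k, n

    def daf(self, population: str | None = None) -> np.ndarray:
        """Derived allele frequency per site (NaN where all alleles missing)."""
        k, n = self.derived_counts(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, k / np.maximum(n, 1), np.nan)


@dataclass
class PopulationManifest:
    """sample -> population label and pipeline role."""

    table: pd.DataFrame  # columns: sample_id, population, role

    REQUIRED = ("sample_id", "population", "role")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"manifest missing column {col!r}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "PopulationManifest":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples_with_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "sample_id"])

    def populations_with_role(self, role: str) -> list[str]:
        return sorted(self.table.loc[self.table["role"] == role, "population"].unique())

    def population_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["population"].iloc[0]

    def require_scan_roles(self) -> None:
        """A scan run needs non-empty target, reference and outgroup roles."""
        for role in (ROLE_TARGET, ROLE_REFERENCE, ROLE_OUTGROUP):
            if not self.samples_with_role(role):
                raise ValueError(f"manifest has no samples with role {role!r}")


@dataclass(frozen=True)
class Region:
    """A candidate interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    methods: frozenset = field(default_factory=frozenset)
    scores: tuple = ()  # tuple of (method, score) pairs, hashable
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def score_dict(self) -> dict:
        return dict(self.scores)

    @property
    def top_score(self) -> float | None:
        d = self.score_dict()
        return max(d.values()) if d else None


def build_site_table(panel: HaplotypePanel, populations: list[str] | None = None,
                     rsids: list[str] | None = None) -> pd.DataFrame:
    """Per-site summary: position, optional rsid, DAF per population, missingness."""
    if populations is None:
        populations = sorted(set(panel.populations))
    out = {"position": panel.positions}
    if rsids is not None:
        out["rsid"] = rsids
    for pop in populations:
        out[f"daf_{pop}"] = panel.daf(pop)
    out["missingness"] = (panel.H == MISSING).mean(axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, manifest: PopulationManifest, ancestral: dict | None = None,
                    max_missing: float = 0.05) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Read phased biallelic SNPs into a :class:`HaplotypePanel` plus site table.

    Only biallelic SNPs with a per-site missing allele rate <= ``max_missing``
    are retained; multiallelic or non-SNP records are skipped with a logged
    count.  The ancestral allele is taken from the ``AA`` INFO tag or, if
    ``ancestral`` (a position -> allele mapping) is given, from that mapping;
    it is never inferred.  Sites whose ancestral allele matches neither REF
    nor ALT are skipped.

    Raises
    ------
    ValueError
        If a retained sample has an unphased genotype at a retained site, or
        if a manifest sample is absent from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    wanted = [s for s in manifest.table["sample_id"]]
    missing_samples = [s for s in wanted if s not in vcf_samples]
    if missing_samples:
        raise ValueError(f"manifest samples absent from VCF: {missing_samples}")
    col_of = {s: vcf_samples.index(s) for s in wanted}
    cols = np.array([col_of[s] for s in wanted])

    positions, anc_alleles, der_alleles, rsids, rows = [], [], [], [], []
    n_skipped_multi = 0
    n_dropped_missing = 0
    n_skipped_anc = 0
    chrom = None

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped_multi += 1
            continue
        chrom = v.CHROM if chrom is None else chrom
        aa = None
        if ancestral is not None:
            aa = ancestral.get(v.POS)
        else:
            try:
                aa = v.INFO.get("AA")
            except KeyError:
                aa = None
        if aa is None or aa.upper() not in (v.REF.upper(), v.ALT[0].upper()):
            n_skipped_anc += 1
            continue
        # genotype array: (n_samples, 3) = allele1, allele2, phased flag
        g = np.asarray(v.genotype.array())[cols]
        alleles = g[:, :2].astype(np.int8)
        phased = g[:, 2].astype(bool)
        is_missing = alleles < 0
        unphased = ~phased & ~is_missing.all(axis=1)
        if unphased.any():
            bad = wanted[int(np.flatnonzero(unphased)[0])]
            raise ValueError(
                f"unphased genotype for sample {bad!r} at {v.CHROM}:{v.POS}"
            )
        miss_rate = is_missing.mean()
        if miss_rate > max_missing:
            n_dropped_missing += 1
            continue
        hap = alleles.reshape(-1)  # rows 2i, 2i+1 = sample i
        hap = hap.astype(np.int8)
        hap[hap < 0] = MISSING
        if aa.upper() == v.ALT[0].upper():  # ALT is ancestral: flip polarity
            ones = hap == 1
            zeros = hap == 0
            hap[ones] = 0
            hap[zeros] = 1
            anc, der = v.ALT[0], v.REF
        else:
            anc, der = v.REF, v.ALT[0]
        positions.append(v.POS)
        anc_alleles.append(anc)
        der_alleles.append(der)
        rsids.append(v.ID or ".")
        rows.append(hap)

    if n_skipped_multi:
        logger.info("read_phased_vcf: skipped %d non-biallelic-SNP records", n_skipped_multi)
    if n_dropped_missing:
        logger.info("read_phased_vcf: dropped %d sites with missing rate > %.2f",
                    n_dropped_missing, max_missing)
    if n_skipped_anc:
        logger.info("read_phased_vcf: skipped %d sites without a usable ancestral allele",
                    n_skipped_anc)
    if not rows:
        raise ValueError(f"no usable biallelic phased SNPs in {path}")

    H = np.stack(rows, axis=1)  # (2n, S)
    pops = [manifest.population_of(s) for s in wanted]
    panel = HaplotypePanel(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        H=H,
        sample_ids=wanted,
        populations=pops,
        ancestral=np.asarray(anc_alleles),
        derived=np.asarray(der_alleles),
    )
    sites = build_site_table(panel, rsids=rsids)
    return panel, sites


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as a minimal phased VCF 4.2 (REF = ancestral allele)."""
    anc = panel.ancestral if panel.ancestral is not None else np.full(panel.n_sites, "A")
    der = panel.derived if panel.derived is not None else np.full(panel.n_sites, "G")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_sites):
            col = panel.H[:, j]
            gts = []
            for i in range(panel.n_samples):
                a, b = col[2 * i], col[2 * i + 1]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                gts.append(f"{sa}|{sb}")
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\t.\t{anc[j]}\t{der[j]}\t.\tPASS\t"
                f"AA={anc[j]}\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

BED_HEADER = "#chrom\tstart\tend\tmethods\tscore\tpvalue"


def write_regions_bed(regions: list[Region], path) -> None:
    """Write non-overlapping regions as BED (0-based half-open).

    Internal coordinates are 1-based inclusive, so ``start_bed = start - 1``
    and ``end_bed = end``.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping regions on {chrom}: {a.start}-{a.end} and {b.start}-{b.end}")
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            methods = ",".join(sorted(r.methods)) if r.methods else "."
            score = ";".join(f"{m}={v!r}" for m, v in sorted(r.scores)) if r.scores else "."
            pval = "." if r.pvalue is None else repr(r.pvalue)
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{methods}\t{score}\t{pval}\n")


def read_regions_bed(path) -> list[Region]:
    """Inverse of :func:`write_regions_bed`."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            methods = frozenset()
            scores: tuple = ()
            pvalue = None
            if len(fields) > 3 and fields[3] != ".":
                methods = frozenset(fields[3].split(","))
            if len(fields) > 4 and fields[4] != ".":
                scores = tuple(
                    (m, float(v)) for m, v in
                    (item.split("=", 1) for item in fields[4].split(";"))
                )
            if len(fields) > 5 and fields[5] != ".":
                pvalue = float(fields[5])
            regions.append(Region(chrom=chrom, start=start0 + 1, end=end,
                                  methods=methods, scores=scores, pvalue=pvalue))
    return regions
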