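"""Synthetic phased three-population haplotype data with known truth.

The generator emulates the data regime of the scans this package targets: a
target population of ~54 diploids, a reference population of ~74, and an
African-like outgroup, with

* between-population allele-frequency differentiation from the
  Balding-Nichols model (per-population drift parameter F around shared
  ancestral frequencies drawn from a 1/p, neutral-SFS-shaped density);
* linkage disequilibrium from a founder-mosaic (Li-Stephens-like) copying
  process: each haplotype is a mosaic of K population founder haplotypes
  with Poisson switch points (rate ``rho`` per bp), so haplotype sharing
  decays with physical distance;
* injectable hard sweeps: the derived allele at a focal SNP is raised to a
  target frequency in the target population only, and every carrier shares
  one sweep haplotype over exponentially-distributed flanking extents,
  giving both the frequency differentiation that PBS detects and the
  extended haplotype homozygosity that XP-EHH detects;
* injectable archaic tracts from two divergent archaic sources (a
  Neanderthal-like and a Denisovan-like lineage), each contributing
  private derived alleles at density ``d`` per bp that are absent from the
  outgroup (the aSNP premise), pasted around a per-source anchor into a
  fraction alpha of target haplotypes with exponential extents (mean tract
  length ``tract_mean_bp``), plus four archaic pseudo-individual genotype
  panels (three Neanderthal-like, one Denisovan-like);
* SNP-effect phenotypes with age/sex/height covariates and Gaussian noise;
* synthetic position-keyed association lookup tables emulating biobank
  summary statistics, with plantable blood-phenotype hits.

Every generator is a pure function of its configuration (which includes
the seed): identical configuration gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import HaplotypePanel

__all__ = [
    "SimConfig", "SweepSpec", "ArchaicSourceSpec", "PhenotypeSpec", "AssocTableSpec",
    "TruthRecord", "simulate_panel", "inject_sweep", "inject_archaic",
    "simulate_phenotypes", "simulate_assoc_table",
]

ARCHAIC_INDIVIDUALS = {
    "Neanderthal": ["AltaiNea", "VindijaNea", "ChagyrskayaNea"],
    "Denisova": ["Denisova"],
}

AGE_SEX_PHENOTYPES = ["heart_rate", "haemoglobin", "blood_pressure", "bmi"]
AGE_SEX_HEIGHT_PHENOTYPES = ["chest_depth", "waist", "weight", "fev1", "pef", "fvc"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SweepSpec:
    """A hard sweep in the target population.

    ``position`` picks the closest eligible site (None: nearest the region
    centre with a low-to-moderate starting derived frequency).  ``daf`` is
    the post-sweep target derived allele frequency; ``flank_mean_bp`` the
    mean length of the sweep haplotype shared by carriers on each side of
    the focal SNP (the core-homozygosity boost).
    """

    position: int | None = None
    daf: float = 0.9
    flank_mean_bp: float = 100_000.0
    init_daf_range: tuple = (0.05, 0.25)

    def __post_init__(self) -> None:
        if not 0 < self.daf < 1:
            raise ValueError("sweep daf must lie in (0, 1)")


@dataclass
class ArchaicSourceSpec:
    """One archaic source lineage contributing introgressed tracts."""

    ancestry: str = "Denisova"          # "Neanderthal" or "Denisova"
    alpha: float = 0.4                  # fraction of target haplotypes with a tract
    divergence: float = 1e-3            # private derived alleles per bp
    tract_mean_bp: float = 40_000.0     # mean tract length
    anchor: int | None = None           # locus all tracts cover (None: random)

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.divergence <= 0 or self.tract_mean_bp <= 0:
            raise ValueError("divergence and tract_mean_bp must be positive")
        if self.ancestry not in ARCHAIC_INDIVIDUALS:
            raise ValueError(f"ancestry must be one of {sorted(ARCHAIC_INDIVIDUALS)}")


@dataclass
class PhenotypeSpec:
    """Additive SNP effects plus covariate effects and Gaussian noise."""

    causal: dict = field(default_factory=dict)  # phenotype -> [(site_index, beta), ...]
    sigma: float = 1.0
    b_age: float = 0.05
    b_sex: float = 1.0
    b_height: float = 0.05
    age_range: tuple = (18.0, 65.0)
    p_male: float = 0.5
    height_mean: float = 160.0
    height_sd: float = 7.0
    height_sex_shift: float = 12.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class AssocTableSpec:
    """Synthetic biobank-style association lookup table.

    ``phenotypes`` maps phenotype name -> category; at least one category
    must be the blood-count category.  ``blood_hits`` lists positions that
    get a blood-phenotype p-value below ``hit_p``.
    """

    phenotypes: dict = field(default_factory=lambda: {
        "red_blood_cell_count": "Blood count",
        "lymphocyte_percentage": "Blood count",
        "standing_height": "Body size measures",
        "fev1": "Spirometry",
    })
    blood_category: str = "Blood count"
    blood_hits: tuple = ()
    hit_p: float = 1e-12
    n_phenotypes_tested: int = 1470

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValueError("phenotype list must not be empty")
        if self.blood_category not in self.phenotypes.values():
            raise ValueError("phenotype list must include a blood-count category")


@dataclass
class SimConfig:
    """Neutral three-population panel configuration (defaults = study regime)."""

    seed: int = 0
    L: int = 1_500_000          # region length, bp
    S: int = 5_000              # segregating sites
    n_target: int = 54          # diploids in the scanned population
    n_ref: int = 74             # diploids in the reference population
    n_out: int = 54             # diploids, outgroup
    F_target: float = 0.02      # Balding-Nichols drift vs ancestral
    F_ref: float = 0.02
    F_out: float = 0.15
    K: int = 100                # founder haplotypes per population
    rho: float = 1e-5           # mosaic switch rate per bp
    freq_range: tuple = (0.02, 0.98)  # ancestral-frequency support (log-uniform)
    chrom: str = "chr1"
    pop_target: str = "TGT"
    pop_ref: str = "REF"
    pop_out: str = "OUT"
    sweep: SweepSpec | None = None
    archaic: tuple = ()         # ArchaicSourceSpec instances
    phenotype: PhenotypeSpec | None = None

    def __post_init__(self) -> None:
        if self.S < 20:
            raise ValueError("S must be >= 20 (one scan window)")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        for F in (self.F_target, self.F_ref, self.F_out):
            if not 0 <= F < 1:
                raise ValueError("F must lie in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of injected signals, plus generator internals."""

    sweep_site: int | None = None          # site index of the focal SNP
    sweep_position: int | None = None
    sweep_population: str | None = None
    sweep_daf: float | None = None
    sweep_carrier_rows: np.ndarray | None = None
    tracts: list = field(default_factory=list)   # (hap_row, start_bp, end_bp, ancestry)
    causal: dict = field(default_factory=dict)   # phenotype -> [(site_index, beta)]
    ancestral_freq: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Neutral panel
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p_anc, F):
    """Per-population frequencies around ancestral ``p_anc`` with drift F."""
    if F == 0:
        return p_anc.copy()
    a = p_anc * (1 - F) / F
    b = (1 - p_anc) * (1 - F) / F
    return rng.beta(a, b)


def _mosaic_rows(rng, founders: np.ndarray, n_hap: int, positions: np.ndarray,
                 rho: float) -> np.ndarray:
    """Haplotypes as founder mosaics with Poisson(rho per bp) switch points."""
    K, S = founders.shape
    gaps = np.diff(positions).astype(float)
    p_switch = -np.expm1(-rho * gaps)  # 1 - exp(-rho * gap)
    switch = np.empty((n_hap, S), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_hap, S - 1)) < p_switch
    draws = rng.integers(0, K, size=(n_hap, S))
    cols = np.arange(S)
    last_switch = np.maximum.accumulate(np.where(switch, cols, -1), axis=1)
    path = np.take_along_axis(draws, last_switch, axis=1)
    return founders[path, np.broadcast_to(cols, (n_hap, S))]


def simulate_panel(config: SimConfig) -> tuple[HaplotypePanel, TruthRecord]:
    """Neutral panel plus truth; applies sweep/archaic/phenotype specs if set.

    Ancestral frequencies are log-uniform on ``freq_range`` (density
    proportional to 1/p, the shape of a neutral site-frequency spectrum);
    population frequencies follow Balding-Nichols(F); haplotypes are
    founder mosaics, so LD decays with distance at rate ~2*rho per bp.
    """
    rng = np.random.default_rng(config.seed)
    positions = np.sort(rng.choice(config.L, size=config.S, replace=False)) + 1
    lo, hi = config.freq_range
    p_anc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.S))

    pops = [
        (config.pop_target, config.n_target, config.F_target),
        (config.pop_ref, config.n_ref, config.F_ref),
        (config.pop_out, config.n_out, config.F_out),
    ]
    blocks, sample_ids, populations = [], [], []
    for name, n, F in pops:
        p_pop = _balding_nichols(rng, p_anc, F)
        founders = (rng.random((config.K, config.S)) < p_pop).astype(np.int8)
        blocks.append(_mosaic_rows(rng, founders, 2 * n, positions, config.rho))
        sample_ids += [f"{name}{i:03d}" for i in range(n)]
        populations += [name] * n

    panel = HaplotypePanel(
        chrom=config.chrom,
        positions=positions,
        H=np.concatenate(blocks, axis=0).astype(np.int8),
        sample_ids=sample_ids,
        populations=populations,
    )
    truth = TruthRecord(ancestral_freq=p_anc)

    if config.sweep is not None:
        panel, truth = inject_sweep(
            panel, truth, config.sweep, population=config.pop_target,
            rng=np.random.default_rng(np.random.SeedSequence([config.seed, 1])))
    # Archaic tracts are injected by the caller via inject_archaic (it also
    # returns the archaic reference panels, which a tuple return here would
    # silently drop).
    return panel, truth


# ---------------------------------------------------------------------------
# Sweep injection
# ---------------------------------------------------------------------------

def _pick_focal_site(panel, spec, population):
    daf = panel.daf(population)
    if spec.position is not None:
        j = int(np.argmin(np.abs(panel.positions - spec.position)))
        if daf[j] == 1:
            raise ValueError(f"focal site at {panel.positions[j]} is fixed "
                             f"in {population}")
        if daf[j] == 0:
            raise ValueError(f"focal site at {panel.positions[j]} is not "
                             f"segregating in {population}")
        return j
    lo, hi = spec.init_daf_range
    centre = (panel.positions[0] + panel.positions[-1]) / 2
    eligible = np.flatnonzero((daf >= lo) & (daf <= hi))
    if eligible.size == 0:
        eligible = np.flatnonzero((daf > 0) & (daf < 1))
    if eligible.size == 0:
        raise ValueError("no segregating site available for the sweep")
    return int(eligible[np.argmin(np.abs(panel.positions[eligible] - centre))])


def inject_sweep(panel: HaplotypePanel, truth: TruthRecord,
                 spec: SweepSpec | None, population: str = "TGT",
                 rng: np.random.Generator | None = None):
    """Raise the focal derived allele to the target frequency in one population.

    One existing carrier haplotype is designated the sweep haplotype; the
    right number of non-carrier haplotypes is converted, and every carrier
    is overwritten with the sweep haplotype over an interval around the
    focal SNP with per-carrier exponential extents (mean ``flank_mean_bp``
    per side).  Carriers therefore share long identical flanks (the EHH
    signal), the focal derived frequency lands within one chromosome of
    the target (the PBS signal), and no row outside the population is
    touched.  A ``None`` spec returns the input unchanged.
    """
    if spec is None:
        return panel, truth
    rng = rng or np.random.default_rng(0)
    panel = panel.copy()
    rows = panel.haplotype_rows(population)
    j = _pick_focal_site(panel, spec, population)
    col = panel.H[rows, j]
    carriers = rows[col == 1]
    if carriers.size == rows.size:
        raise ValueError("focal site is fixed in the target population")
    if carriers.size == 0:
        raise ValueError("focal site is not segregating in the target population")
    m_star = int(round(spec.daf * rows.size))
    if m_star < carriers.size:
        raise ValueError(
            f"target DAF {spec.daf} below current frequency {carriers.size / rows.size:.3f}"
        )
    non_carriers = rows[col == 0]
    converted = rng.choice(non_carriers, size=m_star - carriers.size, replace=False)
    all_carriers = np.sort(np.concatenate([carriers, converted]))
    sweep_hap = panel.H[rng.choice(carriers), :].copy()

    focal_pos = panel.positions[j]
    left = rng.exponential(spec.flank_mean_bp, size=all_carriers.size)
    right = rng.exponential(spec.flank_mean_bp, size=all_carriers.size)
    for r, lext, rext in zip(all_carriers, left, right):
        sel = (panel.positions >= focal_pos - lext) & (panel.positions <= focal_pos + rext)
        panel.H[r, sel] = sweep_hap[sel]

    truth = replace(truth,
                    sweep_site=j, sweep_position=int(focal_pos),
                    sweep_population=population,
                    sweep_daf=m_star / rows.size,
                    sweep_carrier_rows=all_carriers)
    return panel, truth


# ---------------------------------------------------------------------------
# Archaic injection
# ---------------------------------------------------------------------------

def inject_archaic(panel: HaplotypePanel, truth: TruthRecord,
                   sources: tuple, population: str = "TGT", outgroup: str = "OUT",
                   rng: np.random.Generator | None = None):
    """Paste archaic tracts into target haplotypes; emit archaic panels.

    Each source lineage carries private derived alleles at Poisson density
    ``divergence`` per bp at positions new to the panel (absent, by
    construction, from the outgroup) plus its own alleles at the shared
    polymorphic sites.  A fraction ``alpha`` of target haplotypes receives
    one tract covering the source anchor with exponential extents on both
    sides (mean tract length ``tract_mean_bp``), clipped to the region.
    Private sites carried by no modern haplotype are not added to the
    panel (they would not segregate in a modern call set) but remain in
    the archaic genotype panels.

    Returns ``(panel, truth, archaic_panels)`` where ``archaic_panels`` is
    a position-indexed boolean DataFrame with one column per archaic
    pseudo-individual (three Neanderthal-like, one Denisovan-like).
    """
    rng = rng or np.random.default_rng(0)
    sources = tuple(sources)
    L = int(panel.positions[-1])
    for s in sources:
        if s.tract_mean_bp >= L:
            raise ValueError("tract mean length must be smaller than the region")

    p_anc = truth.ancestral_freq
    if p_anc is None:
        p_anc = np.clip(panel.daf(), 0.02, 0.98)

    rows = panel.haplotype_rows(population)
    n_modern_sites = panel.n_sites
    existing = set(int(p) for p in panel.positions)

    # Per source: private positions, source alleles at shared sites, tracts.
    per_source = []
    tracts = list(truth.tracts)
    for src in sources:
        n_priv = rng.poisson(src.divergence * L)
        priv_set: set[int] = set()
        while len(priv_set) < n_priv:
            c = int(rng.integers(1, L + 1))
            if c not in existing:
                priv_set.add(c)
                existing.add(c)
        priv = np.array(sorted(priv_set), dtype=np.int64)
        shared_alleles = (rng.random(n_modern_sites) < p_anc).astype(np.int8)
        anchor = src.anchor if src.anchor is not None else int(rng.integers(1, L + 1))
        carriers = rows[rng.random(rows.size) < src.alpha]
        half = src.tract_mean_bp / 2.0
        spans = []
        for r in carriers:
            a = max(1, int(anchor - rng.exponential(half)))
            b = min(L, int(anchor + rng.exponential(half)))
            spans.append((int(r), a, b))
            tracts.append((int(r), a, b, src.ancestry))
        per_source.append((src, priv, shared_alleles, spans))

    # Which private sites are carried by at least one modern haplotype?
    carried_positions = []
    carried_rows = []  # parallel: list of carrier row arrays
    for src, priv, _, spans in per_source:
        for p in priv:
            who = [r for r, a, b in spans if a <= p <= b]
            if who:
                carried_positions.append(int(p))
                carried_rows.append(np.array(who))

    # Assemble the extended panel.
    new_pos = np.array(sorted(set(carried_positions)), dtype=np.int64)
    pos_all = np.sort(np.concatenate([panel.positions, new_pos]))
    idx_of = {int(p): i for i, p in enumerate(pos_all)}
    H_new = np.zeros((panel.n_haplotypes, pos_all.size), dtype=np.int8)
    old_cols = np.array([idx_of[int(p)] for p in panel.positions])
    H_new[:, old_cols] = panel.H
    for p, who in zip(carried_positions, carried_rows):
        H_new[who, idx_of[p]] = 1
    # Paste source alleles at shared sites inside each tract.
    for src, priv, shared_alleles, spans in per_source:
        for r, a, b in spans:
            sel = (panel.positions >= a) & (panel.positions <= b)
            H_new[r, old_cols[sel]] = shared_alleles[sel]

    panel_out = HaplotypePanel(
        chrom=panel.chrom, positions=pos_all, H=H_new,
        sample_ids=panel.sample_ids, populations=panel.populations,
    )

    # Archaic pseudo-individual panels over all sites (shared + all private).
    all_priv = np.concatenate([priv for _, priv, _, _ in per_source]) \
        if per_source else np.array([], dtype=np.int64)
    arch_pos = np.sort(np.concatenate([panel.positions, all_priv]))
    arch = pd.DataFrame(False, index=pd.Index(arch_pos, name="position"),
                        columns=[ind for inds in ARCHAIC_INDIVIDUALS.values() for ind in inds])
    for src, priv, shared_alleles, _ in per_source:
        for ind in ARCHAIC_INDIVIDUALS[src.ancestry]:
            # Lineage private alleles: each individual carries most of them.
            carry = rng.random(priv.size) < 0.9 if len(ARCHAIC_INDIVIDUALS[src.ancestry]) > 1 \
                else np.ones(priv.size, dtype=bool)
            arch.loc[priv[carry], ind] = True
            arch.loc[panel.positions[shared_alleles == 1], ind] = True

    truth = replace(truth, tracts=tracts)
    return panel_out, truth, arch


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(panel: HaplotypePanel, spec: PhenotypeSpec,
                        seed: int = 0, populations: list[str] | None = None) -> pd.DataFrame:
    """Phenotype table: y = sum(beta_j g_j) + covariate effects + noise.

    Genotypes are 0/1/2 derived-allele dosages.  Haemoglobin-group
    phenotypes depend on age and sex; body-size/spirometry-group
    phenotypes additionally on height.  Covariates: age uniform, sex
    Bernoulli (0 = female, 1 = male), height Gaussian with a sex shift.
    """
    if spec.sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    if populations is None:
        keep = np.arange(panel.n_samples)
    else:
        pops = np.asarray(panel.populations)
        keep = np.flatnonzero(np.isin(pops, populations))
    n = keep.size
    age = rng.uniform(*spec.age_range, size=n)
    sex = (rng.random(n) < spec.p_male).astype(int)
    height = rng.normal(spec.height_mean, spec.height_sd, size=n) \
        + spec.height_sex_shift * sex

    G = (panel.H[2 * keep] == 1).astype(int) + (panel.H[2 * keep + 1] == 1).astype(int)
    out = pd.DataFrame({
        "sample_id": [panel.sample_ids[i] for i in keep],
        "population": [panel.populations[i] for i in keep],
        "age": age, "sex": sex, "height": height,
    })
    for phen in AGE_SEX_PHENOTYPES + AGE_SEX_HEIGHT_PHENOTYPES:
        y = spec.b_age * age + spec.b_sex * sex
        if phen in AGE_SEX_HEIGHT_PHENOTYPES:
            y = y + spec.b_height * height
        for site, beta in spec.causal.get(phen, []):
            y = y + beta * G[:, site]
        out[phen] = y + rng.normal(0.0, spec.sigma, size=n)
    return out


# ---------------------------------------------------------------------------
# Association lookup table
# ---------------------------------------------------------------------------

def simulate_assoc_table(positions, spec: AssocTableSpec, seed: int = 0) -> pd.DataFrame:
    """Biobank-style lookup table: one row per position x phenotype.

    Background p-values are uniform; positions in ``spec.blood_hits`` get a
    blood-category p-value of ``spec.hit_p`` (well below the Bonferroni
    cutoff for ``n_phenotypes_tested`` phenotypes).
    """
    rng = np.random.default_rng(seed)
    positions = np.asarray(positions, dtype=np.int64)
    hits = set(int(p) for p in spec.blood_hits)
    blood_phens = [p for p, c in spec.phenotypes.items() if c == spec.blood_category]
    rows = []
    for pos in positions:
        for phen, cat in spec.phenotypes.items():
            if int(pos) in hits and phen == blood_phens[0]:
                p = spec.hit_p
            else:
                p = rng.uniform(1e-6, 1.0)
            rows.append((int(pos), phen, cat, rng.normal(), p))
    return pd.DataFrame(rows, columns=["position", "phenotype", "category", "beta", "p"])
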