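"""Synthetic multi-region tumor sequencing data with known ground truth.

Generates, for a virtual patient, the observations the rest of the package
consumes: germline heterozygous SNPs with a known parental phase, somatic
SNVs organised into per-tumor trunks and per-region private sets,
chromosome-scale copy-number alterations (CNAs) assigned to a specific
homolog, and read counts drawn under a purity-mixture model with Poisson
depth and binomial allele sampling.  Every emitted observation traces back
to a truth record, so filtering, recall and phasing can be tested against
a known answer.

The read-count model is intentionally minimal and analytically checkable:
total depth at a site is zero-truncated Poisson(mean_depth); alternate reads
are Binomial(total, expected AF).  An optional per-base error rate mixes the
expected AF toward the opposite allele; it is off by default so that the
generator's moments match the mixture formula exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam

logger = logging.getLogger(__name__)

HOMOLOGS = ("A", "B")

_BASES = ("A", "C", "G", "T")

#: hs37d5 lengths for the four chromosomes carrying the candidate events
#: (6q, 8q, 17p, 21q); a compact but realistically scaled default genome.
DEFAULT_GENOME = (
    ("6", 171_115_067),
    ("8", 146_364_022),
    ("17", 81_195_210),
    ("21", 48_129_895),
)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class DegenerateSiteError(ValueError):
    """Raised when the expected-AF denominator is zero (purity 1 with a
    homozygous total deletion): no reads can come from the site."""


@dataclass(frozen=True)
class CNASpec:
    """A copy-number event on one homolog of one tumor.

    ``homolog_copies`` is the tumor copy number of the affected homolog:
    0 is a one-copy loss, 2 a one-copy gain, 3 a two-copy gain, and so on.
    The unaffected homolog always stays at one copy; 1 would be no event
    and is rejected.  Coordinates are 0-based half-open.
    """

    tumor_id: str
    chrom: str
    start: int
    end: int
    affected_homolog: str
    homolog_copies: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigError(f"CNASpec start must precede end: {self}")
        if self.affected_homolog not in HOMOLOGS:
            raise ConfigError(f"affected_homolog must be one of {HOMOLOGS}")
        if self.homolog_copies < 0 or self.homolog_copies == 1:
            raise ConfigError("homolog_copies must be 0 (loss) or >= 2 (gain)")

    @property
    def state(self) -> str:
        return "loss" if self.homolog_copies == 0 else "gain"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SomaticParams:
    """Counts and allele-frequency model for simulated somatic SNVs.

    Trunk mutations are clonal within a tumor and offered to every region
    of that tumor; each region detects each trunk mutation independently
    with ``trunk_detection_prob`` (modelling caller misses, the mechanism
    that keeps within-tumor recall below 1).  ``cross_tumor_shared`` > 0
    seeds mutations into the trunks of *all* tumors and switches the
    scenario label to metastasis.  Somatic allele frequencies are drawn
    from a beta distribution with the given mean and concentration
    (a = mean * conc, b = (1 - mean) * conc), mimicking the low-VAF spread
    seen in real tumor regions.
    """

    trunk_mutations_per_tumor: int = 35
    private_mutations_per_region: int = 8
    trunk_detection_prob: float = 0.85
    cross_tumor_shared: int = 0
    vaf_distribution: tuple[float, float] = (0.25, 15.0)

    def __post_init__(self) -> None:
        if min(self.trunk_mutations_per_tumor, self.private_mutations_per_region,
               self.cross_tumor_shared) < 0:
            raise ConfigError("somatic mutation counts must be >= 0")
        if not 0.0 <= self.trunk_detection_prob <= 1.0:
            raise ConfigError("trunk_detection_prob must lie in [0, 1]")
        mean, conc = self.vaf_distribution
        if not 0.0 < mean < 1.0 or conc <= 0:
            raise ConfigError("vaf_distribution needs mean in (0,1), concentration > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a simulated multi-region sequencing study.

    Defaults reflect the study design the package targets: two patients,
    three synchronous tumors each sampled twice, ~118X mean depth, and
    samples containing at least 80% tumor cells (purity 0.8).
    """

    seed: int = 0
    n_patients: int = 2
    tumors_per_patient: int = 3
    regions_per_tumor: int = 2
    purity_per_region: float = 0.8
    mean_depth: float = 118.0
    het_site_density: float = 5.0  # sites per megabase
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    cna_specs: tuple[CNASpec, ...] = ()
    somatic_params: SomaticParams = field(default_factory=SomaticParams)
    breakpoint_jitter: int = 0  # +- uniform(0, j) bp applied to emitted segment ends
    error_rate: float = 0.0  # per-read probability of reporting the other allele

    def __post_init__(self) -> None:
        if min(self.n_patients, self.tumors_per_patient, self.regions_per_tumor) < 1:
            raise ConfigError("patient/tumor/region counts must be >= 1")
        if not 0.0 <= self.purity_per_region <= 1.0:
            raise ConfigError("purity_per_region must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if self.het_site_density <= 0:
            raise ConfigError("het_site_density must be > 0")
        if not self.genome:
            raise ConfigError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 0:
                raise ConfigError(f"zero-length chromosome {chrom!r}")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigError("error_rate must lie in [0, 0.5)")
        if self.breakpoint_jitter < 0:
            raise ConfigError("breakpoint_jitter must be >= 0")
        chrom_len = dict(self.genome)
        by_tumor: dict[str, list[CNASpec]] = {}
        for spec in self.cna_specs:
            if spec.chrom not in chrom_len:
                raise ConfigError(f"CNASpec chromosome {spec.chrom!r} not in genome")
            if spec.end > chrom_len[spec.chrom]:
                raise ConfigError(f"CNASpec exceeds chromosome length: {spec}")
            by_tumor.setdefault(spec.tumor_id, []).append(spec)
        for tumor_id, specs in by_tumor.items():
            specs = sorted(specs, key=lambda s: (s.chrom, s.start))
            for a, b in zip(specs, specs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    raise ConfigError(f"overlapping CNASpecs for tumor {tumor_id}")


@dataclass(frozen=True)
class HetSiteTruth:
    """A germline heterozygous site with its true parental phase."""

    chrom: str
    pos: int  # 1-based
    alt_homolog: str  # which homolog carries the ALT allele


@dataclass
class SimulationTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    scenario: str  # "multi-centric" | "metastasis"
    het_sites: list[HetSiteTruth]
    cna_specs: list[CNASpec]
    trunk_mutations: dict[str, list[str]]  # tumor_id -> mutation keys
    cross_tumor_mutations: list[str]
    somatic_by_region: dict[str, list[str]]  # region_id -> emitted mutation keys
    region_to_tumor: dict[str, str]


@dataclass
class VariantRecord:
    """One simulated variant with per-sample read counts (VCF-ready)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]]  # sample -> (alt_reads, total_reads)


@dataclass
class SegmentRow:
    """A copy-number segment as emitted to SEG (0-based half-open here)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    state: str


@dataclass
class PatientData:
    patient_id: str
    normal_sample: str
    samples: list[str]  # normal first, then regions in tumor/region order
    records: list[VariantRecord]
    segments: list[SegmentRow]
    truth: SimulationTruth


def mutation_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def simulate_het_sites(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> list[HetSiteTruth]:
    """Draw germline heterozygous sites along the genome.

    Site counts per chromosome are Poisson(density * length / 1e6);
    positions are uniform, unique and sorted; the ALT-carrying homolog is
    a fair coin per site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites: list[HetSiteTruth] = []
    for chrom, length in config.genome:
        n = int(rng.poisson(config.het_site_density * length / 1e6))
        positions: set[int] = set()
        while len(positions) < n:
            draw = rng.integers(1, length + 1, size=n - len(positions))
            positions.update(int(p) for p in draw)
        homologs = rng.integers(0, 2, size=n)
        for pos, h in zip(sorted(positions), homologs):
            sites.append(HetSiteTruth(chrom, pos, HOMOLOGS[h]))
    return sites


def expected_vaf(alt_homolog: str, spec: CNASpec | None, purity: float) -> float:
    """Expected ALT allele frequency at a germline het site in a tumor region.

    Tumor cells (fraction ``purity``) carry the CNA-adjusted homolog copy
    numbers; admixed normal cells carry one copy of each homolog:

        AF = (purity * c_alt + (1 - purity)) / (purity * (c_A + c_B) + 2 * (1 - purity))

    where ``c_alt`` is the tumor copy number of the ALT-carrying homolog.
    Outside any CNA both homologs are at one copy and the AF is 0.5 at any
    purity.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must lie in [0, 1]")
    if spec is None:
        c_alt, c_total = 1, 2
    else:
        if alt_homolog not in HOMOLOGS:
            raise ValueError(f"alt_homolog must be one of {HOMOLOGS}")
        c_alt = spec.homolog_copies if alt_homolog == spec.affected_homolog else 1
        c_total = spec.homolog_copies + 1
    num = purity * c_alt + (1.0 - purity)
    den = purity * c_total + 2.0 * (1.0 - purity)
    if den == 0.0:
        raise DegenerateSiteError("no copies left at site (purity 1, total deletion)")
    return num / den


def _truncated_poisson(mean_depth: float, size: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson depths (every emitted site has >= 1 read)."""
    total = rng.poisson(mean_depth, size=size)
    while True:
        zero = total == 0
        if not zero.any():
            return total
        total[zero] = rng.poisson(mean_depth, size=int(zero.sum()))


def sample_read_counts(expected_af: float, mean_depth: float,
                       rng: np.random.Generator) -> tuple[int, int]:
    """Draw (alt_reads, total_reads) for one site."""
    alt, total = sample_read_counts_array(np.array([expected_af]), mean_depth, rng)
    return int(alt[0]), int(total[0])


def sample_read_counts_array(expected_af: np.ndarray, mean_depth: float,
                             rng: np.random.Generator,
                             error_rate: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised read-count sampling; returns (alt_reads, total_reads)."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    af = np.asarray(expected_af, dtype=float)
    if error_rate:
        af = af * (1.0 - error_rate) + (1.0 - af) * error_rate
    total = _truncated_poisson(mean_depth, af.size, rng)
    alt = rng.binomial(total, af)
    return alt, total


def _tumor_ids(config: SimulationConfig) -> list[str]:
    return [f"T{i + 1}" for i in range(config.tumors_per_patient)]


def _region_ids(config: SimulationConfig) -> dict[str, list[str]]:
    return {t: [f"{t}R{j + 1}" for j in range(config.regions_per_tumor)]
            for t in _tumor_ids(config)}


def _spec_at(specs: list[CNASpec], chrom: str, pos: int) -> CNASpec | None:
    for spec in specs:
        if spec.chrom == chrom and spec.start < pos <= spec.end:
            return spec
    return None


def _draw_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(0, 4)]
    alt = _BASES[rng.integers(0, 3)]
    if alt >= ref:  # skip over ref so alt != ref, uniform over the other 3
        alt = _BASES[(_BASES.index(alt) + 1) % 4]
        if alt == ref:
            alt = _BASES[(_BASES.index(alt) + 1) % 4]
    return ref, alt


def _draw_position(chrom_lengths: dict[str, int], used: dict[str, set[int]],
                   rng: np.random.Generator) -> tuple[str, int]:
    """Draw a fresh genomic position, length-weighted, avoiding all used
    positions so mutation keys never collide across pools."""
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    while True:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        if pos not in used[chrom]:
            used[chrom].add(pos)
            return chrom, pos


def simulate_patient(config: SimulationConfig, patient_index: int = 0) -> PatientData:
    """Simulate one patient: normal + all tumor regions, segments, truth.

    Deterministic given (config, patient_index): the per-patient generator
    is seeded with the pair (config.seed, patient_index).
    """
    rng = np.random.default_rng((config.seed, patient_index))
    patient_id = f"P{patient_index + 1}"
    chrom_lengths = dict(config.genome)
    chrom_order = {c: i for i, (c, _) in enumerate(config.genome)}
    tumors = _tumor_ids(config)
    regions = _region_ids(config)
    region_to_tumor = {r: t for t, rs in regions.items() for r in rs}
    all_regions = [r for t in tumors for r in regions[t]]
    normal_sample = f"{patient_id}N"
    samples = [normal_sample] + all_regions

    specs_by_tumor = {t: [s for s in config.cna_specs if s.tumor_id == t]
                      for t in tumors}
    params = config.somatic_params

    het_sites = simulate_het_sites(config, rng)
    used: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for site in het_sites:
        used[site.chrom].add(site.pos)

    records: list[VariantRecord] = []

    # --- germline het sites ---------------------------------------------
    n_sites = len(het_sites)
    af_by_sample: dict[str, np.ndarray] = {
        normal_sample: np.full(n_sites, 0.5)
    }
    for region in all_regions:
        specs = specs_by_tumor[region_to_tumor[region]]
        af = np.empty(n_sites)
        for i, site in enumerate(het_sites):
            af[i] = expected_vaf(site.alt_homolog,
                                 _spec_at(specs, site.chrom, site.pos),
                                 config.purity_per_region)
        af_by_sample[region] = af
    counts_by_sample = {
        s: sample_read_counts_array(af_by_sample[s], config.mean_depth, rng,
                                    config.error_rate)
        for s in samples
    }
    for i, site in enumerate(het_sites):
        ref, alt = _draw_alleles(rng)
        counts = {s: (int(counts_by_sample[s][0][i]), int(counts_by_sample[s][1][i]))
                  for s in samples}
        records.append(VariantRecord(site.chrom, site.pos, ref, alt, counts))

    # --- somatic SNVs ----------------------------------------------------
    vaf_mean, vaf_conc = params.vaf_distribution
    beta_a, beta_b = vaf_mean * vaf_conc, (1.0 - vaf_mean) * vaf_conc

    def new_mutation() -> tuple[str, int, str, str, float]:
        chrom, pos = _draw_position(chrom_lengths, used, rng)
        ref, alt = _draw_alleles(rng)
        vaf = float(rng.beta(beta_a, beta_b))
        return chrom, pos, ref, alt, vaf

    # present[region] maps mutation key -> expected AF in that region
    present: dict[str, dict[str, float]] = {r: {} for r in all_regions}
    trunk_keys: dict[str, list[str]] = {t: [] for t in tumors}
    cross_keys: list[str] = []
    somatic_meta: dict[str, tuple[str, int, str, str, float]] = {}

    def add_mutation(key_regions: list[str], thin: bool) -> str:
        chrom, pos, ref, alt, vaf = new_mutation()
        key = mutation_key(chrom, pos, ref, alt)
        somatic_meta[key] = (chrom, pos, ref, alt, vaf)
        for region in key_regions:
            if thin and rng.random() >= params.trunk_detection_prob:
                continue
            present[region][key] = vaf
        return key

    for _ in range(params.cross_tumor_shared):
        key = add_mutation(all_regions, thin=True)
        cross_keys.append(key)
        for t in tumors:
            trunk_keys[t].append(key)
    for t in tumors:
        for _ in range(params.trunk_mutations_per_tumor):
            key = add_mutation(regions[t], thin=True)
            trunk_keys[t].append(key)
    for region in all_regions:
        for _ in range(params.private_mutations_per_region):
            add_mutation([region], thin=False)

    for key, (chrom, pos, ref, alt, _vaf) in somatic_meta.items():
        counts: dict[str, tuple[int, int]] = {}
        for sample in samples:
            af = present.get(sample, {}).get(key, 0.0)
            alt_reads, total = sample_read_counts(af, config.mean_depth, rng)
            counts[sample] = (alt_reads, total)
        records.append(VariantRecord(chrom, pos, ref, alt, counts))

    records.sort(key=lambda r: (chrom_order[r.chrom], r.pos))

    # --- copy-number segments --------------------------------------------
    segments: list[SegmentRow] = []
    for t in tumors:
        for spec in sorted(specs_by_tumor[t],
                           key=lambda s: (chrom_order[s.chrom], s.start)):
            start, end = spec.start, spec.end
            if config.breakpoint_jitter:
                j = config.breakpoint_jitter
                start = max(0, start + int(rng.integers(-j, j + 1)))
                end = min(chrom_lengths[spec.chrom], end + int(rng.integers(-j, j + 1)))
                if start >= end:
                    start, end = spec.start, spec.end
            # emulate array probe support at ~1 probe / 5 kb
            n_probes = max(1, (end - start) // 5000)
            segments.append(SegmentRow(t, spec.chrom, start, end, n_probes, spec.state))

    truth = SimulationTruth(
        patient_id=patient_id,
        scenario="metastasis" if params.cross_tumor_shared > 0 else "multi-centric",
        het_sites=het_sites,
        cna_specs=[s for t in tumors for s in specs_by_tumor[t]],
        trunk_mutations={t: sorted(trunk_keys[t]) for t in tumors},
        cross_tumor_mutations=sorted(cross_keys),
        somatic_by_region={r: sorted(present[r]) for r in all_regions},
        region_to_tumor=region_to_tumor,
    )
    return PatientData(patient_id, normal_sample, samples, records, segments, truth)


# --------------------------------------------------------------------------
# writers / readers


def write_patient_vcf(patient: PatientData, path: str,
                      genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME) -> None:
    """Write a multi-sample VCF 4.2 (normal + regions) with DP and AD."""
    header = pysam.VariantHeader()
    for chrom, length in genome:
        header.contigs.add(chrom, length=length)
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    for sample in patient.samples:
        header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for rec in patient.records:
            row = vcf.new_record(contig=rec.chrom, start=rec.pos - 1,
                                 alleles=(rec.ref, rec.alt))
            for sample in patient.samples:
                alt_reads, total = rec.counts[sample]
                row.samples[sample]["DP"] = total
                row.samples[sample]["AD"] = (total - alt_reads, alt_reads)
            vcf.write(row)


def write_seg(segments: list[SegmentRow], path: str) -> None:
    """Write segments as tab-separated SEG (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_probes\tstate\n")
        for seg in segments:
            fh.write(f"{seg.sample_id}\t{seg.chrom}\t{seg.start + 1}\t{seg.end}"
                     f"\t{seg.n_probes}\t{seg.state}\n")


def write_truth(truth: SimulationTruth, path: str) -> None:
    """Serialise ground truth to JSON (lossless round-trip with read_truth)."""
    payload = asdict(truth)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str) -> SimulationTruth:
    with open(path) as fh:
        payload = json.load(fh)
    payload["het_sites"] = [HetSiteTruth(**h) for h in payload["het_sites"]]
    payload["cna_specs"] = [CNASpec(**s) for s in payload["cna_specs"]]
    return SimulationTruth(**payload)


# --------------------------------------------------------------------------
# lightweight segment-pair simulator for calibration and power studies


def simulate_segment_pair(n_sites: int,
                          mean_depth: float,
                          purity_a: float,
                          purity_b: float,
                          homolog_a: str,
                          homolog_b: str,
                          rng: np.random.Generator,
                          homolog_copies: int = 0,
                          normal_depth: float | None = None):
    """Simulate one shared CNA observed in two tumors, phasing-ready.

    Both tumors carry the same copy-number state (``homolog_copies`` on the
    affected homolog, default one-copy loss) on ``homolog_a`` and
    ``homolog_b`` respectively; the same-homolog null is ``homolog_a ==
    homolog_b``.  Returns ``(records, truth_homologs)`` where records carry
    AF/depth for the normal and the two tumors ``Ta``/``Tb`` with deltas
    filled, and ``truth_homologs`` is the per-site ALT-carrying homolog.

    Sites whose sampled normal AF falls outside a het call or with zero
    tumor depth are not filtered here; feed the records through
    :func:`cnaphase.phasing.phase_concordance_test` (which applies its own
    admission rules) or pre-filter with ``select_polymorphic_sites``.
    """
    from .phasing import HetSitePhasingRecord  # local import to avoid a cycle

    if normal_depth is None:
        normal_depth = mean_depth
    alt_homolog = np.array([HOMOLOGS[i] for i in rng.integers(0, 2, size=n_sites)])
    spec_a = CNASpec("Ta", "1", 0, n_sites + 1, homolog_a, homolog_copies)
    spec_b = CNASpec("Tb", "1", 0, n_sites + 1, homolog_b, homolog_copies)
    af_a = np.array([expected_vaf(h, spec_a, purity_a) for h in alt_homolog])
    af_b = np.array([expected_vaf(h, spec_b, purity_b) for h in alt_homolog])

    alt_n, tot_n = sample_read_counts_array(np.full(n_sites, 0.5), normal_depth, rng)
    alt_a, tot_a = sample_read_counts_array(af_a, mean_depth, rng)
    alt_b, tot_b = sample_read_counts_array(af_b, mean_depth, rng)

    records = []
    for i in range(n_sites):
        af_normal = alt_n[i] / tot_n[i]
        rec = HetSitePhasingRecord(
            chrom="1", pos=i + 1,
            af_normal=float(af_normal), depth_normal=int(tot_n[i]),
            af_tumor={"Ta": float(alt_a[i] / tot_a[i]),
                      "Tb": float(alt_b[i] / tot_b[i])},
            depth_tumor={"Ta": int(tot_a[i]), "Tb": int(tot_b[i])},
            delta={"Ta": float(alt_a[i] / tot_a[i] - af_normal),
                   "Tb": float(alt_b[i] / tot_b[i] - af_normal)},
        )
        records.append(rec)
    return records, alt_homolog
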