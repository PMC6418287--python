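"""Somatic/germline classification and exclusion filtering of variants.

A variant observed in a tumor region is classified against the matched
normal by presence/absence of alternate reads, then run through a set of
exclusion filters mirroring standard matched-normal somatic calling
practice: segmental-duplication membership, any alternate read in the
normal, minimum depths in normal and tumor, minimum alternate-read count
and VAF in the tumor, and population/local-cohort frequency cutoffs.
Every failing reason is reported (no short-circuiting), so a verdict table
documents exactly why each candidate was discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

#: the full set of defined failure reason codes
REASON_CODES = frozenset({
    "segdup", "normal_alt_present", "normal_low_depth", "tumor_low_depth",
    "tumor_few_alt_reads", "tumor_low_vaf", "population_frequent",
    "local_cohort_frequent",
})


@dataclass(frozen=True)
class VariantObservation:
    """One variant in one sample, with its read support."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError("need 0 <= alt_reads <= total_reads")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def vaf(self) -> float | None:
        if self.total_reads == 0:
            return None
        return self.alt_reads / self.total_reads


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the exclusion filters.

    Defaults: >=10 total reads in the normal, zero alternate reads allowed
    in the normal, >=8 total and >=3 alternate reads in the tumor, tumor
    VAF >= 3%, population frequency not above 2%, local-cohort frequency
    strictly below 5%.
    """

    min_normal_total: int = 10
    max_normal_alt: int = 0
    min_tumor_total: int = 8
    min_tumor_alt: int = 3
    min_tumor_vaf: float = 0.03
    max_population_freq: float = 0.02
    max_local_cohort_freq: float = 0.05

    def __post_init__(self) -> None:
        if min(self.min_normal_total, self.max_normal_alt,
               self.min_tumor_total, self.min_tumor_alt) < 0:
            raise ValueError("integer thresholds must be >= 0")
        for frac in (self.min_tumor_vaf, self.max_population_freq,
                     self.max_local_cohort_freq):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass
class FilterVerdict:
    key: str
    sample_id: str
    reasons: frozenset[str] = field(default_factory=frozenset)

    @property
    def status(self) -> str:
        return "pass" if not self.reasons else "fail"


def classify_origin(tumor_variant: VariantObservation,
                    normal_obs: VariantObservation) -> str:
    """Germline iff the variant is present in the matched normal.

    Presence means at least one alternate read in the tumor-free tissue.
    """
    if tumor_variant.key != normal_obs.key:
        raise ValueError(f"mismatched variant keys: "
                         f"{tumor_variant.key} vs {normal_obs.key}")
    return "germline" if normal_obs.alt_reads > 0 else "somatic"


def apply_somatic_filters(tumor_obs: VariantObservation,
                          normal_obs: VariantObservation,
                          in_segdup: bool = False,
                          population_freq: float | None = None,
                          local_cohort_freq: float | None = None,
                          cfg: FilterConfig = FilterConfig()) -> FilterVerdict:
    """Apply all exclusion filters to one somatic candidate; collect every
    applicable failure reason.

    A tumor observation with zero total reads fails ``tumor_low_depth``
    (its VAF is undefined, which is not an error).  Frequency filters are
    skipped when no frequency is known for the variant.
    """
    if tumor_obs.key != normal_obs.key:
        raise ValueError("observations must share a variant key")
    reasons: set[str] = set()
    if in_segdup:
        reasons.add("segdup")
    if normal_obs.alt_reads > cfg.max_normal_alt:
        reasons.add("normal_alt_present")
    if normal_obs.total_reads < cfg.min_normal_total:
        reasons.add("normal_low_depth")
    if tumor_obs.total_reads < cfg.min_tumor_total:
        reasons.add("tumor_low_depth")
    if tumor_obs.alt_reads < cfg.min_tumor_alt:
        reasons.add("tumor_few_alt_reads")
    vaf = tumor_obs.vaf
    if vaf is None:
        reasons.add("tumor_low_depth")
    elif vaf < cfg.min_tumor_vaf:
        reasons.add("tumor_low_vaf")
    if population_freq is not None and population_freq > cfg.max_population_freq:
        reasons.add("population_frequent")
    if local_cohort_freq is not None and local_cohort_freq >= cfg.max_local_cohort_freq:
        reasons.add("local_cohort_frequent")
    return FilterVerdict(tumor_obs.key, tumor_obs.sample_id, frozenset(reasons))


class SegdupIndex:
    """Membership test against a set of half-open genomic intervals."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._intervals = {c: sorted(iv) for c, iv in (intervals or {}).items()}

    @classmethod
    def from_bed(cls, path: str) -> "SegdupIndex":
        intervals: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split()[:3]
                intervals.setdefault(chrom, []).append((int(start), int(end)))
        return cls(intervals)

    def __contains__(self, site: tuple[str, int]) -> bool:
        chrom, pos = site  # pos 1-based
        for start, end in self._intervals.get(chrom, ()):
            if start < pos <= end:
                return True
        return False


def filter_variant_table(observations: list[VariantObservation],
                         normal_sample: str,
                         segdups: SegdupIndex | None = None,
                         population_freqs: dict[str, float] | None = None,
                         cohort_freqs: dict[str, float] | None = None,
                         cfg: FilterConfig = FilterConfig(),
                         ) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Batch-filter all tumor observations against the matched normal.

    Returns ``(pass_sets, verdict_table)`` where ``pass_sets`` maps each
    tumor sample to the set of mutation keys that are somatic and pass
    every exclusion filter, and the verdict table has one row per
    (variant, tumor sample) pair.  A tumor variant with no matched-normal
    observation is treated as 0/0 in the normal and so fails
    ``normal_low_depth``.
    """
    segdups = segdups or SegdupIndex()
    population_freqs = population_freqs or {}
    cohort_freqs = cohort_freqs or {}

    normal_by_key: dict[str, VariantObservation] = {}
    tumor_obs: list[VariantObservation] = []
    seen: set[tuple[str, str]] = set()
    for obs in observations:
        pair = (obs.sample_id, obs.key)
        if pair in seen:
            raise ValueError(f"duplicate observation for {pair}")
        seen.add(pair)
        if obs.sample_id == normal_sample:
            normal_by_key[obs.key] = obs
        else:
            tumor_obs.append(obs)

    pass_sets: dict[str, set[str]] = {}
    rows = []
    for obs in tumor_obs:
        pass_sets.setdefault(obs.sample_id, set())
        normal = normal_by_key.get(obs.key)
        if normal is None:
            normal = VariantObservation(normal_sample, obs.chrom, obs.pos,
                                        obs.ref, obs.alt, 0, 0)
        origin = classify_origin(obs, normal)
        verdict = apply_somatic_filters(
            obs, normal,
            in_segdup=(obs.chrom, obs.pos) in segdups,
            population_freq=population_freqs.get(obs.key),
            local_cohort_freq=cohort_freqs.get(obs.key),
            cfg=cfg,
        )
        somatic_pass = origin == "somatic" and verdict.status == "pass"
        if somatic_pass:
            pass_sets[obs.sample_id].add(obs.key)
        rows.append({
            "sample_id": obs.sample_id, "key": obs.key, "origin": origin,
            "status": verdict.status,
            "reasons": ",".join(sorted(verdict.reasons)),
            "alt_reads": obs.alt_reads, "total_reads": obs.total_reads,
        })
    table = pd.DataFrame(rows, columns=["sample_id", "key", "origin", "status",
                                        "reasons", "alt_reads", "total_reads"])
    return pass_sets, table


def read_vcf_observations(path: str) -> list[VariantObservation]:
    """Read per-sample observations from a multi-sample VCF with DP/AD.

    Sites where a sample has no reads are still emitted (0/0) so that the
    matched-normal lookup and depth filters see them.  Only the first ALT
    allele of each record is considered.
    """
    observations: list[VariantObservation] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else None
            if alt is None:
                continue
            for sample in rec.samples:
                fmt = rec.samples[sample]
                ad = fmt.get("AD")
                if ad is not None and ad[0] is not None:
                    alt_reads = int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0
                    total = int(sum(a for a in ad if a is not None))
                else:
                    alt_reads, total = 0, int(fmt.get("DP") or 0)
                observations.append(VariantObservation(
                    sample, rec.chrom, rec.pos, rec.ref, alt, total, alt_reads))
    return observations


def read_frequency_table(path: str) -> dict[str, float]:
    """Read a TSV of (chrom, pos, ref, alt, freq) into a key->freq map."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}": float(r.freq)
            for r in df.itertuples()}
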