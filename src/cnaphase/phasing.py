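"""Chromosome phasing of shared copy-number alterations via allele
frequency shifts, and the Welch two-sample t-test that decides whether two
tumors altered the same homolog.

At a germline heterozygous site the two alleles sit on opposite parental
homologs and the normal-tissue allele frequency (AF) is near 0.5.  A CNA
that gains or loses one homolog unbalances the two alleles: in the tumor,
sites whose ALT allele rides the amplified (or retained) homolog shift up,
the others shift down.  The *direction* of the per-site AF delta
(tumor AF − normal AF) therefore reveals the phase: sites shifting the
same way share a homolog.  If two tumors carry the same CNA on the same
homolog, the haplotype that shifts up in one shifts up in the other; if
they altered opposite homologs the same haplotype shifts in opposite
directions.  AF observations of one haplotype are modelled as random
variables with common mean μ and variance σ², and the haplotype's deltas
are compared across tumors with a Welch unequal-variance t-test.  The null
hypothesis is that the CNAs occurred on the same homolog.

Decision rule for one candidate CNA and one tumor pair: infer haplotypes
from tumor A's shift directions, compare the up-shifted (H1) sites' deltas
between the tumors with a Welch test, repeat with tumor B as reference,
and require (i) rejection in both directions and (ii) opposite mean shift
signs to call ``different_homolog``.  The sign guard keeps a purity
difference between tumors on the *same* homolog (same sign, different
magnitude) from masquerading as a phase difference.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

VERDICTS = ("same_homolog", "different_homolog", "inconclusive")


@dataclass(frozen=True)
class PhasingConfig:
    """Admission rules and test parameters for the phasing analysis.

    ``het_band`` admits a site as heterozygous when the normal AF falls in
    the interval; ``min_depth`` applies to the normal sample (mirroring
    the matched-normal depth filter); ``min_shift`` is the smallest |delta|
    treated as an informative shift; ``min_informative_sites`` gates the
    Welch test; ``alpha`` is the two-sided significance level.
    """

    het_band: tuple[float, float] = (0.35, 0.65)
    min_depth: int = 10
    min_shift: float = 0.05
    min_informative_sites: int = 10
    alpha: float = 0.05
    use_raw_af: bool = False  # compare raw tumor AFs instead of deltas

    def __post_init__(self) -> None:
        lo, hi = self.het_band
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("het_band must be an interval inside (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_shift < 0 or self.min_depth < 0:
            raise ValueError("min_shift and min_depth must be >= 0")
        if self.min_informative_sites < 2:
            raise ValueError("min_informative_sites must be >= 2")


@dataclass
class HetSitePhasingRecord:
    """A germline het site inside a candidate CNA with its AFs and deltas."""

    chrom: str
    pos: int
    af_normal: float
    depth_normal: int
    af_tumor: dict[str, float] = field(default_factory=dict)
    depth_tumor: dict[str, int] = field(default_factory=dict)
    delta: dict[str, float] = field(default_factory=dict)

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class HaplotypeAssignment:
    """Per-site haplotype labels derived from one tumor's shift directions."""

    reference_tumor: str
    labels: dict[tuple[str, int], str]  # site -> "H1" | "H2" | "uninformative"

    def sites(self, label: str) -> list[tuple[str, int]]:
        return [s for s, lab in self.labels.items() if lab == label]


@dataclass
class WelchResult:
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    n_x: int
    n_y: int
    t_statistic: float
    df: float
    p_value: float


@dataclass
class PhasingDecision:
    cna_id: str
    tumor_a: str
    tumor_b: str
    welch_ab: WelchResult | None  # haplotype from tumor_a, compared A vs B
    welch_ba: WelchResult | None
    sign_concordant: bool | None
    verdict: str
    n_informative_sites: tuple[int, int]  # matched H1 sites per direction


def select_polymorphic_sites(normal_observations,
                             cfg: PhasingConfig = PhasingConfig(),
                             ) -> list[HetSitePhasingRecord]:
    """Admit heterozygous sites from matched-normal observations.

    Accepts any iterable of objects with chrom/pos/alt_reads/total_reads
    attributes (e.g. ``filtering.VariantObservation``).  Keeps sites with
    normal depth >= ``min_depth`` and normal AF inside ``het_band``;
    returns records sorted by position, deltas not yet computed.
    """
    lo, hi = cfg.het_band
    records = []
    for obs in normal_observations:
        if obs.total_reads < cfg.min_depth or obs.total_reads == 0:
            continue
        af = obs.alt_reads / obs.total_reads
        if lo <= af <= hi:
            records.append(HetSitePhasingRecord(obs.chrom, obs.pos, af,
                                                obs.total_reads))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def admit_het_records(records: list[HetSitePhasingRecord],
                      cfg: PhasingConfig = PhasingConfig(),
                      ) -> list[HetSitePhasingRecord]:
    """Apply the heterozygous-site admission rules (normal depth and
    het-band) to already-built phasing records, e.g. from a simulator."""
    lo, hi = cfg.het_band
    return [r for r in records
            if r.depth_normal >= cfg.min_depth and lo <= r.af_normal <= hi]


def compute_deltas(records: list[HetSitePhasingRecord],
                   tumor_counts: dict[str, dict[tuple[str, int], tuple[int, int]]],
                   ) -> list[HetSitePhasingRecord]:
    """Fill per-tumor AF and delta (tumor AF − normal AF) for every record.

    ``tumor_counts`` maps tumor id -> site -> (alt_reads, total_reads);
    pooled counts across a tumor's regions are the usual input.  Sites
    missing or with zero depth in any requested tumor are dropped (logged).
    """
    kept = []
    for rec in records:
        out = replace(rec, af_tumor=dict(rec.af_tumor),
                      depth_tumor=dict(rec.depth_tumor), delta=dict(rec.delta))
        ok = True
        for tumor, counts in tumor_counts.items():
            pair = counts.get(rec.site)
            if pair is None or pair[1] == 0:
                logger.debug("dropping site %s: no coverage in %s", rec.site, tumor)
                ok = False
                break
            alt, total = pair
            af = alt / total
            out.af_tumor[tumor] = af
            out.depth_tumor[tumor] = total
            out.delta[tumor] = af - rec.af_normal
        if ok:
            kept.append(out)
    return kept


def infer_haplotypes(records: list[HetSitePhasingRecord], reference_tumor: str,
                     cfg: PhasingConfig = PhasingConfig()) -> HaplotypeAssignment:
    """Group sites by the direction of their AF shift in the reference
    tumor: H1 shifts up (delta > +min_shift), H2 down (delta < −min_shift),
    the rest are uninformative."""
    labels: dict[tuple[str, int], str] = {}
    for rec in records:
        d = rec.delta.get(reference_tumor)
        if d is None or abs(d) <= cfg.min_shift:
            labels[rec.site] = "uninformative"
        elif d > 0:
            labels[rec.site] = "H1"
        else:
            labels[rec.site] = "H2"
    return HaplotypeAssignment(reference_tumor, labels)


def welch_t_test(xs, ys) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

        t  = (x̄ − ȳ) / sqrt(s²_x/n_x + s²_y/n_y)
        df = (s²_x/n_x + s²_y/n_y)² /
             [(s²_x/n_x)²/(n_x−1) + (s²_y/n_y)²/(n_y−1)]

    with unbiased sample variances s².  Degenerate cases: if both sample
    variances are zero the statistic is 0 with p = 1 when the means agree,
    and ±inf with p = 0 (and a warning) when they differ.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n_x, n_y = xs.size, ys.size
    if n_x < 2 or n_y < 2:
        raise ValueError("welch_t_test requires at least two observations per sample")
    mean_x, mean_y = float(xs.mean()), float(ys.mean())
    var_x = float(xs.var(ddof=1))
    var_y = float(ys.var(ddof=1))
    se2 = var_x / n_x + var_y / n_y
    if se2 == 0.0:
        if mean_x == mean_y:
            t, df, p = 0.0, float(n_x + n_y - 2), 1.0
        else:
            warnings.warn("degenerate Welch input: zero variance, unequal means",
                          RuntimeWarning, stacklevel=2)
            t = math.inf if mean_x > mean_y else -math.inf
            df, p = float(n_x + n_y - 2), 0.0
    else:
        t = (mean_x - mean_y) / math.sqrt(se2)
        df = se2 ** 2 / ((var_x / n_x) ** 2 / (n_x - 1)
                         + (var_y / n_y) ** 2 / (n_y - 1))
        p = 2.0 * float(stats.t.sf(abs(t), df))
    return WelchResult(mean_x, mean_y, var_x, var_y, n_x, n_y, t, df, p)


def _directional_test(records: list[HetSitePhasingRecord], reference: str,
                      other: str, cfg: PhasingConfig):
    """One direction of the concordance test: H1 sites by the reference
    tumor's shifts, compared reference-vs-other on the matched site set.

    Returns ``(welch, sign_same, n_matched)``; welch is None when fewer
    than ``min_informative_sites`` matched sites exist.
    """
    assignment = infer_haplotypes(records, reference, cfg)
    matched = [r for r in records
               if assignment.labels[r.site] == "H1" and other in r.delta]
    n = len(matched)
    if n < cfg.min_informative_sites:
        return None, None, n
    if cfg.use_raw_af:
        xs = [r.af_tumor[reference] for r in matched]
        ys = [r.af_tumor[other] for r in matched]
    else:
        xs = [r.delta[reference] for r in matched]
        ys = [r.delta[other] for r in matched]
    welch = welch_t_test(xs, ys)
    # signs of the mean shifts of the same haplotype in the two tumors
    mean_ref = float(np.mean([r.delta[reference] for r in matched]))
    mean_oth = float(np.mean([r.delta[other] for r in matched]))
    sign_same = mean_ref * mean_oth > 0
    return welch, sign_same, n


def phase_concordance_test(records: list[HetSitePhasingRecord],
                           tumor_a: str, tumor_b: str,
                           cfg: PhasingConfig = PhasingConfig(),
                           cna_id: str = "") -> PhasingDecision:
    """Decide whether two tumors altered the same homolog at one CNA.

    Runs the directional Welch comparison with each tumor as the haplotype
    reference.  Verdicts:

    - ``different_homolog``: both directions reject at ``alpha`` and the
      mean shifts of the matched haplotype are not sign-concordant across
      the two tumors;
    - ``same_homolog``: mean shifts agree in sign in both directions and
      neither direction rejects;
    - ``inconclusive`` otherwise, including whenever either direction has
      fewer than ``min_informative_sites`` matched informative sites.
    """
    records = [r for r in records if tumor_a in r.delta and tumor_b in r.delta]
    welch_ab, sign_ab, n_ab = _directional_test(records, tumor_a, tumor_b, cfg)
    welch_ba, sign_ba, n_ba = _directional_test(records, tumor_b, tumor_a, cfg)
    if welch_ab is None or welch_ba is None:
        return PhasingDecision(cna_id, tumor_a, tumor_b, welch_ab, welch_ba,
                               None, "inconclusive", (n_ab, n_ba))
    sign_concordant = bool(sign_ab and sign_ba)
    reject_ab = welch_ab.p_value < cfg.alpha
    reject_ba = welch_ba.p_value < cfg.alpha
    if reject_ab and reject_ba and not sign_concordant:
        verdict = "different_homolog"
    elif sign_concordant and not reject_ab and not reject_ba:
        verdict = "same_homolog"
    else:
        verdict = "inconclusive"
    return PhasingDecision(cna_id, tumor_a, tumor_b, welch_ab, welch_ba,
                           sign_concordant, verdict, (n_ab, n_ba))
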