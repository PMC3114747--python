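"""Within-exon allelic-imbalance scanning of RNA-seq pileups.

In a homogeneous sample without DNA-level copy-number change, the allelic
imbalance measured along one exon is constant: every heterozygous site
reflects the same two chromosomes at the same expression ratio.  When
subclones carry different acquired point mutations, sites within the same
exon report different variant-allele fractions — a germline heterozygous
site sits at 0.5 while a somatic variant carried by a third of the cells
sits near one sixth of the reads on the variant allele, or one third if
the mutated allele is expressed from a single copy shared by carriers.
Significant fluctuation of the per-site variant fraction within a single
exon is therefore a signature of subclonal heterogeneity that expression
confounders (allele-specific expression, per-subclone expression level,
splicing) cannot produce, because those act on the exon as a whole.

Sites are scored with ``0.5 - |0.5 - #B/(#A+#B)|`` (0 at a fixed site, 0.5
at perfect balance) with an exact binomial (Clopper-Pearson) 95% CI on the
variant fraction; only sites covered by at least ``min_reads`` reads
(default 100) are considered.  Two sites in the same exon whose CIs are
disjoint constitute a heterogeneity call; a pair closer than the read
length additionally rules out a focal CNA shared by all subclones, which
would shift both sites together.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

__all__ = [
    "VariantSite",
    "ImbalanceScore",
    "ExonAnnotation",
    "HeterogeneityCall",
    "score_sites",
    "detect_exon_fluctuation",
    "generate_rnaseq_fixture",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSite:
    """Per-nucleotide reference/variant read counts on one transcript."""

    transcript_id: str
    position: int  # 1-based position in transcript coordinates
    ref_base: str
    alt_base: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError("read counts must be non-negative")
        if self.position < 1:
            raise ValidationError("positions are 1-based and must be >= 1")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        if self.depth == 0:
            raise ValidationError("alt_fraction undefined at zero depth")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class ImbalanceScore:
    """Folded imbalance score in [0, 0.5] with a binomial CI on alt fraction."""

    score: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ExonAnnotation:
    """Sorted, non-overlapping half-open exon intervals in transcript coords."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s or s < 0:
                raise ValidationError(f"invalid exon interval [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError("exons must be sorted and non-overlapping")
        object.__setattr__(self, "exons", exons)

    def exon_index(self, position: int) -> int | None:
        """Index of the exon containing a 1-based position, else None."""
        zero_based = position - 1
        starts = [s for s, _ in self.exons]
        i = bisect.bisect_right(starts, zero_based) - 1
        if i >= 0 and zero_based < self.exons[i][1]:
            return i
        return None


@dataclass(frozen=True)
class HeterogeneityCall:
    """A within-exon pair of sites with significantly different imbalance."""

    transcript_id: str
    exon_index: int
    positions: tuple[int, int]
    distance_bp: int
    within_read_length: bool  # True -> a shared focal CNA is excluded
    adjacent: bool  # True if no passing site lies between the pair
    p_value: float | None = None
    q_value: float | None = None


def score_sites(
    sites: Iterable[VariantSite],
    min_reads: int = 100,
    ci_level: float = 0.95,
) -> list[tuple[VariantSite, ImbalanceScore]]:
    """Filter sites by coverage and score their allelic imbalance.

    Sites with fewer than ``min_reads`` supporting reads are discarded.
    The CI is the exact (Clopper-Pearson) binomial interval on the
    variant-allele fraction.
    """
    scored = []
    for site in sites:
        if site.depth < min_reads:
            continue
        frac = site.alt_fraction
        low, high = proportion_confint(
            site.alt_count, site.depth, alpha=1 - ci_level, method="beta"
        )
        scored.append(
            (
                site,
                ImbalanceScore(
                    score=0.5 - abs(0.5 - frac),
                    ci_low=float(low),
                    ci_high=float(high),
                ),
            )
        )
    return scored


def detect_exon_fluctuation(
    scored: Sequence[tuple[VariantSite, ImbalanceScore]],
    annotation: ExonAnnotation | Mapping[str, ExonAnnotation],
    read_length: int = 50,
    mode: str = "ci",
    fisher_alpha: float = 0.05,
) -> list[HeterogeneityCall]:
    """Emit every within-exon site pair with significantly different imbalance.

    In ``"ci"`` mode (default) a pair is called when the two 95% CIs are
    disjoint — a descriptive criterion, reported without multiplicity
    correction.  In ``"fisher"`` mode pairs are tested with Fisher's exact
    test on the 2x2 read-count table and called at Benjamini-Hochberg FDR
    ``fisher_alpha`` across all pairs of the run.

    Sites falling outside every annotated exon are skipped with a warning.
    """
    if mode not in ("ci", "fisher"):
        raise ValidationError("mode must be 'ci' or 'fisher'")
    annotations: Mapping[str, ExonAnnotation]
    if isinstance(annotation, ExonAnnotation):
        annotations = {annotation.transcript_id: annotation}
    else:
        annotations = annotation

    by_exon: dict[tuple[str, int], list[tuple[VariantSite, ImbalanceScore]]] = {}
    for site, score in scored:
        ann = annotations.get(site.transcript_id)
        idx = ann.exon_index(site.position) if ann is not None else None
        if idx is None:
            logger.warning(
                "site %s:%d outside all annotated exons; skipped",
                site.transcript_id,
                site.position,
            )
            continue
        by_exon.setdefault((site.transcript_id, idx), []).append((site, score))

    candidates = []
    for (tid, exon_idx), members in sorted(by_exon.items()):
        members = sorted(members, key=lambda pair: pair[0].position)
        for i, (s1, sc1) in enumerate(members):
            for j in range(i + 1, len(members)):
                s2, sc2 = members[j]
                candidates.append((tid, exon_idx, s1, sc1, s2, sc2, j == i + 1))

    calls: list[HeterogeneityCall] = []
    if mode == "ci":
        for tid, exon_idx, s1, sc1, s2, sc2, adjacent in candidates:
            if sc1.ci_high < sc2.ci_low or sc2.ci_high < sc1.ci_low:
                distance = abs(s2.position - s1.position)
                calls.append(
                    HeterogeneityCall(
                        transcript_id=tid,
                        exon_index=exon_idx,
                        positions=(s1.position, s2.position),
                        distance_bp=distance,
                        within_read_length=distance < read_length,
                        adjacent=adjacent,
                    )
                )
        return calls

    p_values = [
        stats.fisher_exact(
            [[s1.ref_count, s1.alt_count], [s2.ref_count, s2.alt_count]]
        )[1]
        for _, _, s1, _, s2, _, _ in candidates
    ]
    if not p_values:
        return []
    reject, q_values, _, _ = multipletests(p_values, alpha=fisher_alpha, method="fdr_bh")
    for (tid, exon_idx, s1, sc1, s2, sc2, adjacent), p, q, rej in zip(
        candidates, p_values, q_values, reject
    ):
        if rej:
            distance = abs(s2.position - s1.position)
            calls.append(
                HeterogeneityCall(
                    transcript_id=tid,
                    exon_index=exon_idx,
                    positions=(s1.position, s2.position),
                    distance_bp=distance,
                    within_read_length=distance < read_length,
                    adjacent=adjacent,
                    p_value=float(p),
                    q_value=float(q),
                )
            )
    return calls


def generate_rnaseq_fixture(
    subclone_fractions: Sequence[float],
    somatic_sites: Mapping[int, Sequence[int]],
    depth: int = 1000,
    germline_het_sites: Sequence[int] = (),
    transcript_id: str = "synthetic-tx",
    seed=0,
) -> list[VariantSite]:
    """Simulate per-site read counts for a mixture of expressing subclones.

    ``somatic_sites`` maps a 1-based transcript position to the indices of
    the subclones carrying a somatic variant there; the variant-allele
    probability at that site is the summed fraction of the carriers
    (both alleles expressed equally, equal expression across subclones).
    Germline heterozygous sites have probability 0.5 in every subclone.
    Counts are binomial draws at the given depth, reproducible under seed.
    """
    fractions = np.asarray(subclone_fractions, dtype=float)
    if np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError("subclone fractions must be non-negative and sum to 1")
    if depth <= 0:
        raise ValidationError("depth must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sites = []
    planned: list[tuple[int, float]] = [(int(p), 0.5) for p in germline_het_sites]
    for pos, carriers in somatic_sites.items():
        carriers = list(carriers)
        if any(c < 0 or c >= fractions.size for c in carriers):
            raise ValidationError("somatic carrier index out of range")
        planned.append((int(pos), float(fractions[carriers].sum())))
    for pos, p_alt in sorted(planned):
        alt = int(rng.binomial(depth, p_alt))
        sites.append(
            VariantSite(
                transcript_id=transcript_id,
                position=pos,
                ref_base="A",
                alt_base="G",
                ref_count=depth - alt,
                alt_count=alt,
            )
        )
    return sites
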