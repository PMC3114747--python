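"""Ground-truthed simulator for SNP-array signals of subclone mixtures.

The simulator emulates the aggregate signal of a tumor biopsy: a diploid
stromal component mixed with one or two aberrant tumor subclones derived
from the same germline.  A germline is a pair of binary haplotypes
(0 = A allele, 1 = B allele), heterozygous at each locus with probability
``het_prob`` (default 9.5%, homozygous loci split evenly between AA and
BB).  Each subclone is the germline plus blocks of copy-number aberrations
drawn from four kinds: homozygous deletion, hemizygous deletion, gain of
one copy and gain of two copies.  Blocks are 1,000 loci long and separated
by 1,000 aberration-free loci by default, so the classifier is tested on
broad aberrations rather than focal events.

Components are mixed linearly — stroma at ``alpha``, one subclone at
``1 - alpha``, or two subclones at ``2(1-alpha)/3`` and ``(1-alpha)/3`` —
and Gaussian noise is added to the aggregate A and B channels before the
(beta, rho) transform, so both coordinates inherit correlated noise.

The per-locus ground truth is the state (gain / loss / normal) of the
aberrant component with the largest mixing coefficient at that locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .signals import AlleleSignal, LocusProfile, mix_signals, to_profile

__all__ = [
    "Aberration",
    "AberrationSpec",
    "SubcloneGenome",
    "MixtureSpec",
    "TruthTrack",
    "generate_germline",
    "apply_aberrations",
    "default_aberration_layout",
    "simulate_dataset",
]

#: Canonical state labels used across the package.
STATES = ("normal", "loss", "gain")


class Aberration(str, Enum):
    """The four simulated copy-number aberration kinds."""

    HOMOZYGOUS_DELETION = "homozygous_deletion"
    HEMIZYGOUS_DELETION = "hemizygous_deletion"
    GAIN_ONE = "gain_one"
    GAIN_TWO = "gain_two"

    @property
    def sign(self) -> str:
        """Three-state label implied by the aberration ('loss' or 'gain')."""
        if self in (Aberration.HOMOZYGOUS_DELETION, Aberration.HEMIZYGOUS_DELETION):
            return "loss"
        return "gain"


@dataclass(frozen=True)
class AberrationSpec:
    """A contiguous block of one aberration kind within one subclone."""

    kind: Aberration
    start: int
    length: int = 1000

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Aberration(self.kind))
        if self.length <= 0:
            raise ValidationError("aberration length must be positive")
        if self.start < 0:
            raise ValidationError("aberration start must be non-negative")

    @property
    def end(self) -> int:
        """Exclusive end locus (0-based half-open)."""
        return self.start + self.length


@dataclass(frozen=True)
class SubcloneGenome:
    """Integer A/B-allele copy vectors of one homogeneous component."""

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=int)
        b = np.asarray(self.b, dtype=int)
        if a.shape != b.shape or a.ndim != 1:
            raise ValidationError("copy vectors must be 1-D and of equal length")
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError("copy numbers must be non-negative integers")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n_loci(self) -> int:
        return int(self.a.size)

    @property
    def total(self) -> np.ndarray:
        return self.a + self.b


@dataclass(frozen=True)
class MixtureSpec:
    """Configuration of one simulated dataset.

    ``snr`` is the ratio of the mean allele-channel signal to the noise
    standard deviation when ``snr_scale == "amplitude"`` (the default), or
    the ratio of mean signal power to noise variance when ``"power"``.
    ``snr = inf`` disables noise.
    """

    alpha: float
    n_subclones: int = 1
    snr: float = 30.0
    n_loci: int = 10_000
    het_prob: float = 0.095
    seed: int = 0
    block_length: int = 1000
    gap_length: int = 1000
    snr_scale: str = "amplitude"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.n_subclones not in (1, 2):
            raise ValidationError("n_subclones must be 1 or 2")
        if not self.snr > 0:
            raise ValidationError("snr must be positive")
        if self.n_loci <= 0:
            raise ValidationError("n_loci must be positive")
        if not 0.0 <= self.het_prob <= 1.0:
            raise ValidationError("het_prob must lie in [0, 1]")
        if self.snr_scale not in ("amplitude", "power"):
            raise ValidationError("snr_scale must be 'amplitude' or 'power'")

    @property
    def coefficients(self) -> tuple[float, ...]:
        """Mixing coefficients (stroma first), summing to 1."""
        if self.n_subclones == 1:
            return (self.alpha, 1.0 - self.alpha)
        return (self.alpha, 2.0 * (1.0 - self.alpha) / 3.0, (1.0 - self.alpha) / 3.0)


@dataclass(frozen=True)
class TruthTrack:
    """Per-locus ground-truth state plus the aberration layout that made it."""

    state: np.ndarray
    specs_by_subclone: tuple[tuple[AberrationSpec, ...], ...]
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        state = np.asarray(self.state)
        bad = set(np.unique(state)) - set(STATES)
        if bad:
            raise ValidationError(f"unknown truth states: {sorted(bad)}")
        object.__setattr__(self, "state", state)

    @property
    def n_loci(self) -> int:
        return int(self.state.size)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_germline(n_loci: int, het_prob: float = 0.095, seed=0):
    """Draw a pair of binary haplotypes with independent per-locus zygosity.

    Heterozygous loci (probability ``het_prob``) carry one A and one B
    allele, the carrier haplotype chosen uniformly; homozygous loci split
    evenly between AA and BB.
    """
    if n_loci <= 0:
        raise ValidationError("n_loci must be positive")
    if not 0.0 <= het_prob <= 1.0:
        raise ValidationError("het_prob must lie in [0, 1]")
    rng = _rng(seed)
    het = rng.random(n_loci) < het_prob
    hom_allele = rng.integers(0, 2, size=n_loci)
    which_carries_b = rng.integers(0, 2, size=n_loci)
    h1 = np.where(het, which_carries_b == 0, hom_allele).astype(np.int8)
    h2 = np.where(het, which_carries_b == 1, hom_allele).astype(np.int8)
    return h1, h2


def germline_genome(h1: np.ndarray, h2: np.ndarray) -> SubcloneGenome:
    """Diploid genome combining the two haplotypes (a + b = 2 everywhere)."""
    a = (h1 == 0).astype(int) + (h2 == 0).astype(int)
    b = (h1 == 1).astype(int) + (h2 == 1).astype(int)
    return SubcloneGenome(a=a, b=b)


def _check_no_conflicts(specs: Sequence[AberrationSpec]) -> None:
    for i, s1 in enumerate(specs):
        for s2 in specs[i + 1 :]:
            overlap = min(s1.end, s2.end) - max(s1.start, s2.start)
            if overlap > 0 and s1.kind != s2.kind:
                raise ValidationError(
                    f"conflicting aberrations overlap within one subclone: "
                    f"{s1.kind.value}@[{s1.start},{s1.end}) vs "
                    f"{s2.kind.value}@[{s2.start},{s2.end})"
                )


def apply_aberrations(germline, specs: Sequence[AberrationSpec], seed=0) -> SubcloneGenome:
    """Build one subclone genome by editing haplotype multiplicities.

    Each block edits the copy count of the two parental haplotypes: a
    homozygous deletion removes both, a hemizygous deletion removes one
    chosen by a seeded coin flip per block, and gains duplicate one chosen
    haplotype once or twice.  A single coin per block keeps the B-allele
    frequency band coherent along the block, as a clonal event would.
    """
    h1, h2 = germline
    h1 = np.asarray(h1)
    h2 = np.asarray(h2)
    specs = [AberrationSpec(s.kind, s.start, s.length) for s in specs]
    _check_no_conflicts(specs)
    rng = _rng(seed)
    mult = np.ones((2, h1.size), dtype=int)
    for spec in specs:
        if spec.end > h1.size:
            raise ValidationError(
                f"aberration [{spec.start},{spec.end}) exceeds {h1.size} loci"
            )
        sl = slice(spec.start, spec.end)
        chosen = int(rng.integers(0, 2))
        if spec.kind is Aberration.HOMOZYGOUS_DELETION:
            mult[:, sl] = 0
        elif spec.kind is Aberration.HEMIZYGOUS_DELETION:
            mult[chosen, sl] = 0
        elif spec.kind is Aberration.GAIN_ONE:
            mult[chosen, sl] = 2
        else:  # GAIN_TWO
            mult[chosen, sl] = 3
    a = mult[0] * (h1 == 0) + mult[1] * (h2 == 0)
    b = mult[0] * (h1 == 1) + mult[1] * (h2 == 1)
    return SubcloneGenome(a=a, b=b)


_KIND_ORDER = (
    Aberration.HOMOZYGOUS_DELETION,
    Aberration.HEMIZYGOUS_DELETION,
    Aberration.GAIN_ONE,
    Aberration.GAIN_TWO,
)


def default_aberration_layout(
    n_loci: int, n_subclones: int, block_length: int = 1000, gap_length: int = 1000
) -> tuple[tuple[AberrationSpec, ...], ...]:
    """Standard block layout: the four kinds in blocks separated by gaps.

    Subclone 1 places the four kinds at starts ``gap + i*(block+gap)``.
    With two subclones, subclone 2's grid is shifted by half a block and its
    kinds rotated by one, so the aggregate realizes overlapping
    combinations of aberrations (including deletion-with-duplication)
    while kinds never conflict within a subclone.
    """
    period = block_length + gap_length
    layouts = []
    for sub in range(n_subclones):
        offset = gap_length + (block_length // 2) * sub
        specs = []
        for i in range(4):
            kind = _KIND_ORDER[(i + sub) % 4]
            start = offset + i * period
            if start + block_length > n_loci:
                raise ValidationError(
                    f"n_loci={n_loci} too small for the default block layout "
                    f"(needs at least {start + block_length})"
                )
            specs.append(AberrationSpec(kind=kind, start=start, length=block_length))
        layouts.append(tuple(specs))
    return tuple(layouts)


def truth_from_specs(
    n_loci: int,
    specs_by_subclone: Sequence[Sequence[AberrationSpec]],
    coefficients: Sequence[float],
) -> TruthTrack:
    """Label each locus by the aberrant component with the largest coefficient.

    ``coefficients`` includes the stromal coefficient first; subclone i has
    coefficient ``coefficients[i + 1]``.  Loci aberrant in no subclone are
    'normal'.  Ties go to the earlier subclone.
    """
    state = np.full(n_loci, "normal", dtype="<U6")
    order = sorted(
        range(len(specs_by_subclone)),
        key=lambda i: -coefficients[i + 1],
    )
    for i in order:
        if coefficients[i + 1] <= 0:
            continue  # a component absent from the mixture contributes no truth
        for spec in specs_by_subclone[i]:
            sl = slice(spec.start, min(spec.end, n_loci))
            seg = state[sl]
            seg[seg == "normal"] = spec.kind.sign
            state[sl] = seg
    return TruthTrack(
        state=state,
        specs_by_subclone=tuple(tuple(s) for s in specs_by_subclone),
        coefficients=tuple(float(c) for c in coefficients),
    )


def add_channel_noise(
    signal: AlleleSignal, snr: float, rng, snr_scale: str = "amplitude"
) -> AlleleSignal:
    """Add i.i.d. Gaussian noise to the aggregate A and B channels.

    The noise standard deviation of each channel is ``mean(channel)/snr``
    on the amplitude scale or ``sqrt(mean(channel**2)/snr)`` on the power
    scale.  Channels are clipped at zero afterwards, since negative
    aggregate copy numbers are not physical.
    """
    if math.isinf(snr):
        return signal
    if snr_scale == "amplitude":
        sd_a = float(np.mean(signal.a)) / snr
        sd_b = float(np.mean(signal.b)) / snr
    else:
        sd_a = math.sqrt(float(np.mean(signal.a**2)) / snr)
        sd_b = math.sqrt(float(np.mean(signal.b**2)) / snr)
    a = np.clip(signal.a + rng.normal(0.0, sd_a, signal.n_loci), 0.0, None)
    b = np.clip(signal.b + rng.normal(0.0, sd_b, signal.n_loci), 0.0, None)
    return AlleleSignal(a=a, b=b)


def simulate_dataset(spec: MixtureSpec) -> tuple[LocusProfile, TruthTrack]:
    """Simulate one mixture dataset and its ground truth.

    Returns the noisy (beta, rho, log_r) profile of the aggregate signal
    and the per-locus truth track.  Identical specs (including the seed)
    give bit-identical outputs.
    """
    rng = _rng(spec.seed)
    h1, h2 = generate_germline(spec.n_loci, spec.het_prob, rng)
    stroma = germline_genome(h1, h2)
    layouts = default_aberration_layout(
        spec.n_loci, spec.n_subclones, spec.block_length, spec.gap_length
    )
    subclones = [apply_aberrations((h1, h2), specs, rng) for specs in layouts]
    coeffs = spec.coefficients
    aggregate = mix_signals([stroma, *subclones], coeffs)
    noisy = add_channel_noise(aggregate, spec.snr, rng, spec.snr_scale)
    profile = to_profile(noisy)
    truth = truth_from_specs(spec.n_loci, layouts, coeffs)
    return profile, truth
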