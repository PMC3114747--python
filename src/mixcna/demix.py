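"""De-mixing of aggregate signals: the solvable case and the general failure.

Two results live here.

:func:`infer_mixing_coefficient` solves the one practically solvable
de-mixing instance: a single tumor component plus diploid stroma with
mixing coefficient ``x``.  At a deletion locus the aggregate copy number is
``c = 2x + m(1-x)`` with tumor copy number ``m`` either 1 (hemizygous) or 0
(homozygous), giving the closed-form candidates ``x = (c - m)/(2 - m)``.
Solving each locus for both hypotheses and taking the mode of the pooled
candidates recovers the single ``x`` that must satisfy every locus; each
locus then gets the ``m`` whose candidate lies nearer the mode.

:func:`enumerate_demixings` demonstrates why the general problem is hopeless:
for three or more components, even with binary per-allele genotypes, an
exhaustive search over all component sets and gridded coefficient vectors
finds multiple exact reconstructions of the same aggregate — the linear
system is underdetermined and no sparse-recovery argument rescues it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .signals import AlleleSignal, LocusProfile

__all__ = [
    "MixingSolution",
    "EnumerationResult",
    "infer_mixing_coefficient",
    "enumerate_demixings",
]


@dataclass(frozen=True)
class MixingSolution:
    """Inferred stromal coefficient and per-locus tumor copy number.

    ``per_locus_m`` maps each usable deletion locus to its inferred tumor
    copy number (0 or 1); ``per_locus_candidates`` maps it to the pair of
    candidate x values (m=0 hypothesis first; NaN where the candidate fell
    outside [0, 1]).  ``histogram`` is the candidate count per 0.01 bin.
    """

    x_hat: float
    per_locus_m: dict[int, int]
    per_locus_candidates: dict[int, tuple[float, float]]
    histogram: np.ndarray
    bin_width: float
    n_loci_used: int


def infer_mixing_coefficient(
    profile: LocusProfile,
    loss_loci,
    bin_width: float = 0.01,
) -> MixingSolution:
    """Estimate the stromal mixing coefficient from deletion loci.

    ``loss_loci`` is any index set of candidate deletion loci (typically
    the classifier's loss calls); only loci with aggregate copy number
    below 2 are usable.  Candidates outside [0, 1] are discarded before the
    mode is taken; histogram ties go to the bin with the smaller within-bin
    variance (then to the lower bin).
    """
    loci = np.asarray(loss_loci, dtype=int)
    if loci.size == 0:
        raise ValidationError("loss_loci must be non-empty")
    cbar = 2.0 * profile.rho[loci]
    usable = cbar < 2.0
    if not np.any(usable):
        raise ValidationError("no deletion loci: no locus has aggregate copy number < 2")
    loci = loci[usable]
    cbar = cbar[usable]

    cand0 = cbar / 2.0        # homozygous-deletion hypothesis, m = 0
    cand1 = cbar - 1.0        # hemizygous-deletion hypothesis, m = 1
    eps = 1e-9
    valid0 = (cand0 >= -eps) & (cand0 <= 1 + eps)
    valid1 = (cand1 >= -eps) & (cand1 <= 1 + eps)
    pooled = np.concatenate([cand0[valid0], cand1[valid1]])
    if pooled.size == 0:
        raise ValidationError("all candidate coefficients fall outside [0, 1]")
    pooled = np.clip(pooled, 0.0, 1.0)

    n_bins = int(round(1.0 / bin_width))
    # nudge values sitting a float-representation error below a bin edge
    bins = np.minimum(np.floor(pooled / bin_width + 1e-6).astype(int), n_bins - 1)
    histogram = np.bincount(bins, minlength=n_bins)
    top = histogram.max()
    tied = np.flatnonzero(histogram == top)
    if tied.size > 1:
        variances = [float(np.var(pooled[bins == i])) for i in tied]
        mode_bin = int(tied[int(np.argmin(variances))])
    else:
        mode_bin = int(tied[0])
    x_hat = (mode_bin + 0.5) * bin_width

    per_locus_m: dict[int, int] = {}
    per_locus_candidates: dict[int, tuple[float, float]] = {}
    for j, c0, c1, v0, v1 in zip(loci, cand0, cand1, valid0, valid1):
        d0 = abs(c0 - x_hat) if v0 else np.inf
        d1 = abs(c1 - x_hat) if v1 else np.inf
        per_locus_m[int(j)] = 0 if d0 <= d1 else 1
        per_locus_candidates[int(j)] = (
            float(c0) if v0 else float("nan"),
            float(c1) if v1 else float("nan"),
        )
    return MixingSolution(
        x_hat=float(x_hat),
        per_locus_m=per_locus_m,
        per_locus_candidates=per_locus_candidates,
        histogram=histogram,
        bin_width=bin_width,
        n_loci_used=int(loci.size),
    )


@dataclass(frozen=True)
class EnumerationResult:
    """All exact reconstructions of an aggregate found by exhaustive search.

    Each solution is a tuple of ``((a_profile, b_profile), coefficient)``
    pairs, sorted canonically so solutions differing only by component
    permutation are identical.  ``search_space_size`` is the number of
    nonzero binary per-allele profiles (2**s - 1).
    """

    solutions: tuple
    search_space_size: int

    @property
    def n_solutions(self) -> int:
        return len(self.solutions)


def enumerate_demixings(
    aggregate: AlleleSignal,
    k: int,
    coefficient_step: float = 0.1,
    tol: float = 1e-9,
) -> EnumerationResult:
    """Exhaustively enumerate k-component binary de-mixings of an aggregate.

    Components have per-allele genotypes in {0, 1} per locus, each allele
    profile drawn from the 2**s - 1 nonzero binary vectors over the s loci.
    Coefficients run over the positive grid of the given step and sum to 1.
    Guard rails (s <= 12, k <= 4) keep the search exhaustive but finite;
    this is a demonstration device, not a production solver.
    """
    s = aggregate.n_loci
    if s > 12:
        raise ValidationError("enumeration is limited to s <= 12 loci; use a smaller instance")
    if not 1 <= k <= 4:
        raise ValidationError("enumeration is limited to 1 <= k <= 4 components")
    n_steps = int(round(1.0 / coefficient_step))
    if abs(n_steps * coefficient_step - 1.0) > 1e-9 or n_steps < 1:
        raise ValidationError("coefficient_step must divide 1 exactly")

    profiles = [
        np.array([(i >> j) & 1 for j in range(s)], dtype=float)
        for i in range(1, 2**s)
    ]
    components = [
        (tuple(int(v) for v in pa), tuple(int(v) for v in pb))
        for pa in profiles
        for pb in profiles
    ]
    comp_a = np.array([c[0] for c in components], dtype=float)
    comp_b = np.array([c[1] for c in components], dtype=float)

    # positive integer compositions of n_steps into k parts -> coefficient grid
    grids = []
    for cut in itertools.combinations(range(1, n_steps), k - 1):
        parts = np.diff((0, *cut, n_steps))
        grids.append(parts * coefficient_step)
    if not grids:  # k == 1
        grids = [np.array([1.0])]
    # all orderings, since component sets are enumerated as sorted combinations
    weightings = np.unique(
        np.array([p for g in grids for p in itertools.permutations(g)]), axis=0
    )

    found = set()
    for idx in itertools.combinations(range(len(components)), k):
        sub_a = comp_a[list(idx)]  # (k, s)
        sub_b = comp_b[list(idx)]
        res_a = weightings @ sub_a - aggregate.a  # (n_weightings, s)
        res_b = weightings @ sub_b - aggregate.b
        exact = np.all(np.abs(res_a) <= tol, axis=1) & np.all(
            np.abs(res_b) <= tol, axis=1
        )
        for w in weightings[exact]:
            sol = tuple(
                sorted(
                    (components[i], round(float(c), 12))
                    for i, c in zip(idx, w)
                )
            )
            found.add(sol)
    return EnumerationResult(
        solutions=tuple(sorted(found)), search_space_size=2**s - 1
    )
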