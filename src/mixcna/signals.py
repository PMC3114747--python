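"""Allele-signal containers and the B-allele-frequency / log-R transform.

A SNP array (or any counting assay) applied to a mixed cell population
measures, at each locus, the *average* number of A- and B-allele copies per
cell.  This module holds those aggregate channels (:class:`AlleleSignal`),
the forward mixing model that produces them from homogeneous components
(:func:`mix_signals`), and the per-locus change of coordinates to B-allele
frequency ``beta`` and total-DNA enrichment ``rho`` (:func:`to_profile`):

    beta_j = b_j / (a_j + b_j)          # 0.5 at a balanced heterozygote
    rho_j  = (a_j + b_j) / 2            # 1 for a diploid locus
    log_r_j = log2(rho_j)               # 0 for a diploid locus

``beta`` carries the allelic-imbalance information, ``rho``/``log_r`` the
total-DNA information; downstream copy-number calling combines both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = ["AlleleSignal", "LocusProfile", "to_profile", "mix_signals"]


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class AlleleSignal:
    """Aggregate per-locus A- and B-allele quantities, averaged over cells.

    Both channels are non-negative reals of identical length; for a pure
    diploid component they are the integer copy numbers of each allele.
    """

    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = _as_1d_float(self.a, "a")
        b = _as_1d_float(self.b, "b")
        if a.shape != b.shape:
            raise ValidationError(
                f"a and b must have identical length, got {a.size} and {b.size}"
            )
        if a.size == 0:
            raise ValidationError("signal must cover at least one locus")
        if np.any(a < 0) or np.any(b < 0):
            raise ValidationError("allele signals must be non-negative")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n_loci(self) -> int:
        return int(self.a.size)

    @property
    def total(self) -> np.ndarray:
        """Aggregate copy number per locus (a + b)."""
        return self.a + self.b


@dataclass(frozen=True)
class LocusProfile:
    """Per-locus (beta, rho, log_r) coordinates of an aggregate signal.

    ``log_r`` is NaN wherever ``rho == 0`` (the log is undefined there; the
    ``rho = 0`` value itself carries the homozygous-deletion evidence).
    ``chrom``/``pos`` are optional genomic labels carried through I/O.
    """

    beta: np.ndarray
    rho: np.ndarray
    log_r: np.ndarray
    chrom: np.ndarray | None = field(default=None, compare=False)
    pos: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        beta = _as_1d_float(self.beta, "beta")
        rho = _as_1d_float(self.rho, "rho")
        log_r = _as_1d_float(self.log_r, "log_r")
        if not (beta.shape == rho.shape == log_r.shape):
            raise ValidationError("beta, rho and log_r must have identical length")
        if beta.size == 0:
            raise ValidationError("profile must cover at least one locus")
        if np.any((beta < 0) & ~np.isnan(beta)) or np.any((beta > 1) & ~np.isnan(beta)):
            raise ValidationError("beta must lie in [0, 1]")
        if np.any(rho < 0):
            raise ValidationError("rho must be non-negative")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "log_r", log_r)
        if self.pos is not None:
            object.__setattr__(self, "pos", np.asarray(self.pos))
        if self.chrom is not None:
            object.__setattr__(self, "chrom", np.asarray(self.chrom))

    @property
    def n_loci(self) -> int:
        return int(self.beta.size)


def to_profile(signal: AlleleSignal, *, chrom=None, pos=None) -> LocusProfile:
    """Transform aggregate allele channels to (beta, rho, log_r) coordinates.

    Zero-coverage loci (a + b = 0) get ``beta = 0.5`` by convention so that a
    homozygous deletion does not spuriously register as allelic imbalance;
    their ``rho = 0`` carries the deletion evidence and ``log_r`` is NaN.
    """
    total = signal.total
    beta = np.full(signal.n_loci, 0.5)
    np.divide(signal.b, total, out=beta, where=total > 0)
    rho = total / 2.0
    log_r = np.full(signal.n_loci, np.nan)
    np.log2(rho, out=log_r, where=rho > 0)
    return LocusProfile(beta=beta, rho=rho, log_r=log_r, chrom=chrom, pos=pos)


def mix_signals(components: Sequence, coefficients: Sequence[float]) -> AlleleSignal:
    """Forward mixing model: coefficient-weighted sum of component signals.

    ``components`` may be any objects exposing per-locus ``a``/``b`` arrays
    (``AlleleSignal`` or a subclone genome).  Coefficients must be
    non-negative and sum to 1 within 1e-9; all components must cover the
    same loci.
    """
    if len(components) == 0:
        raise ValidationError("at least one component is required")
    if len(components) != len(coefficients):
        raise ValidationError("one coefficient per component is required")
    coeffs = _as_1d_float(coefficients, "coefficients")
    if np.any(coeffs < 0):
        raise ValidationError("mixing coefficients must be non-negative")
    if abs(coeffs.sum() - 1.0) > 1e-9:
        raise ValidationError(
            f"mixing coefficients must sum to 1 (got {coeffs.sum():.12g})"
        )
    lengths = {np.asarray(c.a).size for c in components}
    lengths |= {np.asarray(c.b).size for c in components}
    if len(lengths) != 1:
        raise ValidationError("all components must cover the same number of loci")
    a = np.zeros(lengths.pop(), dtype=float)
    b = np.zeros_like(a)
    for x, comp in zip(coeffs, components):
        a += x * np.asarray(comp.a, dtype=float)
        b += x * np.asarray(comp.b, dtype=float)
    return AlleleSignal(a=a, b=b)
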