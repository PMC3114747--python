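"""Readers and writers for signal TSV, calls TSV, BED segments and YAML config.

Conventions: positions in signal and calls TSVs are 1-based (array-export
convention); BED intervals are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .classify import StateCallTrack
from .errors import ValidationError
from .rnaseq import ExonAnnotation, VariantSite
from .signals import AlleleSignal, LocusProfile, to_profile
from .simulate import TruthTrack

__all__ = [
    "read_signal_tsv",
    "write_signal_tsv",
    "read_variant_tsv",
    "read_exon_bed",
    "write_calls_tsv",
    "write_segments_bed",
    "write_truth_bed",
    "load_yaml_config",
]

logger = logging.getLogger(__name__)


def read_signal_tsv(path) -> LocusProfile:
    """Read a BeadStudio-style signal table (chrom, pos, baf, log_r).

    Optional ``a_signal``/``b_signal`` columns take precedence when both
    are present (the profile is recomputed from them); otherwise ``rho``
    is recovered as ``2**log_r``.  Rows with non-finite baf or log_r are
    dropped with a logged count; positions are 1-based and kept verbatim.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "baf", "log_r"} - set(df.columns)
    if missing:
        raise ValidationError(f"signal TSV is missing columns: {sorted(missing)}")
    if {"a_signal", "b_signal"} <= set(df.columns):
        keep = np.isfinite(df["a_signal"]) & np.isfinite(df["b_signal"])
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropped %d rows with non-finite allele signals", dropped)
        df = df[keep]
        signal = AlleleSignal(a=df["a_signal"].to_numpy(), b=df["b_signal"].to_numpy())
        return to_profile(
            signal, chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy(dtype=int)
        )
    keep = np.isfinite(df["baf"]) & np.isfinite(df["log_r"])
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d rows with non-finite baf/log_r", dropped)
    df = df[keep]
    log_r = df["log_r"].to_numpy(dtype=float)
    return LocusProfile(
        beta=df["baf"].to_numpy(dtype=float),
        rho=np.power(2.0, log_r),
        log_r=log_r,
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(dtype=int),
    )


def _default_coords(profile_len: int, chrom, pos):
    if chrom is None:
        chrom = np.full(profile_len, "chrS")
    if pos is None:
        pos = np.arange(1, profile_len + 1)
    return np.asarray(chrom), np.asarray(pos)


def write_signal_tsv(profile: LocusProfile, path, signal: AlleleSignal | None = None) -> None:
    """Write a signal table; includes raw allele channels when given."""
    chrom, pos = _default_coords(profile.n_loci, profile.chrom, profile.pos)
    df = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "baf": profile.beta, "log_r": profile.log_r}
    )
    if signal is not None:
        df["a_signal"] = signal.a
        df["b_signal"] = signal.b
    df.to_csv(path, sep="\t", index=False)


def read_variant_tsv(path) -> list[VariantSite]:
    """Read a per-nucleotide count table (transcript_id, pos, ref, alt, counts)."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "pos", "ref", "alt", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"variant TSV is missing columns: {sorted(missing)}")
    if "masked" in df.columns:  # honor an upstream indel-adjacency mask
        df = df[~df["masked"].astype(bool)]
    return [
        VariantSite(
            transcript_id=str(row.transcript_id),
            position=int(row.pos),
            ref_base=str(row.ref),
            alt_base=str(row.alt),
            ref_count=int(row.ref_count),
            alt_count=int(row.alt_count),
        )
        for row in df.itertuples()
    ]


def read_exon_bed(path) -> dict[str, ExonAnnotation]:
    """Read exon boundaries from a BED file in transcript coordinates.

    The BED chrom column holds the transcript id; intervals are 0-based
    half-open as usual for BED.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValidationError("exon BED needs at least chrom, start, end columns")
    annotations = {}
    for tid, group in df.groupby(0):
        exons = sorted(zip(group[1].astype(int), group[2].astype(int)))
        annotations[str(tid)] = ExonAnnotation(transcript_id=str(tid), exons=tuple(exons))
    return annotations


def write_calls_tsv(
    calls: StateCallTrack, path, profile: LocusProfile | None = None
) -> None:
    """Write per-SNP calls: chrom, pos, baf, log_r, m, log_r_mean, state."""
    chrom = pos = None
    if profile is not None:
        chrom, pos = profile.chrom, profile.pos
    chrom, pos = _default_coords(calls.n_loci, chrom, pos)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "baf": profile.beta if profile is not None else np.nan,
            "log_r": profile.log_r if profile is not None else np.nan,
            "m": calls.m.m,
            "log_r_mean": calls.logr_mean,
            "state": calls.state,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _runs(states: np.ndarray):
    """Yield (start_index, end_index, state) for maximal runs of equal state."""
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            yield start, i, states[start]
            start = i


def write_segments_bed(calls: StateCallTrack, path, profile: LocusProfile | None = None) -> None:
    """Merge equal-state runs into BED intervals (chrom, start, end, state)."""
    chrom = pos = None
    if profile is not None:
        chrom, pos = profile.chrom, profile.pos
    chrom, pos = _default_coords(calls.n_loci, chrom, pos)
    rows = []
    for start, end, state in _runs(calls.state):
        rows.append(
            (chrom[start], int(pos[start]) - 1, int(pos[end - 1]), state)
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_truth_bed(truth: TruthTrack, path, chrom_label: str = "chrS") -> None:
    """Write per-subclone aberration blocks: chrom, start, end, state, subclone."""
    rows = []
    for sub_idx, specs in enumerate(truth.specs_by_subclone, start=1):
        for spec in specs:
            rows.append((chrom_label, spec.start, spec.end, spec.kind.sign, sub_idx))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def load_yaml_config(path) -> Mapping:
    """Load a YAML run-configuration mapping (empty file -> empty mapping)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValidationError("config file must contain a mapping at the top level")
    return data
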