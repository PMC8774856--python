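"""Base composition, AT/GC skews, CpG-island scanning and molecular weight.

Skews follow the strand-asymmetry convention

    AT-skew = (A - T) / (A + T),    GC-skew = (G - C) / (G + C),

computed on H-strand counts. A positive AT-skew means an excess of A over T.
When a denominator is zero the skew is reported as ``None`` (undefined), never
as a silent 0. N bases are tallied separately and excluded from percentage
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlphabetError, MitoprofileError
from .seq_io import AnnotatedMitogenome, FeatureRecord


@dataclass(frozen=True)
class BaseCounts:
    nA: int
    nC: int
    nG: int
    nT: int
    nN: int = 0

    @property
    def total(self) -> int:
        return self.nA + self.nC + self.nG + self.nT + self.nN

    @property
    def total_acgt(self) -> int:
        return self.nA + self.nC + self.nG + self.nT

    @classmethod
    def from_sequence(cls, seq: str) -> "BaseCounts":
        return cls(
            nA=seq.count("A"),
            nC=seq.count("C"),
            nG=seq.count("G"),
            nT=seq.count("T"),
            nN=seq.count("N"),
        )

    def __add__(self, other: "BaseCounts") -> "BaseCounts":
        return BaseCounts(
            self.nA + other.nA,
            self.nC + other.nC,
            self.nG + other.nG,
            self.nT + other.nT,
            self.nN + other.nN,
        )


@dataclass(frozen=True)
class CompositionProfile:
    region_label: str
    counts: BaseCounts
    at_percent: float | None
    gc_percent: float | None
    at_skew: float | None
    gc_skew: float | None
    molecular_weight_kDa: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Report dict with skews rounded half-away-from-zero to ``ndigits``."""

        def r(x, nd):
            if x is None:
                return None
            scaled = abs(x) * 10**nd
            return float(np.copysign(np.floor(scaled + 0.5) / 10**nd, x))

        c = self.counts
        return {
            "region_label": self.region_label,
            "A": c.nA,
            "C": c.nC,
            "G": c.nG,
            "T": c.nT,
            "N": c.nN,
            "AT_percent": r(self.at_percent, 2),
            "GC_percent": r(self.gc_percent, 2),
            "AT_skew": r(self.at_skew, ndigits),
            "GC_skew": r(self.gc_skew, ndigits),
        }


def profile_from_counts(counts: BaseCounts, label: str = "sequence") -> CompositionProfile:
    """Composition profile (percentages over non-N total, skews) from counts."""
    at = counts.nA + counts.nT
    gc = counts.nG + counts.nC
    denom = counts.total_acgt
    return CompositionProfile(
        region_label=label,
        counts=counts,
        at_percent=100.0 * at / denom if denom else None,
        gc_percent=100.0 * gc / denom if denom else None,
        at_skew=(counts.nA - counts.nT) / at if at else None,
        gc_skew=(counts.nG - counts.nC) / gc if gc else None,
    )


def base_stats(sequence: str, label: str = "sequence") -> CompositionProfile:
    """Counts, AT/GC percentages and skews of a sequence."""
    if not sequence:
        raise MitoprofileError("base_stats: empty sequence")
    return profile_from_counts(BaseCounts.from_sequence(sequence), label)


def _mask_profile(genome: AnnotatedMitogenome, mask: np.ndarray, label: str) -> CompositionProfile:
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1")
    sel = arr[mask]
    counts = BaseCounts(
        nA=int((sel == b"A").sum()),
        nC=int((sel == b"C").sum()),
        nG=int((sel == b"G").sum()),
        nT=int((sel == b"T").sum()),
        nN=int((sel == b"N").sum()),
    )
    return profile_from_counts(counts, label)


def partition_profiles(
    genome: AnnotatedMitogenome,
    features: Sequence[FeatureRecord] | None = None,
) -> list[CompositionProfile]:
    """Profiles for the whole genome, gene-class partitions and each feature.

    Partitions: whole genome; all PCGs; all tRNA genes; all rRNA genes;
    non-coding positions (everything not covered by a PCG/tRNA/rRNA gene,
    i.e. intergenic spacers, replication origin and control region); then one
    profile per individual feature. All counting is on the H-strand; within a
    partition, positions covered by overlapping member features are counted
    once.
    """
    feats = list(features) if features is not None else genome.features
    L = genome.length
    masks = {
        "genome": np.ones(L, dtype=bool),
        "PCGs": np.zeros(L, dtype=bool),
        "tRNAs": np.zeros(L, dtype=bool),
        "rRNAs": np.zeros(L, dtype=bool),
    }
    gene_cover = np.zeros(L, dtype=bool)
    for f in feats:
        span = slice(f.start - 1, f.end)
        if f.kind == "PCG":
            masks["PCGs"][span] = True
        elif f.kind == "tRNA":
            masks["tRNAs"][span] = True
        elif f.kind == "rRNA":
            masks["rRNAs"][span] = True
        if f.kind in ("PCG", "tRNA", "rRNA"):
            gene_cover[span] = True
    masks["non_coding"] = ~gene_cover

    out = [_mask_profile(genome, mask, label) for label, mask in masks.items()]
    for f in feats:
        m = np.zeros(L, dtype=bool)
        m[f.start - 1 : f.end] = True
        out.append(_mask_profile(genome, m, f.name))
    return out


@dataclass(frozen=True)
class CpGIsland:
    start: int  # 1-based inclusive
    end: int
    gc_percent: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_passes(seq: str, i: int, window: int, min_gc: float, min_obs_exp: float) -> bool:
    w = seq[i : i + window]
    nc, ng = w.count("C"), w.count("G")
    if 100.0 * (nc + ng) / window <= min_gc:
        return False
    if nc == 0 or ng == 0:
        return False
    obs_exp = w.count("CG") * window / (nc * ng)
    return obs_exp >= min_obs_exp


def find_cpg_islands(
    sequence: str,
    window: int = 100,
    min_length: int = 200,
    min_gc: float = 50.0,
    min_obs_exp: float = 0.6,
) -> list[CpGIsland]:
    """CpG islands by the sliding-window criterion of Gardiner-Garden & Frommer.

    A window of ``window`` bp qualifies when its G+C percentage exceeds
    ``min_gc`` and its observed/expected CpG ratio — ``nCpG * window /
    (nC * nG)`` — is at least ``min_obs_exp``. Overlapping or abutting
    qualifying windows are merged; merged islands shorter than ``min_length``
    are discarded; the reported GC% and obs/exp are recomputed over the merged
    span.
    """
    L = len(sequence)
    if window > L:
        raise MitoprofileError(f"window {window} exceeds sequence length {L}")
    qualifying = [
        i for i in range(L - window + 1)
        if _window_passes(sequence, i, window, min_gc, min_obs_exp)
    ]
    islands: list[CpGIsland] = []
    i = 0
    while i < len(qualifying):
        j = i
        # merge windows that overlap or abut the running span
        end = qualifying[i] + window - 1
        while j + 1 < len(qualifying) and qualifying[j + 1] <= end + 1:
            j += 1
            end = qualifying[j] + window - 1
        start = qualifying[i]
        span = sequence[start : end + 1]
        if len(span) >= min_length:
            nc, ng = span.count("C"), span.count("G")
            obs_exp = span.count("CG") * len(span) / (nc * ng) if nc and ng else 0.0
            islands.append(
                CpGIsland(
                    start=start + 1,
                    end=end + 1,
                    gc_percent=100.0 * (nc + ng) / len(span),
                    obs_exp_cpg=obs_exp,
                )
            )
        i = j + 1
    return islands


#: average masses (Da) of the anhydrous internal nucleotide-monophosphate
#: residues of a DNA chain (phosphodiester-linked; no terminal corrections are
#: applied for a closed circular strand)
RESIDUE_MASS_DA = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}


def molecular_weight(sequence: str, double_stranded: bool = True) -> float:
    """Molecular weight of a circular DNA molecule in kDa.

    Sums the average residue masses of the nucleotide monophosphates over the
    strand (and its complement when ``double_stranded``). Being circular, no
    terminal OH/phosphate correction is applied.
    """
    if set(sequence) - set("ACGT"):
        raise AlphabetError("molecular_weight requires a pure ACGT sequence")
    counts = BaseCounts.from_sequence(sequence)
    return molecular_weight_from_counts(counts, double_stranded=double_stranded)


def molecular_weight_from_counts(counts: BaseCounts, double_stranded: bool = True) -> float:
    m = (
        counts.nA * RESIDUE_MASS_DA["A"]
        + counts.nC * RESIDUE_MASS_DA["C"]
        + counts.nG * RESIDUE_MASS_DA["G"]
        + counts.nT * RESIDUE_MASS_DA["T"]
    )
    if double_stranded:
        # complement strand swaps A<->T and C<->G counts
        m += (
            counts.nT * RESIDUE_MASS_DA["A"]
            + counts.nG * RESIDUE_MASS_DA["C"]
            + counts.nC * RESIDUE_MASS_DA["G"]
            + counts.nA * RESIDUE_MASS_DA["T"]
        )
    return m / 1000.0
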