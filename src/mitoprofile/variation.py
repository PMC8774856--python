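"""Variant calling and diversity statistics from a multiple alignment of
conspecific mitogenomes.

A variant is one polymorphic alignment column (substitutions; a contiguous
run of gap columns shared by the same rows is merged into a single indel
event). Substitutions are typed as transitions (A<->G, C<->T) or
transversions. Diversity statistics follow the DnaSP conventions: by default
sites containing any gap or N are excluded entirely (complete deletion);
nucleotide diversity pi is the mean pairwise difference per considered site,
haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2), the conservation index C
is the fraction of monomorphic considered sites and k the mean pairwise
difference count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from Bio.Seq import Seq

from .errors import AlignmentError
from .seq_io import FeatureRecord, MultipleAlignment

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass
class VariantCall:
    ref_position: int  # 1-based on the gap-stripped reference row
    aln_column: int  # 1-based alignment column (first column of the event)
    kind: str  # transition | transversion | indel
    ref_allele: str
    alt_alleles: tuple[str, ...]
    carriers: tuple[str, ...]
    region: str = "NA"
    coding_effect: str = "NA"
    insertion_index: int = 0  # > 0 for insertions relative to the reference


def _col_array(aln: MultipleAlignment) -> np.ndarray:
    return np.array([list(r) for r in aln.rows], dtype="U1")


def _ref_position_map(ref_row: str) -> np.ndarray:
    """For each alignment column: 1-based position of the last reference base
    at or before that column (0 before the first base)."""
    pos = 0
    out = np.zeros(len(ref_row), dtype=int)
    for i, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
        out[i] = pos
    return out


def _region_of(pos: int, features: Sequence[FeatureRecord] | None) -> str:
    if not features:
        return "NA"
    for f in features:
        if f.start <= pos <= f.end:
            return f.name
    return "intergenic"


def call_variants(
    aln: MultipleAlignment,
    reference_id: str | None = None,
    features: Sequence[FeatureRecord] | None = None,
) -> list[VariantCall]:
    """One call per polymorphic column; shared contiguous gap runs merge into
    one indel event. A column holding both a substitution and a gap yields two
    calls. Multi-allelic columns count once, with every alternative allele
    recorded; the column is typed a transition only if every ref-alt pair is a
    transition.
    """
    if aln.n_rows < 2:
        raise AlignmentError("variant calling requires at least 2 rows")
    ref_id = reference_id or aln.reference_id
    cols = _col_array(aln)
    ridx = aln.ids.index(ref_id)
    refmap = _ref_position_map(aln.rows[ridx])
    calls: list[VariantCall] = []

    # substitutions, column by column
    for c in range(aln.n_columns):
        col = cols[:, c]
        bases = [b for b in col if b not in ("-", "N")]
        states = sorted(set(bases))
        if len(states) < 2:
            continue
        ref_base = col[ridx]
        if ref_base in ("-", "N"):
            # insertion/ambiguity relative to reference; substitution typed
            # against the majority state
            counts = {s: bases.count(s) for s in states}
            ref_base = max(sorted(states), key=counts.get)
        alts = tuple(s for s in states if s != ref_base)
        if not alts:
            continue
        carriers = tuple(
            aln.ids[i] for i in range(aln.n_rows) if col[i] in alts
        )
        kind = "transition" if all(is_transition(ref_base, a) for a in alts) else "transversion"
        pos = int(refmap[c])
        calls.append(
            VariantCall(
                ref_position=max(pos, 1),
                aln_column=c + 1,
                kind=kind,
                ref_allele=str(ref_base),
                alt_alleles=alts,
                carriers=carriers,
                region=_region_of(max(pos, 1), features),
            )
        )

    # indels: maximal runs of columns with an identical non-empty gap pattern
    gap = cols == "-"
    c = 0
    while c < aln.n_columns:
        pattern = gap[:, c]
        if not pattern.any():
            c += 1
            continue
        d = c
        while d + 1 < aln.n_columns and (gap[:, d + 1] == pattern).all() and gap[:, d + 1].any():
            d += 1
        carriers = tuple(aln.ids[i] for i in range(aln.n_rows) if pattern[i])
        ref_has_gap = bool(pattern[ridx])
        pos = int(refmap[c])
        ref_allele = "-" * (d - c + 1) if ref_has_gap else aln.rows[ridx][c : d + 1]
        alt = (
            "".join(cols[np.flatnonzero(~pattern)[0], c : d + 1])
            if ref_has_gap
            else "-" * (d - c + 1)
        )
        calls.append(
            VariantCall(
                ref_position=max(pos, 1),
                aln_column=c + 1,
                kind="indel",
                ref_allele=ref_allele,
                alt_alleles=(alt,),
                carriers=carriers,
                region=_region_of(max(pos, 1), features),
                insertion_index=1 if ref_has_gap else 0,
            )
        )
        c = d + 1
    calls.sort(key=lambda v: (v.aln_column, v.kind))
    return calls


def classify_coding_effect(
    variant: VariantCall,
    genome,
    features: Sequence[FeatureRecord],
) -> str:
    """Effect of a substitution under the vertebrate mitochondrial code.

    ``synonymous`` / ``missense`` / ``nonsense`` for substitutions inside a
    protein-coding gene (L-strand genes handled by complementing the alleles),
    ``noncoding`` outside PCGs, ``NA`` for indels (frameshift classification
    is out of scope).
    """
    if variant.kind == "indel":
        return "NA"
    pos = variant.ref_position
    pcg = next(
        (f for f in features if f.kind == "PCG" and f.start <= pos <= f.end), None
    )
    if pcg is None:
        return "noncoding"
    gene_seq = genome.extract(pcg)
    if pcg.strand == "H":
        off = pos - pcg.start
        ref_allele, alt_allele = variant.ref_allele, variant.alt_alleles[0]
    else:
        off = pcg.end - pos
        comp = str.maketrans("ACGTN", "TGCAN")
        ref_allele = variant.ref_allele.translate(comp)
        alt_allele = variant.alt_alleles[0].translate(comp)
    codon_i, codon_off = divmod(off, 3)
    codon = gene_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "NA"  # inside the incomplete terminal codon
    alt_codon = codon[:codon_off] + alt_allele + codon[codon_off + 1 :]
    ref_aa = str(Seq(codon).translate(table=2))
    alt_aa = str(Seq(alt_codon).translate(table=2))
    if alt_aa == "*":
        return "nonsense" if ref_aa != "*" else "synonymous"
    return "synonymous" if ref_aa == alt_aa else "missense"


def incidence(n_variants: int, length_bp: int) -> tuple[float, float] | None:
    """Variant incidence as ('one variant per X bp', percent of nucleotides).

    Returns None when there are no variants.
    """
    if length_bp <= 0:
        raise AlignmentError("incidence requires a positive length")
    if n_variants == 0:
        return None
    return (
        round(length_bp / n_variants, 1),
        round(100.0 * n_variants / length_bp, 2),
    )


@dataclass
class DiversityStats:
    pi: float
    hd: float
    c_index: float
    k: float
    n_haplotypes: int
    n_variable_sites: int
    n_singleton_sites: int
    n_parsimony_informative_sites: int
    sites_considered: int
    incidence_bp: float | None

    @property
    def incidence(self) -> tuple[float, float] | None:
        return incidence(self.n_variable_sites, self.sites_considered)


def _considered_columns(cols: np.ndarray, gap_mode: str) -> np.ndarray:
    bad = (cols == "-") | (cols == "N")
    if gap_mode == "complete_deletion":
        return ~bad.any(axis=0)
    if gap_mode == "all":
        return np.ones(cols.shape[1], dtype=bool)
    raise AlignmentError(f"unknown gap_mode {gap_mode!r}")


def diversity_stats(
    aln: MultipleAlignment, gap_mode: str = "complete_deletion"
) -> DiversityStats:
    """pi, Hd, conservation index C, k and site classes for an alignment."""
    if aln.n_rows < 2:
        raise AlignmentError("diversity statistics require at least 2 rows")
    cols = _col_array(aln)
    mask = _considered_columns(cols, gap_mode)
    m = int(mask.sum())
    if m == 0:
        raise AlignmentError("no sites remain after gap/N exclusion")
    sub = cols[:, mask]
    n = aln.n_rows

    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(int((sub[i] != sub[j]).sum()))
    k = float(np.mean(diffs))
    pi = k / m

    variable = 0
    singleton = 0
    informative = 0
    for c in range(m):
        col = sub[:, c]
        states, counts = np.unique(col, return_counts=True)
        if len(states) > 1:
            variable += 1
            if all(c == 1 for c in sorted(counts)[:-1]):
                singleton += 1
            if (counts >= 2).sum() >= 2:
                informative += 1

    hap = haplotype_partition(aln, include_indels=(gap_mode == "all"))
    freqs = np.array([len(members) for members in hap.values()])
    p = freqs / freqs.sum()
    hd = (n / (n - 1)) * (1.0 - float((p**2).sum())) if n > 1 else 0.0

    inc = incidence(variable, m)
    return DiversityStats(
        pi=pi,
        hd=hd,
        c_index=1.0 - variable / m,
        k=k,
        n_haplotypes=len(hap),
        n_variable_sites=variable,
        n_singleton_sites=singleton,
        n_parsimony_informative_sites=informative,
        sites_considered=m,
        incidence_bp=inc[0] if inc else None,
    )


def haplotype_diversity(frequencies: Sequence[int]) -> float:
    """Hd = n/(n-1) * (1 - sum p_i^2) from a haplotype frequency vector."""
    freqs = np.asarray(frequencies, dtype=float)
    n = freqs.sum()
    if n < 2:
        return 0.0
    p = freqs / n
    return float((n / (n - 1)) * (1.0 - (p**2).sum()))


def haplotype_partition(
    aln: MultipleAlignment, include_indels: bool = False
) -> dict[int, list[str]]:
    """Group rows identical over considered sites; numbered by first occurrence.

    With ``include_indels=False`` (default) columns containing any gap are
    excluded before comparison, so length variants of the same substitution
    haplotype merge.
    """
    cols = _col_array(aln)
    if include_indels:
        mask = np.ones(cols.shape[1], dtype=bool)
    else:
        mask = ~(cols == "-").any(axis=0)
    keys: dict[str, int] = {}
    partition: dict[int, list[str]] = {}
    for rid, row in zip(aln.ids, cols[:, mask]):
        key = "".join(row)
        if key not in keys:
            keys[key] = len(keys) + 1
            partition[keys[key]] = []
        partition[keys[key]].append(rid)
    return partition


@dataclass
class HaplotypeNetwork:
    nodes: dict[int, dict]  # haplotype number -> {"members": [...], "frequency": int}
    edges: list[tuple[int, int, int]]  # (node, node, n_differences)


def haplotype_network(
    partition: dict[int, list[str]], aln: MultipleAlignment
) -> HaplotypeNetwork:
    """Minimum-spanning network over haplotypes.

    Hamming distances between one representative row per haplotype (gap
    columns excluded); the network is the union of all minimum spanning
    trees — an edge belongs to some MST exactly when its endpoints are not
    already connected by strictly lighter edges.
    """
    if len(partition) < 2:
        raise AlignmentError("a network requires at least 2 haplotypes")
    cols = _col_array(aln)
    mask = ~(cols == "-").any(axis=0)
    reps = {
        h: cols[aln.ids.index(members[0]), mask] for h, members in partition.items()
    }
    hids = sorted(partition)
    dist = {}
    for i, a in enumerate(hids):
        for b in hids[i + 1 :]:
            dist[(a, b)] = int((reps[a] != reps[b]).sum())

    edges = []
    weights = sorted(set(dist.values()))
    for w in weights:
        lighter = nx.Graph()
        lighter.add_nodes_from(hids)
        lighter.add_edges_from(e for e, d in dist.items() if d < w)
        for (a, b), d in dist.items():
            if d == w and not nx.has_path(lighter, a, b):
                edges.append((a, b, d))
    nodes = {
        h: {"members": list(members), "frequency": len(members)}
        for h, members in partition.items()
    }
    return HaplotypeNetwork(nodes=nodes, edges=sorted(edges))


@dataclass
class WindowStats:
    start: int  # 1-based alignment column
    end: int
    n_variants: int
    incidence_bp: float | None
    c_index: float


def variability_track(
    aln: MultipleAlignment,
    window: int = 50,
    step: int = 10,
    hvs_incidence: float = 1.0 / 25.0,
) -> tuple[list[WindowStats], list[tuple[int, int]]]:
    """Per-window variant density and conservation, plus merged hypervariable
    segments (windows whose variant incidence meets ``hvs_incidence``)."""
    if window > aln.n_columns:
        raise AlignmentError("window exceeds alignment length")
    cols = _col_array(aln)
    variable = np.array(
        [len({b for b in cols[:, c]}) > 1 for c in range(aln.n_columns)]
    )
    out = []
    hot = []
    for start in range(0, aln.n_columns - window + 1, step):
        n_var = int(variable[start : start + window].sum())
        inc = incidence(n_var, window)
        out.append(
            WindowStats(
                start=start + 1,
                end=start + window,
                n_variants=n_var,
                incidence_bp=inc[0] if inc else None,
                c_index=1.0 - n_var / window,
            )
        )
        if n_var / window >= hvs_incidence:
            hot.append((start + 1, start + window))
    merged: list[tuple[int, int]] = []
    for s, e in hot:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return out, merged
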