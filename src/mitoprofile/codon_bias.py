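"""Codon usage and codon-bias statistics under the vertebrate mitochondrial code.

Protein-coding genes of vertebrate mitogenomes frequently end in incomplete
stop codons (a bare T or TA at the genome level) that are completed to TAA by
polyadenylation of the mRNA. :func:`extract_cds` applies that completion
before any counting, so stop-codon usage includes the completed TAAs.

Under translation table 2 the 60 sense codons partition into 12 two-fold,
6 four-fold and 2 six-fold synonymous families (Leu and Ser are treated as
single six-fold families); the stop family is {TAA, TAG, AGA, AGG}. This
class structure fixes the bounds of the effective number of codons:
ENc = 20 at maximal bias, 60 when all synonymous codons are used equally.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio.Data import CodonTable

from .errors import CodingSequenceError, MitoprofileError
from .seq_io import AnnotatedMitogenome, FeatureRecord

_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))  # ('AGA', 'AGG', 'TAA', 'TAG')
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
CODON_TO_AA = dict(_TABLE.forward_table)

#: synonymous families: amino acid -> sorted tuple of codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] = FAMILIES[_aa] + (_c,)

#: degeneracy classes of the mito code: k -> number of families
DEGENERACY_CLASSES = Counter(len(v) for v in FAMILIES.values())
assert dict(DEGENERACY_CLASSES) == {2: 12, 4: 6, 6: 2}


@dataclass
class CodingSequence:
    gene: str
    codons: list[str]
    start_codon: str
    stop_codon: str
    stop_completion: str  # none | TA_plus_A | T_plus_AA
    strand: str
    atypical_start: bool = False


def extract_cds(
    genome: AnnotatedMitogenome,
    feature: FeatureRecord,
    allow_internal_stops: bool = False,
) -> CodingSequence:
    """Extract a PCG as codons, completing incomplete stop codons with A's.

    L-strand genes are reverse-complemented before codon splitting. A
    trailing length of 1 mod 3 is a bare-T stop (completed T+AA), 2 mod 3 a
    TA stop (completed TA+A); both yield a final TAA codon, so the codon
    count is ``ceil(size/3)``. An in-frame stop before the final codon raises
    :class:`CodingSequenceError` naming its position; a start codon that is
    not ATN sets ``atypical_start`` and emits a warning.
    """
    if feature.kind != "PCG":
        raise CodingSequenceError(f"{feature.name}: extract_cds requires kind=PCG")
    seq = genome.extract(feature)
    rem = len(seq) % 3
    if rem == 1:
        completion, seq = "T_plus_AA", seq + "AA"
    elif rem == 2:
        completion, seq = "TA_plus_A", seq + "A"
    else:
        completion = "none"
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons[:-1]):
        if codon in STOP_CODONS and not allow_internal_stops:
            raise CodingSequenceError(
                f"{feature.name}: internal in-frame stop {codon} at codon {idx + 1}"
            )
    start = codons[0]
    atypical = not (start[:2] == "AT")
    if atypical:
        warnings.warn(f"{feature.name}: start codon {start} is not ATN", stacklevel=2)
    return CodingSequence(
        gene=feature.name,
        codons=codons,
        start_codon=start,
        stop_codon=codons[-1],
        stop_completion=completion,
        strand=feature.strand,
        atypical_start=atypical,
    )


def classify_start_stop(cds: CodingSequence) -> tuple[str, str]:
    """Start class (ATG/ATA/ATT/ATC/other) and stop class of a coding sequence."""
    start = cds.start_codon if cds.start_codon in ("ATG", "ATA", "ATT", "ATC") else "other"
    if cds.stop_completion == "T_plus_AA":
        stop = "incomplete_T"
    elif cds.stop_completion == "TA_plus_A":
        stop = "incomplete_TA"
    elif cds.stop_codon == "TAA":
        stop = "TAA_complete"
    elif cds.stop_codon == "AGA":
        stop = "AGA_complete"
    else:
        stop = "other"
    return start, stop


@dataclass
class CodonUsageTable:
    """Pooled codon counts with derived percentages and amino-acid frequencies.

    ``counts`` may hold non-integer weights (e.g. when built from a printed
    percentage table); every derived statistic is scale-free or uses the
    weights consistently.
    """

    counts: dict[str, float]
    discarded_with_N: int = 0

    @property
    def total_codons(self) -> float:
        return sum(self.counts.values())

    @property
    def total_sense(self) -> float:
        return sum(v for c, v in self.counts.items() if c in CODON_TO_AA)

    @property
    def percent(self) -> dict[str, float]:
        tot = self.total_codons
        return {c: 100.0 * v / tot for c, v in self.counts.items()} if tot else {}

    @property
    def aa_percent(self) -> dict[str, float]:
        """Per amino acid (stops pooled as '*'), percentage of all codons."""
        tot = self.total_codons
        agg: dict[str, float] = defaultdict(float)
        for c, v in self.counts.items():
            agg[CODON_TO_AA.get(c, "*")] += v
        return {aa: 100.0 * v / tot for aa, v in agg.items()} if tot else {}

    def family_counts(self, aa: str) -> list[float]:
        return [self.counts.get(c, 0.0) for c in FAMILIES[aa]]

    @classmethod
    def from_cds(
        cls, cds_list: Iterable[CodingSequence], include_stops: bool = True
    ) -> "CodonUsageTable":
        counts: Counter[str] = Counter()
        discarded = 0
        for cds in cds_list:
            for codon in cds.codons:
                if "N" in codon:
                    discarded += 1
                elif include_stops or codon in CODON_TO_AA:
                    counts[codon] += 1
        return cls(counts=dict(counts), discarded_with_N=discarded)

    @classmethod
    def from_percent(cls, percent: Mapping[str, float]) -> "CodonUsageTable":
        """Build a table from printed percentages, used as relative weights."""
        return cls(counts={c: float(p) for c, p in percent.items()})


def codon_usage(
    cds_list: Sequence[CodingSequence], include_stops: bool = True
) -> CodonUsageTable:
    """Pooled codon usage over one or more coding sequences."""
    if not cds_list:
        raise MitoprofileError("codon_usage requires at least one coding sequence")
    return CodonUsageTable.from_cds(cds_list, include_stops=include_stops)


def rscu(usage: CodonUsageTable) -> dict[str, float | None]:
    """Relative synonymous codon usage.

    For a codon in a synonymous family of size ``k`` with family total ``N``:
    ``RSCU = k * count / N``. Families with no observations map to ``None``
    for each member codon.
    """
    out: dict[str, float | None] = {}
    for aa, codons in FAMILIES.items():
        fam_total = sum(usage.counts.get(c, 0.0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = (k * usage.counts.get(c, 0.0) / fam_total) if fam_total > 0 else None
    return out


def _family_homozygosity(counts: Sequence[float]) -> float | None:
    """Wright's codon homozygosity F = (n*sum(p^2) - 1) / (n - 1); None if n <= 1."""
    n = sum(counts)
    if n <= 1:
        return None
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(usage: CodonUsageTable, impute_empty_classes: bool = True) -> float:
    """Effective number of codons (Wright) under the mitochondrial code.

    Per-family homozygosities are averaged within each degeneracy class
    (2-, 4-, 6-fold) and ENc = sum over classes of m_k / mean(F_k). Families
    with fewer than 2 observations are excluded from their class mean; an
    empty class is imputed from the global mean F of eligible families
    (disable with ``impute_empty_classes`` to get an error instead). The
    result is clipped to the theoretical maximum of 60.
    """
    by_class: dict[int, list[float]] = defaultdict(list)
    for aa, codons in FAMILIES.items():
        f = _family_homozygosity(usage.family_counts(aa))
        if f is not None:
            by_class[len(codons)].append(f)
    all_f = [f for fs in by_class.values() for f in fs]
    if not all_f:
        raise MitoprofileError("ENc undefined: no synonymous family has >= 2 codons")
    global_mean = sum(all_f) / len(all_f)
    total = 0.0
    for k, m_k in sorted(DEGENERACY_CLASSES.items()):
        fs = by_class.get(k, [])
        if fs:
            mean_f = sum(fs) / len(fs)
        elif impute_empty_classes:
            mean_f = global_mean
        else:
            raise MitoprofileError(f"ENc undefined: no eligible {k}-fold family")
        if mean_f <= 0:
            mean_f = 1.0 / k  # guard: F cannot fall below the uniform bound
        total += m_k / mean_f
    return min(total, 60.0)


def optimal_codons(usage: CodonUsageTable) -> dict[str, str]:
    """Most frequent codon per synonymous family (alphabetical tie-break)."""
    out = {}
    for aa, codons in FAMILIES.items():
        out[aa] = max(codons, key=lambda c: (usage.counts.get(c, 0.0), [-ord(x) for x in c]))
    return out


def cbi(
    usage: CodonUsageTable,
    optimal: Mapping[str, str] | None = None,
) -> float:
    """Codon bias index of Bennetzen & Hall.

    ``CBI = (N_opt - N_ran) / (N_tot - N_ran)`` where N_opt counts occurrences
    of the optimal codons, N_tot counts all codons of amino acids with >= 2
    synonyms (all of them, under the mito code) and N_ran = sum over amino
    acids of n_aa / k_aa is the count expected under uniform synonymous usage.
    With ``optimal=None`` the optimal set is the per-family argmax of the
    supplied usage itself.
    """
    opt = dict(optimal) if optimal is not None else optimal_codons(usage)
    n_opt = n_tot = n_ran = 0.0
    for aa, codons in FAMILIES.items():
        fam = sum(usage.counts.get(c, 0.0) for c in codons)
        n_tot += fam
        n_ran += fam / len(codons)
        n_opt += usage.counts.get(opt[aa], 0.0)
    if math.isclose(n_tot, n_ran):
        raise MitoprofileError("CBI undefined: N_tot equals N_ran")
    return (n_opt - n_ran) / (n_tot - n_ran)


def gc3s(usage: CodonUsageTable) -> float:
    """G+C fraction at third positions of sense codons (stops excluded)."""
    tot = usage.total_sense
    if tot == 0:
        raise MitoprofileError("gc3s undefined: no sense codons")
    gc = sum(v for c, v in usage.counts.items() if c in CODON_TO_AA and c[2] in "GC")
    return gc / tot


def enc_expected(s: float) -> float:
    """Expected ENc at GC3s = s under pure compositional drift:
    ``ENc*(s) = 2 + s + 29 / (s^2 + (1-s)^2)``."""
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def gc3s_and_curve(usage: CodonUsageTable) -> tuple[float, float]:
    """(GC3s, expected ENc at that GC3s) for the ENc–GC3s plot."""
    s = gc3s(usage)
    return s, enc_expected(s)


@dataclass
class CodonBiasStats:
    rscu: dict[str, float | None]
    enc: float
    cbi: float
    gc3s: float
    enc_expected_at_gc3s: float


def bias_stats(
    usage: CodonUsageTable, optimal: Mapping[str, str] | None = None
) -> CodonBiasStats:
    s, expected = gc3s_and_curve(usage)
    return CodonBiasStats(
        rscu=rscu(usage),
        enc=enc(usage),
        cbi=cbi(usage, optimal=optimal),
        gc3s=s,
        enc_expected_at_gc3s=expected,
    )


def per_gene_bias_table(genome: AnnotatedMitogenome) -> list[dict]:
    """ENc / CBI / GC3s per PCG plus a pooled all-PCG row.

    The CBI optimal-codon set is taken from the pooled usage, so per-gene CBI
    measures use of the genome-wide preferred codons.
    """
    pcgs = [f for f in genome.features if f.kind == "PCG"]
    cds_list = [extract_cds(genome, f) for f in pcgs]
    pooled = codon_usage(cds_list)
    sense_pooled = CodonUsageTable(
        counts={c: v for c, v in pooled.counts.items() if c in CODON_TO_AA}
    )
    opt = optimal_codons(sense_pooled)
    rows = []
    for cds in cds_list:
        u = CodonUsageTable.from_cds([cds], include_stops=False)
        rows.append(
            {
                "gene": cds.gene,
                "enc": enc(u),
                "cbi": cbi(u, optimal=opt),
                "gc3s": gc3s(u),
            }
        )
    rows.append(
        {
            "gene": "overall_PCGs",
            "enc": enc(sense_pooled),
            "cbi": cbi(sense_pooled, optimal=opt),
            "gc3s": gc3s(sense_pooled),
        }
    )
    return rows


def load_reference_usage() -> CodonUsageTable:
    """The bundled pooled codon-usage percentages of the mink reference PCGs."""
    ref = resources.files("mitoprofile.data").joinpath("mink_codon_usage.tsv")
    percent: dict[str, float] = {}
    with resources.as_file(ref) as p, open(p) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            codon, _aa, pct = line.split("\t")
            percent[codon] = float(pct)
    return CodonUsageTable.from_percent(percent)
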