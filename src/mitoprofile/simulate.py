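"""Synthetic mitogenome and haplotype-set generator with known ground truth.

The generator emulates the structure every pipeline stage expects from a
mustelid-like mitogenome: a ~16.5 kb circular sequence with the bundled gene
layout, a biased base composition (A > T > C > G, A+T around 60%), simple
sequence repeats, a minisatellite array and conserved motifs planted in the
control region, a stem-loop at the light-strand replication origin, and
haplotype sets produced by a star-genealogy substitution + indel process with
known rates. Every planted element and every introduced mutation is recorded,
so detector recall and variant-calling output can be scored exactly.

The mutation process is deliberately single-hit (mu <= 0.01 is enforced): each
haplotype mutates independently from the common ancestor, so the expected
pairwise difference per ungapped site is 2*mu and the transition fraction of
substitutions is kappa/(kappa+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .codon_bias import STOP_CODONS
from .control_region import load_motif_library
from .errors import SimulationError
from .seq_io import (
    AnnotatedMitogenome,
    FeatureRecord,
    MultipleAlignment,
    load_feature_template,
    revcomp,
)

#: H-strand base fractions of the reference mitogenome (A, C, G, T)
DEFAULT_BASE_FRACTIONS = (0.3282, 0.2611, 0.1383, 0.2724)


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # ssr | tandem | motif | hairpin
    payload: str  # repeat unit, motif, or hairpin stem
    copies: int = 1
    loop_length: int = 0  # hairpins only
    position: int | None = None  # 1-based; None = place within the CR
    name: str = ""


def default_planted_elements() -> list[PlantedElement]:
    """The study-like default plant set: control-region SSRs, the RS3-style
    minisatellite and the origin stem-loop (the conserved CR motifs, including
    the GCCCCAT D-loop terminator, come from the motif library plants)."""
    return [
        PlantedElement(kind="ssr", payload="CT", copies=3, name="(CT)3"),
        PlantedElement(kind="ssr", payload="AT", copies=3, name="(AT)3"),
        PlantedElement(kind="ssr", payload="T", copies=6, name="T6"),
        PlantedElement(kind="ssr", payload="C", copies=7, name="C7"),
        PlantedElement(kind="ssr", payload="G", copies=8, name="G8"),
        PlantedElement(kind="tandem", payload="GCACACGTAC", copies=22, name="RS3"),
        PlantedElement(
            kind="hairpin", payload="GGCTAGCATCG", loop_length=13,
            position=5171, name="OL_stem_loop",
        ),
    ]


@dataclass
class GenomeSpec:
    length: int = 16_504
    base_fractions: tuple[float, float, float, float] = DEFAULT_BASE_FRACTIONS
    feature_template: list[FeatureRecord] | None = None
    planted_elements: list[PlantedElement] | None = None
    plant_cr_motifs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_fractions) - 1.0) > 1e-9:
            raise SimulationError("base fractions must sum to 1")
        if self.length < 1000:
            raise SimulationError("genome length < 1 kb is not supported")


@dataclass
class MutationSpec:
    n_haplotypes: int = 6
    mu: float = 0.002  # expected substitutions per site per lineage
    kappa: float = 10.0  # transition/transversion rate ratio
    indel_rate: float = 1e-4  # expected indel events per site per lineage
    indel_length_geometric_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.indel_rate < 0:
            raise SimulationError("rates must be >= 0")
        if self.kappa <= 0:
            raise SimulationError("kappa must be > 0")
        if self.mu > 0.01:
            raise SimulationError(
                "mu > 0.01 leaves the single-hit regime this generator supports"
            )


def _render(element: PlantedElement, rng: np.random.Generator) -> str:
    if element.kind in ("ssr", "tandem"):
        return element.payload * element.copies
    if element.kind == "motif":
        return element.payload
    if element.kind == "hairpin":
        pairs = {"A": "T", "T": "A", "C": "G", "G": "C"}
        while True:
            loop = "".join(rng.choice(list("ACGT"), size=element.loop_length))
            # loop ends must not base-pair, or the stem would extend inward
            if loop[0] != pairs[loop[-1]]:
                break
        return element.payload + loop + revcomp(element.payload)
    raise SimulationError(f"unknown planted element kind {element.kind!r}")


def generate_genome(spec: GenomeSpec) -> tuple[AnnotatedMitogenome, dict]:
    """Draw a background genome, plant elements, and return it with its truth
    record (exact coordinates of everything planted). Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    features = (
        list(spec.feature_template)
        if spec.feature_template is not None
        else load_feature_template()
    )
    if features and max(f.end for f in features) > spec.length:
        raise SimulationError("feature template does not fit the requested length")
    plants = (
        list(spec.planted_elements)
        if spec.planted_elements is not None
        else default_planted_elements()
    )

    cr = next((f for f in features if f.kind == "control_region"), None)

    # resolve placements before sampling so misfits fail fast
    placements: list[tuple[PlantedElement, int, str]] = []  # (element, start0, rendered)
    occupied: list[tuple[int, int]] = []
    cr_items: list[tuple[PlantedElement, str]] = []  # (element, rendered)
    if spec.plant_cr_motifs and cr is not None:
        for entry in load_motif_library():
            cr_items.append(
                (PlantedElement(kind="motif", payload=entry.motif, name=entry.element),
                 entry.motif)
            )
    for el in plants:
        rendered = _render(el, rng)
        if el.position is None:
            cr_items.append((el, rendered))
        else:
            start0 = el.position - 1
            placements.append((el, start0, rendered))
            occupied.append((start0, start0 + len(rendered) - 1))

    # lay the CR items left-to-right with small random spacers
    truth_elements: list[dict] = []
    if cr_items:
        if cr is None:
            raise SimulationError("CR-placed elements require a control_region feature")
        total = sum(len(r) for _, r in cr_items)
        slack = (cr.end - cr.start + 1) - total
        if slack < len(cr_items):
            raise SimulationError("planted elements do not fit inside the control region")
        gaps = rng.multinomial(slack - len(cr_items), [1 / len(cr_items)] * len(cr_items))
        pos0 = cr.start - 1
        for (el, rendered), extra in zip(cr_items, gaps):
            pos0 += 1 + int(extra)
            placements.append((el, pos0, rendered))
            occupied.append((pos0, pos0 + len(rendered) - 1))
            pos0 += len(rendered)

    spans = sorted(occupied)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise SimulationError("planted elements overlap")
    if spans and spans[-1][1] >= spec.length:
        raise SimulationError("planted element extends past the genome end")

    # background draw
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=spec.length, p=spec.base_fractions)

    for el, start0, rendered in placements:
        seq[start0 : start0 + len(rendered)] = list(rendered)
        truth_elements.append(
            {
                "name": el.name or el.kind,
                "kind": el.kind,
                "start": start0 + 1,
                "end": start0 + len(rendered),
                "unit": el.payload,
                "copies": el.copies,
                "loop_length": el.loop_length,
            }
        )

    planted_mask = np.zeros(spec.length, dtype=bool)
    for s, e in spans:
        planted_mask[s : e + 1] = True
    _scrub_pcg_stops(seq, features, planted_mask, rng, spec.base_fractions)

    genome = AnnotatedMitogenome(
        id=f"synthetic_{spec.seed}",
        sequence="".join(seq),
        circular=True,
        features=features,
    )
    truth = {
        "seed": spec.seed,
        "elements": truth_elements,
        "base_fractions": tuple(spec.base_fractions),
    }
    return genome, truth


#: composition-preserving single-base repairs: each alternative differs from
#: the stop codon at one position and has the same A+T count, so scrubbing
#: does not shift the genome composition (TGA and TGG are sense in the mito code)
_STOP_REPAIRS = {
    "TAA": ("AAA", "TTA", "TAT"),
    "TAG": ("AAG", "TTG", "TAC"),
    "AGA": ("TGA", "ACA", "AGT"),
    "AGG": ("TGG", "ACG", "AGC"),
}


def _break_stop(
    codon: str, rng: np.random.Generator, fractions: Sequence[float], greedy: bool
) -> str | None:
    """Minimal edit turning a stop codon into a sense codon.

    Normally a composition-preserving swap is drawn; in ``greedy`` mode (used
    when overlapping reading frames keep re-creating stops) any single-base
    change to a sense codon is allowed, weighted by the background fractions.
    """
    if not greedy:
        return str(rng.choice(_STOP_REPAIRS[codon]))
    for posn in rng.permutation(3):
        choices, weights = [], []
        for b, w in zip("ACGT", fractions):
            if b == codon[posn]:
                continue
            cand = codon[:posn] + b + codon[posn + 1 :]
            if cand in STOP_CODONS:
                continue
            choices.append(cand)
            weights.append(w)
        if choices:
            p = np.array(weights) / sum(weights)
            return str(rng.choice(choices, p=p))
    return None


def _scrub_pcg_stops(
    seq: np.ndarray,
    features: Sequence[FeatureRecord],
    protected: np.ndarray,
    rng: np.random.Generator,
    fractions: Sequence[float],
    max_passes: int = 100,
) -> None:
    """Resample in-frame internal stop codons of every PCG (both strands) and
    impose canonical start/stop signals, skipping protected (planted) spans.

    Overlapping genes can reintroduce stops into each other, so passes repeat
    until a clean pass or the cap is hit.
    """
    pcgs = [f for f in features if f.kind == "PCG"]

    def write_run(f: FeatureRecord, offset: int, text: str) -> bool:
        """Write ``text`` at reading-frame offset ``offset`` of gene ``f``
        (strand-aware); returns True when any base actually changed."""
        if f.strand == "H":
            s0 = f.start - 1 + offset
            e0 = s0 + len(text)
            payload = list(text)
        else:
            e0 = f.end - offset
            s0 = e0 - len(text)
            payload = list(revcomp(text))
        if s0 < 0 or e0 > len(seq) or protected[s0:e0].any():
            return False
        changed = "".join(seq[s0:e0]) != "".join(payload)
        seq[s0:e0] = payload
        return changed

    def gene_codons(f: FeatureRecord) -> list[str]:
        sub = "".join(seq[f.start - 1 : f.end])
        g = revcomp(sub) if f.strand == "L" else sub
        return [g[i : i + 3] for i in range(0, len(g) - len(g) % 3, 3)]

    for pass_i in range(max_passes):
        dirty = False
        for f in pcgs:  # canonical start; terminal (possibly incomplete) stop
            size = f.end - f.start + 1
            rem = size % 3
            tail = {0: "TAA", 1: "T", 2: "TA"}[rem]
            dirty |= write_run(f, 0, "ATG")
            dirty |= write_run(f, size - len(tail), tail)
        for f in pcgs:
            codons = gene_codons(f)
            if (f.end - f.start + 1) % 3 == 0:
                codons = codons[:-1]  # the final codon is the genomic stop
            # (with an incomplete terminal codon every full codon is internal)
            for idx, codon in enumerate(codons):
                if codon in STOP_CODONS:
                    replacement = _break_stop(codon, rng, fractions, greedy=pass_i >= 10)
                    if replacement is not None and write_run(f, idx * 3, replacement):
                        dirty = True
        if not dirty:
            return
    raise SimulationError("could not reconcile reading frames of overlapping genes")


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


def simulate_haplotypes(
    genome: AnnotatedMitogenome, mspec: MutationSpec
) -> tuple[MultipleAlignment, dict]:
    """Star-genealogy haplotype set, returned already aligned.

    Each haplotype mutates independently from the ancestral genome:
    per-site Bernoulli(mu) substitutions (transition with probability
    kappa/(kappa+1)), and Bernoulli(indel_rate) indel events with geometric
    lengths. Insertion columns are added to the alignment directly, so no
    aligner is involved. The truth record lists every event and the exact
    per-column expected variant calls.
    """
    rng = np.random.default_rng(mspec.seed)
    L = genome.length
    anc = np.array(list(genome.sequence))
    n = mspec.n_haplotypes
    ids = [f"hap{i + 1}" for i in range(n)]
    p_ts = mspec.kappa / (mspec.kappa + 1.0)

    sub_base: dict[tuple[int, int], str] = {}  # (hap, pos0) -> new base
    deletions: dict[int, set[int]] = {h: set() for h in range(n)}  # pos0 deleted
    insertions: dict[tuple[int, int], str] = {}  # (pos0 anchor, hap) -> inserted seq
    events: list[dict] = []

    for h in range(n):
        sub_pos = np.flatnonzero(rng.random(L) < mspec.mu)
        for pos in sub_pos:
            ref = anc[pos]
            if ref == "N":
                continue
            if rng.random() < p_ts:
                alt, kind = _TRANSITION[ref], "transition"
            else:
                alt, kind = rng.choice(_TRANSVERSIONS[ref]), "transversion"
            sub_base[(h, int(pos))] = alt
            events.append(
                {"hap": ids[h], "kind": kind, "position": int(pos) + 1,
                 "ref": str(ref), "alt": str(alt)}
            )
        indel_pos = np.flatnonzero(rng.random(L) < mspec.indel_rate)
        for pos in indel_pos:
            length = int(rng.geometric(mspec.indel_length_geometric_p))
            if rng.random() < 0.5:  # deletion
                span = range(int(pos), min(int(pos) + length, L))
                deletions[h].update(span)
                events.append(
                    {"hap": ids[h], "kind": "deletion", "position": int(pos) + 1,
                     "length": len(span)}
                )
            else:  # insertion after pos
                ins = "".join(rng.choice(list("ACGT"), size=length))
                key = (int(pos), h)
                insertions[key] = insertions.get(key, "") + ins
                events.append(
                    {"hap": ids[h], "kind": "insertion", "position": int(pos) + 1,
                     "inserted": ins}
                )

    # column plan: ancestor columns interleaved with insertion columns
    ins_keys = sorted(insertions)  # by (anchor pos, hap)
    columns: list[tuple[str, int, int]] = []  # (type, pos0, hap or -1)
    ki = 0
    for pos in range(L):
        columns.append(("anc", pos, -1))
        while ki < len(ins_keys) and ins_keys[ki][0] == pos:
            columns.append(("ins", pos, ins_keys[ki][1]))
            ki += 1

    width = L + sum(len(v) for v in insertions.values())
    rows = [np.full(width, "-", dtype="U1") for _ in range(n)]
    col_of_pos = np.zeros(L, dtype=int)
    ci = 0
    for ctype, pos, hap in columns:
        if ctype == "anc":
            col_of_pos[pos] = ci
            for h in range(n):
                if pos in deletions[h]:
                    continue
                rows[h][ci] = sub_base.get((h, pos), anc[pos])
            ci += 1
        else:
            ins = insertions[(pos, hap)]
            rows[hap][ci : ci + len(ins)] = list(ins)
            ci += len(ins)

    aln = MultipleAlignment(
        ids=ids, rows=["".join(r) for r in rows], reference_id=ids[0]
    )

    # expected variant calls, from the generator's own bookkeeping
    expected: list[dict] = []
    touched = sorted({pos for (_, pos) in sub_base})
    for pos in touched:
        col = col_of_pos[pos]
        observed = [rows[h][col] for h in range(n) if rows[h][col] != "-"]
        states = set(observed)
        if len(states) < 2:
            continue  # every row mutated identically, or masked by deletions
        if rows[0][col] != "-":
            ref = rows[0][col]
        else:  # reference deleted: the call is typed against the majority state
            ref = max(sorted(states), key=observed.count)
        alts = sorted(states - {ref})
        kinds = {
            "transition" if (ref in "AG") == (a in "AG") else "transversion"
            for a in alts
        }
        expected.append(
            {
                "aln_column": int(col) + 1,
                "kind": "transition" if kinds == {"transition"} else "transversion",
                "ref": str(ref),
                "alts": tuple(alts),
            }
        )
    truth = {
        "events": events,
        "expected_substitution_calls": expected,
        "n_indel_events": sum(1 for e in events if e["kind"] in ("deletion", "insertion")),
        "mu": mspec.mu,
        "kappa": mspec.kappa,
    }
    return aln, truth
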