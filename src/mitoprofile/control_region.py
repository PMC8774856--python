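"""Control-region (D-loop) dissection.

The mammalian control region divides into three domains in fixed order:
an extended termination-associated sequence (ETAS) domain at the 5' end, a
central conserved domain (CD) carrying the F/E/D/C/B boxes, and a conserved
sequence block (CSB) domain at the 3' end with CSB1-3 and the heavy-/light-
strand promoters. Elements are located by minimum-edit-distance search against
a motif library (bundled default: a synthetic stand-in library, see
``data/cr_motifs_synthetic.tsv``); domain boundaries are derived from the
F-box and B-box anchors. Elements that cannot be placed within their edit cap
are reported as missing, never silently placed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import edlib

from .errors import MitoprofileError


@dataclass(frozen=True)
class MotifEntry:
    element: str
    domain: str  # ETAS | CD | CSB
    motif: str
    max_edits: int


@dataclass(frozen=True)
class LocatedElement:
    element: str
    domain: str
    start: int  # genomic 1-based inclusive
    end: int
    edit_distance: int


@dataclass
class ControlRegionAnnotation:
    cr_start: int
    cr_end: int
    domains: dict[str, tuple[int, int]]
    elements: list[LocatedElement]
    missing: list[str] = field(default_factory=list)


def load_motif_library(path: str | Path | None = None) -> list[MotifEntry]:
    """Read a motif library TSV (element, domain, motif, max_edits)."""
    if path is None:
        ref = resources.files("mitoprofile.data").joinpath("cr_motifs_synthetic.tsv")
        with resources.as_file(ref) as p:
            return load_motif_library(p)
    entries = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            element, domain, motif, max_edits = line.split("\t")
            entries.append(MotifEntry(element, domain, motif.upper(), int(max_edits)))
    if not entries:
        raise MitoprofileError("empty motif library")
    return entries


def _locate(cr_seq: str, motif: str, cap: int) -> tuple[int, int, int] | None:
    """Best infix match (0-based start, end inclusive, distance), leftmost tie-break."""
    res = edlib.align(motif, cr_seq, mode="HW", task="locations", k=cap)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
    return start, end, res["editDistance"]


def annotate_control_region(
    cr_seq: str,
    offset: int = 1,
    motif_library: list[MotifEntry] | None = None,
) -> ControlRegionAnnotation:
    """Locate library elements in a control-region sequence and derive domains.

    ``offset`` is the genomic coordinate (1-based) of the first CR base, so
    all reported coordinates are genomic. Domain boundaries: ETAS runs from
    the CR 5' end to just before the F-box; CD spans F-box through B-box; CSB
    runs from just after the B-box to the CR 3' end. If either anchor is
    missing the corresponding boundary falls back to the located elements of
    each domain.
    """
    if len(cr_seq) < 200:
        raise MitoprofileError(
            f"control region of {len(cr_seq)} bp is too short to annotate (< 200 bp)"
        )
    lib = motif_library if motif_library is not None else load_motif_library()
    located: list[LocatedElement] = []
    missing: list[str] = []
    for entry in lib:
        hit = _locate(cr_seq, entry.motif, entry.max_edits)
        if hit is None:
            missing.append(entry.element)
            continue
        s0, e0, dist = hit
        located.append(
            LocatedElement(
                element=entry.element,
                domain=entry.domain,
                start=offset + s0,
                end=offset + e0,
                edit_distance=dist,
            )
        )
    by_name = {e.element: e for e in located}
    cr_start, cr_end = offset, offset + len(cr_seq) - 1

    f_box, b_box = by_name.get("F_box"), by_name.get("B_box")
    if f_box is not None:
        cd_start = f_box.start
    else:
        cd_members = [e for e in located if e.domain == "CD"]
        cd_start = min((e.start for e in cd_members), default=cr_start)
    if b_box is not None:
        cd_end = b_box.end
    else:
        cd_members = [e for e in located if e.domain == "CD"]
        cd_end = max((e.end for e in cd_members), default=cd_start)
    domains = {
        "ETAS": (cr_start, cd_start - 1),
        "CD": (cd_start, cd_end),
        "CSB": (cd_end + 1, cr_end),
    }
    if not (domains["ETAS"][1] < domains["CD"][0] <= domains["CD"][1] < domains["CSB"][0]):
        raise MitoprofileError("derived domains are not in ETAS < CD < CSB order")
    return ControlRegionAnnotation(
        cr_start=cr_start,
        cr_end=cr_end,
        domains=domains,
        elements=sorted(located, key=lambda e: e.start),
        missing=missing,
    )
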