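"""Repeat catalogue construction and repair for ERV/IAP elements.

RepeatMasker annotates one retrotransposon as several "subelement" rows
(LTRs and internal portions) united by an element ID, and frequently
fragments intact elements: it splits elements across 500 kb bin
boundaries, and separates subelements of a single insertion into distinct
element IDs.  This module parses rmsk-style tables, groups rows into
elements, classifies each element's structure (fully-structured, solo
LTR, or one of several fragmented states), patches the 500 kb artefact,
and mends fragmented elements by merging adjacent compatible fragments.

Coordinates are 0-based half-open throughout (UCSC table convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence, TextIO

from .registry import SubelementRegistry

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}


class StructureClass(str, Enum):
    """Structural state of a grouped repeat element.

    FULL
        Internal portion flanked by LTRs at both element-relative ends
        (a fully-structured element).
    SOLO_LTR
        Only LTR subelement(s), no internal portion (the product of
        inter-LTR recombination).
    FRAG_NO5, FRAG_NO3
        Internal portion with an LTR at only the 3' (resp. 5')
        element-relative end.
    FRAG_INTERNAL_ONLY
        Internal portion(s) with no LTR at all.
    FRAG_OTHER
        Any other arrangement (e.g. an LTR sandwiched between internals).
    """

    FULL = "FULL"
    SOLO_LTR = "SOLO_LTR"
    FRAG_NO5 = "FRAG_NO5"
    FRAG_NO3 = "FRAG_NO3"
    FRAG_INTERNAL_ONLY = "FRAG_INTERNAL_ONLY"
    FRAG_OTHER = "FRAG_OTHER"

    @property
    def fragmented(self) -> bool:
        return self not in (StructureClass.FULL, StructureClass.SOLO_LTR)


@dataclass(frozen=True)
class RepeatFeature:
    """One rmsk-style annotation row: an interval with a subelement type."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    rep_name: str
    rep_class_family: str
    element_id: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature start {self.start} >= end {self.end}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.element_id < 0:
            raise ValueError("element_id must be >= 0")

    @property
    def identity(self) -> tuple:
        """Feature identity ignoring element grouping (for conservation checks)."""
        return (self.chrom, self.start, self.end, self.strand, self.rep_name)


@dataclass(frozen=True)
class MendParams:
    """Parameters of the annotation repair.

    max_gap
        Maximum distance (bp) between facing element boundaries for two
        fragments to be considered adjacent; default 2000.
    boundary_interval
        Binning interval (bp) whose boundaries cause erroneous element
        splits in the source annotation; default 500,000.
    max_intra_gap
        Guard rail: features sharing an element ID but separated by more
        than this are split into distinct elements (rmsk reuses IDs).
    """

    max_gap: int = 2000
    boundary_interval: int = 500_000
    max_intra_gap: int = 50_000

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


def _is_internal(rep_name: str, registry: SubelementRegistry | None) -> bool:
    if registry is not None and rep_name in registry:
        return registry.is_internal(rep_name)
    return rep_name.endswith("-int")


@dataclass
class RepeatElement:
    """A grouped, strand-oriented set of features with a structure class."""

    element_id: int
    chrom: str
    strand: str
    features: list[RepeatFeature]
    structure: StructureClass

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("element must have at least one feature")
        self.features = sorted(self.features, key=lambda f: f.start)
        for f in self.features:
            if f.chrom != self.chrom or f.strand != self.strand:
                raise ValueError("features must share chrom and strand")

    @property
    def span_start(self) -> int:
        return self.features[0].start

    @property
    def span_end(self) -> int:
        return max(f.end for f in self.features)

    @property
    def oriented_features(self) -> list[RepeatFeature]:
        """Features in element (5'→3') order: reversed for minus strand."""
        return self.features if self.strand == "+" else self.features[::-1]

    def ltr_feature(self, which: str, registry: SubelementRegistry | None = None
                    ) -> RepeatFeature:
        """The 5' or 3' LTR feature in element orientation.

        ``which`` is ``"5p"`` or ``"3p"``.  For a solo LTR the single LTR
        is the 5' LTR; requesting its 3' LTR is an error.
        """
        of = self.oriented_features
        if which == "5p":
            if self.structure is StructureClass.SOLO_LTR:
                return of[0]
            cand = of[0]
        elif which == "3p":
            cand = of[-1]
            if self.structure is StructureClass.SOLO_LTR:
                raise ValueError("solo LTR has no distinct 3' LTR")
        else:
            raise ValueError(f"which must be '5p' or '3p', got {which!r}")
        if _is_internal(cand.rep_name, registry):
            raise ValueError(
                f"element {self.element_id} has no {which} LTR ({self.structure.value})"
            )
        return cand


def parse_rm_annotation(
    source: str | TextIO,
    registry: SubelementRegistry | None = None,
    iap_only: bool = False,
) -> list[RepeatFeature]:
    """Parse an rmsk-style annotation table into features.

    Accepts either the simple seven-column layout
    ``chrom start end strand rep_name rep_class_family id`` or the UCSC
    table-browser export with named columns (genoName, genoStart,
    genoEnd, strand, repName, repClass, repFamily, id); a header row is
    auto-detected.  Coordinates are 0-based half-open.

    With ``iap_only`` set, rows whose rep_name is not in ``registry``
    are dropped.  Output is sorted by (chrom, start).
    """
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    if iap_only and registry is None:
        registry = SubelementRegistry.default()
    features: list[RepeatFeature] = []
    try:
        colmap = None  # name -> index, for the UCSC header dialect
        for lineno, line in enumerate(source, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.lstrip("#").split()
            if colmap is None and not features and "genoStart" in fields:
                colmap = {name: i for i, name in enumerate(fields)}
                continue
            if stripped.startswith("#"):
                continue
            try:
                if colmap is not None:
                    chrom = fields[colmap["genoName"]]
                    start = int(fields[colmap["genoStart"]])
                    end = int(fields[colmap["genoEnd"]])
                    strand = fields[colmap["strand"]]
                    rep_name = fields[colmap["repName"]]
                    rep_cf = fields[colmap["repClass"]]
                    if "repFamily" in colmap:
                        rep_cf += "/" + fields[colmap["repFamily"]]
                    element_id = int(fields[colmap["id"]])
                else:
                    if len(fields) < 7:
                        raise ValueError(f"expected >= 7 columns, got {len(fields)}")
                    chrom, start, end, strand, rep_name, rep_cf, element_id = (
                        fields[0], int(fields[1]), int(fields[2]), fields[3],
                        fields[4], fields[5], int(fields[6]),
                    )
            except (ValueError, KeyError, IndexError) as exc:
                raise ValueError(f"malformed annotation row at line {lineno}: {exc}") from exc
            if strand not in VALID_STRANDS:
                raise ValueError(f"unknown strand {strand!r} at line {lineno}")
            if iap_only and rep_name not in registry:  # type: ignore[operator]
                continue
            features.append(RepeatFeature(chrom, start, end, strand, rep_name,
                                          rep_cf, element_id))
    finally:
        if close:
            source.close()
    features.sort(key=lambda f: (f.chrom, f.start))
    return features


def classify_structure(
    features_or_element: RepeatElement | Sequence[RepeatFeature],
    registry: SubelementRegistry | None = None,
) -> StructureClass:
    """Classify an element's structure from its typed subelements.

    Flanking is element-relative: the 5' end of a minus-strand element is
    its genomic right end.
    """
    if isinstance(features_or_element, RepeatElement):
        oriented = features_or_element.oriented_features
    else:
        feats = sorted(features_or_element, key=lambda f: f.start)
        if feats and feats[0].strand == "-":
            feats = feats[::-1]
        oriented = feats
    if not oriented:
        raise ValueError("cannot classify an element with zero features")
    internal_mask = [_is_internal(f.rep_name, registry) for f in oriented]
    has_internal = any(internal_mask)
    has_ltr = not all(internal_mask)
    if not has_internal:
        return StructureClass.SOLO_LTR
    if not has_ltr:
        return StructureClass.FRAG_INTERNAL_ONLY
    ltr_5p = not internal_mask[0]
    ltr_3p = not internal_mask[-1]
    if ltr_5p and ltr_3p:
        return StructureClass.FULL
    if ltr_3p:
        return StructureClass.FRAG_NO5
    if ltr_5p:
        return StructureClass.FRAG_NO3
    return StructureClass.FRAG_OTHER


def _make_element(element_id: int, features: list[RepeatFeature],
                  registry: SubelementRegistry | None) -> RepeatElement:
    feats = sorted(features, key=lambda f: f.start)
    el = RepeatElement(
        element_id=element_id,
        chrom=feats[0].chrom,
        strand=feats[0].strand,
        features=[replace(f, element_id=element_id) for f in feats],
        structure=StructureClass.FULL,  # placeholder, fixed below
    )
    el.structure = classify_structure(el, registry)
    return el


def group_into_elements(
    features: Iterable[RepeatFeature],
    registry: SubelementRegistry | None = None,
    params: MendParams | None = None,
) -> list[RepeatElement]:
    """Group annotation rows into elements by (chrom, strand, element ID).

    rmsk reuses IDs across loci, so a shared ID is additionally split on
    chrom/strand changes (with a warning) and on intra-ID gaps larger
    than ``params.max_intra_gap``.  Split-off groups receive fresh IDs.
    """
    params = params or MendParams()
    by_id: dict[int, list[RepeatFeature]] = {}
    for f in features:
        by_id.setdefault(f.element_id, []).append(f)
    if not by_id:
        return []
    next_id = max(by_id) + 1
    elements: list[RepeatElement] = []
    for element_id in sorted(by_id):
        rows = sorted(by_id[element_id], key=lambda f: (f.chrom, f.strand, f.start))
        groups: list[list[RepeatFeature]] = [[rows[0]]]
        for prev, cur in zip(rows, rows[1:]):
            same_locus = (cur.chrom == prev.chrom and cur.strand == prev.strand
                          and cur.start - prev.end <= params.max_intra_gap)
            if same_locus:
                groups[-1].append(cur)
            else:
                groups.append([cur])
        if len(groups) > 1 and len({(r.chrom, r.strand) for r in rows}) > 1:
            logger.warning(
                "element ID %d spans multiple loci (%d groups); splitting",
                element_id, len(groups),
            )
        for i, grp in enumerate(groups):
            gid = element_id if i == 0 else next_id
            if i > 0:
                next_id += 1
            elements.append(_make_element(gid, grp, registry))
    elements.sort(key=lambda e: (e.chrom, e.span_start))
    return elements


def patch_500kb_splits(
    elements: Sequence[RepeatElement],
    params: MendParams | None = None,
    registry: SubelementRegistry | None = None,
) -> list[RepeatElement]:
    """Unify element pairs erroneously split at binning-interval boundaries.

    Two same-chrom, same-strand elements, one ending exactly at a
    multiple of ``boundary_interval`` and the other starting at that same
    coordinate, are re-united under one element ID.  The match is exact
    (no slack): the artefact is a binning artefact.
    """
    params = params or MendParams()
    interval = params.boundary_interval
    pool = list(elements)
    pool.sort(key=lambda e: (e.chrom, e.strand, e.span_start))
    out: list[RepeatElement] = []
    i = 0
    while i < len(pool):
        cur = pool[i]
        j = i + 1
        # chains across successive boundaries collapse into one element
        while (
            j < len(pool)
            and pool[j].chrom == cur.chrom
            and pool[j].strand == cur.strand
            and cur.span_end % interval == 0
            and pool[j].span_start == cur.span_end
        ):
            cur = _make_element(min(cur.element_id, pool[j].element_id),
                                cur.features + pool[j].features, registry)
            j += 1
        out.append(cur)
        i = j
    out.sort(key=lambda e: (e.chrom, e.span_start))
    return out


# Heuristic partner ranks for mending: a fragment missing its 5' LTR looks
# 5'-ward for, in order, (1) a fragment missing a 3' LTR, (2) a solo LTR,
# (3) a fully-structured element.  Internal-only fragments are missing
# both LTRs, so they qualify for rank 1 on either side.
_RANK1_FOR_5P_MEND = {StructureClass.FRAG_NO3, StructureClass.FRAG_INTERNAL_ONLY}
_RANK1_FOR_3P_MEND = {StructureClass.FRAG_NO5, StructureClass.FRAG_INTERNAL_ONLY}


def _oriented_bounds(el: RepeatElement) -> tuple[int, int]:
    """(start, end) on an axis increasing 5'→3' in element orientation."""
    if el.strand == "+":
        return el.span_start, el.span_end
    return -el.span_end, -el.span_start


def _partner_rank(structure: StructureClass, side: str) -> int | None:
    rank1 = _RANK1_FOR_5P_MEND if side == "5p" else _RANK1_FOR_3P_MEND
    if structure in rank1:
        return 1
    if structure is StructureClass.SOLO_LTR:
        return 2
    if structure is StructureClass.FULL:
        return 3
    return None


def _find_partner(
    el: RepeatElement,
    side: str,
    pool: Sequence[RepeatElement],
    blocked: set[int],
    max_gap: int,
) -> RepeatElement | None:
    """Best mend partner for ``el`` on its 5' or 3' side, or None.

    Candidates are ranked by heuristic class, then nearest facing
    boundary (overlapping envelopes count as adjacent), then 5'-most.
    """
    o_start, o_end = _oriented_bounds(el)
    best_key = None
    best = None
    for idx, p in enumerate(pool):
        if p is el or id(p) in blocked:
            continue
        if p.chrom != el.chrom or p.strand != el.strand:
            continue
        rank = _partner_rank(p.structure, side)
        if rank is None:
            continue
        p_start, p_end = _oriented_bounds(p)
        if side == "5p":
            if p_start > o_start:  # must lie 5' of el
                continue
            gap = o_start - p_end
        else:
            if p_end < o_end:  # must lie 3' of el
                continue
            gap = p_start - o_end
        if gap > max_gap:
            continue
        key = (rank, max(gap, 0), abs(gap), p_start)
        if best_key is None or key < best_key:
            best_key, best = key, p
    return best


def _mendable_sides(structure: StructureClass) -> tuple[str, ...]:
    if structure is StructureClass.FRAG_NO5:
        return ("5p",)
    if structure is StructureClass.FRAG_NO3:
        return ("3p",)
    if structure is StructureClass.FRAG_INTERNAL_ONLY:
        return ("5p", "3p")
    return ()


def mend_fragmented(
    elements: Sequence[RepeatElement],
    params: MendParams | None = None,
    registry: SubelementRegistry | None = None,
) -> list[RepeatElement]:
    """Merge artificially fragmented elements into structured ones.

    Fragmented elements are processed in genomic order; each tries to
    mend its missing 5' LTR, then its missing 3' LTR, against partners
    within ``max_gap`` of the relevant edge, preferring (1) a fragment
    missing the complementary LTR, (2) a solo LTR, (3) a fully-structured
    element (which yields a double or higher-order element).  Each
    element takes part in at most one merge per pass; passes repeat
    until a fixpoint.  Merging never crosses a chromosome or strand, and
    unmendable elements pass through unchanged.
    """
    params = params or MendParams()
    pool = list(elements)
    while True:
        pool.sort(key=lambda e: (e.chrom, e.span_start))
        consumed: set[int] = set()
        merges: list[tuple[RepeatElement, RepeatElement]] = []
        for el in pool:
            if id(el) in consumed:
                continue
            for side in _mendable_sides(el.structure):
                partner = _find_partner(el, side, pool, consumed, params.max_gap)
                if partner is not None:
                    merges.append((el, partner))
                    consumed.add(id(el))
                    consumed.add(id(partner))
                    break
        if not merges:
            return pool
        survivors = [e for e in pool if id(e) not in consumed]
        for a, b in merges:
            five_most = a if _oriented_bounds(a)[0] <= _oriented_bounds(b)[0] else b
            survivors.append(
                _make_element(five_most.element_id, a.features + b.features, registry)
            )
        pool = survivors


@dataclass(frozen=True)
class CatalogueSummary:
    """Structure-class counts over a catalogue."""

    n_elements: int
    n_full: int
    n_solo_ltr: int
    n_fragmented: int

    @property
    def fragmented_fraction(self) -> float:
        return self.n_fragmented / self.n_elements if self.n_elements else 0.0

    def to_dict(self) -> dict:
        return {
            "n_elements": self.n_elements,
            "n_full": self.n_full,
            "n_solo_ltr": self.n_solo_ltr,
            "n_fragmented": self.n_fragmented,
            "fragmented_fraction": self.fragmented_fraction,
        }


def summarize_catalogue(elements: Sequence[RepeatElement]) -> CatalogueSummary:
    n_full = sum(e.structure is StructureClass.FULL for e in elements)
    n_solo = sum(e.structure is StructureClass.SOLO_LTR for e in elements)
    n = len(elements)
    return CatalogueSummary(n, n_full, n_solo, n - n_full - n_solo)


def cpg_density(sequence: str) -> float:
    """CpG dinucleotides per bp: non-overlapping ``CG`` count / length."""
    if not sequence:
        raise ValueError("cannot compute CpG density of an empty sequence")
    return sequence.upper().count("CG") / len(sequence)


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice a chromosome from a pyfaidx.Fasta or a plain mapping of strings."""
    try:
        seq = genome[chrom][start:end]
    except KeyError as exc:
        raise KeyError(f"chromosome {chrom!r} absent from genome") from exc
    return str(getattr(seq, "seq", seq)).upper()


def extract_ltr_sequence(
    element: RepeatElement,
    which_ltr: str,
    genome,
    registry: SubelementRegistry | None = None,
) -> str:
    """The element's 5' or 3' LTR sequence, in element orientation.

    Minus-strand LTRs are reverse-complemented so the returned sequence
    reads 5'→3' in element orientation.
    """
    from Bio.Seq import reverse_complement

    ltr = element.ltr_feature(which_ltr, registry)
    seq = _fetch(genome, ltr.chrom, ltr.start, ltr.end)
    return reverse_complement(seq) if element.strand == "-" else seq


# ---------------------------------------------------------------- I/O

CATALOGUE_COLUMNS = ("element_id", "chrom", "start", "end", "strand",
                     "structure", "subelements")


def write_catalogue_tsv(elements: Sequence[RepeatElement], path: str) -> None:
    """One row per element: envelope, structure, comma-joined subelement names."""
    with open(path, "w") as fh:
        fh.write("\t".join(CATALOGUE_COLUMNS) + "\n")
        for el in sorted(elements, key=lambda e: (e.chrom, e.span_start)):
            names = ",".join(f.rep_name for f in el.features)
            fh.write(f"{el.element_id}\t{el.chrom}\t{el.span_start}\t{el.span_end}"
                     f"\t{el.strand}\t{el.structure.value}\t{names}\n")


def read_catalogue_tsv(path: str) -> "pandas.DataFrame":  # noqa: F821
    import pandas

    return pandas.read_csv(path, sep="\t", dtype={"chrom": str})


def write_annotation_tsv(elements: Sequence[RepeatElement], path: str) -> None:
    """rmsk-style feature table (simple seven-column layout), mended IDs."""
    feats = sorted((f for el in elements for f in el.features),
                   key=lambda f: (f.chrom, f.start))
    with open(path, "w") as fh:
        for f in feats:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.strand}\t{f.rep_name}"
                     f"\t{f.rep_class_family}\t{f.element_id}\n")


def write_bed6(elements: Sequence[RepeatElement], path: str) -> None:
    """Element envelopes as BED6 (name = element_id, score = feature count)."""
    with open(path, "w") as fh:
        for el in sorted(elements, key=lambda e: (e.chrom, e.span_start)):
            fh.write(f"{el.chrom}\t{el.span_start}\t{el.span_end}"
                     f"\t{el.element_id}\t{len(el.features)}\t{el.strand}\n")
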