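"""Inter-individual methylation-variability screen at element edges.

For every outward-facing LTR edge of every catalogued element, the mean
methylation of the CpGs nearest the edge is computed per WGBS sample
from raw methylated/unmethylated call counts.  Samples with too few
calls or covered CpGs at an edge are uninformative; edges without enough
informative samples in every cell-type group are excluded; the surviving
edges are ranked by their inter-individual methylation range (max − min,
no trimming of extremes) per group.  An edge whose screen statistic
reaches the range threshold marks its element as a variably methylated
candidate.

Coverage input is the six-column per-CpG dialect
``chrom  start  end  %methylation  count_methylated  count_unmethylated``.
Counts are primary; the percentage column is ignored.  Records on the
two strands of one CpG dyad are merged onto the plus-strand C.
"""

from __future__ import annotations

import bisect
import gzip
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .catalogue import RepeatElement, RepeatFeature, StructureClass

logger = logging.getLogger(__name__)


class Edge(str, Enum):
    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"


@dataclass(frozen=True)
class CpGCall:
    """Pooled methylation calls at one CpG dyad (plus-strand C position)."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    @property
    def total(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def fraction(self) -> float | None:
        return self.n_meth / self.total if self.total else None


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group: str

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be nonempty")


@dataclass(frozen=True)
class ScreenParams:
    """Filters and thresholds of the variability screen.

    n_edge_cpgs
        CpGs taken from inside the element nearest each outward edge.
    min_calls / min_covered_cpgs
        A sample is informative at an edge only with at least this many
        total methylation calls over the window, and at least this many
        CpGs with any coverage.
    min_informative_samples
        Edges with fewer informative samples in any group are excluded.
    range_threshold
        Minimum inter-individual methylation range for candidacy.
    edge_max_dist
        Optional cap (bp) on CpG distance from the edge; used by the
        LINE/SINE/non-ERV screen variant (200 bp), unset for IAPs.
    statistic
        How per-group ranges combine into one screen statistic:
        ``"min"`` (variability required in every group; default) or
        ``"max"``.
    mean_mode
        ``"pooled"``: Σmeth/Σtotal over the window (default);
        ``"per_cpg"``: unweighted mean of per-CpG fractions.
    """

    n_edge_cpgs: int = 8
    min_calls: int = 20
    min_covered_cpgs: int = 4
    min_informative_samples: int = 5
    range_threshold: float = 0.10
    edge_max_dist: int | None = None
    statistic: str = "min"
    mean_mode: str = "pooled"

    def __post_init__(self) -> None:
        if min(self.n_edge_cpgs, self.min_calls, self.min_covered_cpgs,
               self.min_informative_samples) <= 0:
            raise ValueError("screen filter parameters must be positive")
        if not 0 < self.range_threshold < 1:
            raise ValueError("range_threshold must be in (0,1)")
        if self.statistic not in ("min", "max"):
            raise ValueError("statistic must be 'min' or 'max'")
        if self.mean_mode not in ("pooled", "per_cpg"):
            raise ValueError("mean_mode must be 'pooled' or 'per_cpg'")


def load_coverage(source: str | TextIO) -> dict[str, dict[int, CpGCall]]:
    """Load one sample's per-CpG coverage file.

    Returns ``{chrom: {pos: CpGCall}}``.  Records at consecutive
    positions p and p+1 are the two strands of one CpG dyad (CpGs are at
    least 2 bp apart) and are merged by summing counts onto p.
    Percentage values inconsistent with the counts (beyond rounding)
    draw a warning; negative counts are an error.
    """
    close = False
    if isinstance(source, str):
        source = gzip.open(source, "rt") if source.endswith(".gz") else open(source)
        close = True
    per_chrom: dict[str, dict[int, list[int]]] = {}
    try:
        for lineno, line in enumerate(source, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise ValueError(f"coverage line {lineno}: expected 6 columns")
            chrom, start = fields[0], int(fields[1])
            pct, n_meth, n_unmeth = float(fields[3]), int(fields[4]), int(fields[5])
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"coverage line {lineno}: negative count")
            total = n_meth + n_unmeth
            if total and abs(pct - 100.0 * n_meth / total) > 1.0:
                logger.warning("coverage line %d: %% column (%.1f) inconsistent "
                               "with counts (%d/%d)", lineno, pct, n_meth, total)
            calls = per_chrom.setdefault(chrom, {})
            bucket = calls.setdefault(start, [0, 0])
            bucket[0] += n_meth
            bucket[1] += n_unmeth
    finally:
        if close:
            source.close()
    out: dict[str, dict[int, CpGCall]] = {}
    for chrom, calls in per_chrom.items():
        merged: dict[int, CpGCall] = {}
        for pos in sorted(calls):
            m, u = calls[pos]
            if pos - 1 in merged:  # minus-strand C of the dyad at pos-1
                prev = merged[pos - 1]
                merged[pos - 1] = CpGCall(chrom, pos - 1,
                                          prev.n_meth + m, prev.n_unmeth + u)
            else:
                merged[pos] = CpGCall(chrom, pos, m, u)
        out[chrom] = merged
    return out


@dataclass(frozen=True)
class EdgeWindow:
    """The CpG positions screened at one element edge."""

    element_id: int
    chrom: str
    edge: Edge
    cpg_positions: tuple[int, ...]  # sorted genomic positions


def _outward_edges(element: RepeatElement) -> list[Edge]:
    """Outward-facing LTR edges, in element orientation.

    Fully-structured elements contribute both edges (their internal-facing
    LTR edges are never windowed); a solo LTR contributes a single window
    at its 5' edge; fragments contribute the edges where an LTR exists.
    """
    s = element.structure
    if s is StructureClass.FULL:
        return [Edge.FIVE_PRIME, Edge.THREE_PRIME]
    if s is StructureClass.SOLO_LTR:
        return [Edge.FIVE_PRIME]
    if s is StructureClass.FRAG_NO5:
        return [Edge.THREE_PRIME]
    if s is StructureClass.FRAG_NO3:
        return [Edge.FIVE_PRIME]
    return []


def build_edge_windows(
    element: RepeatElement,
    cpg_positions: Sequence[int],
    params: ScreenParams | None = None,
) -> list[EdgeWindow]:
    """Windows of the ``n_edge_cpgs`` CpGs inside the element nearest
    each outward-facing edge.

    ``cpg_positions`` are the sorted plus-strand CpG positions on the
    element's chromosome.  When ``edge_max_dist`` is set, only CpGs
    within that distance of the edge qualify.  Elements with fewer CpGs
    yield shorter (possibly empty) windows.
    """
    params = params or ScreenParams()
    lo = bisect.bisect_left(cpg_positions, element.span_start)
    hi = bisect.bisect_left(cpg_positions, element.span_end)
    inside = list(cpg_positions[lo:hi])
    windows = []
    for edge in _outward_edges(element):
        # genomic side of the edge: 5' edge is the left end on + strand
        left = (edge is Edge.FIVE_PRIME) == (element.strand == "+")
        if left:
            cands = [p for p in inside
                     if params.edge_max_dist is None
                     or p - element.span_start < params.edge_max_dist]
            sel = cands[: params.n_edge_cpgs]
        else:
            cands = [p for p in inside
                     if params.edge_max_dist is None
                     or element.span_end - 1 - p < params.edge_max_dist]
            sel = cands[-params.n_edge_cpgs:] if cands else []
        if not sel:
            logger.debug("element %d %s edge: no CpGs", element.element_id, edge.value)
        windows.append(EdgeWindow(element.element_id, element.chrom, edge, tuple(sel)))
    return windows


@dataclass(frozen=True)
class SampleEdgeMethylation:
    """One sample's summarised methylation over an edge window."""

    sample_id: str
    group: str
    mean_meth: float | None
    total_calls: int
    covered_cpgs: int
    informative: bool


def sample_edge_methylation(
    window: EdgeWindow,
    calls: Mapping[str, Mapping[int, CpGCall]],
    meta: SampleMeta,
    params: ScreenParams | None = None,
) -> SampleEdgeMethylation:
    """Summarise one sample at one edge window.

    The default mean is the pooled-count mean Σmeth/Σtotal over the
    window's covered CpGs.  Informative requires ≥ ``min_calls`` total
    calls and ≥ ``min_covered_cpgs`` covered CpGs.  An empty window, or
    an edge absent from the sample's coverage, yields an uninformative
    record rather than an error.
    """
    params = params or ScreenParams()
    chrom_calls = calls.get(window.chrom, {})
    meth = unmeth = covered = 0
    fracs = []
    for pos in window.cpg_positions:
        call = chrom_calls.get(pos)
        if call is None or call.total == 0:
            continue
        covered += 1
        meth += call.n_meth
        unmeth += call.n_unmeth
        fracs.append(call.n_meth / call.total)
    total = meth + unmeth
    if total == 0:
        mean = None
    elif params.mean_mode == "pooled":
        mean = meth / total
    else:
        mean = float(np.mean(fracs))
    informative = total >= params.min_calls and covered >= params.min_covered_cpgs
    return SampleEdgeMethylation(meta.sample_id, meta.group, mean, total,
                                 covered, informative)


@dataclass
class EdgeRangeResult:
    """Per-cell-type methylation ranges at one element edge."""

    element_id: int
    chrom: str
    edge: Edge
    group_n_informative: dict[str, int]
    group_range: dict[str, float | None]
    passed_sample_filter: bool
    screen_statistic: float | None
    candidate: bool


def edge_range(
    window: EdgeWindow,
    summaries: Sequence[SampleEdgeMethylation],
    params: ScreenParams | None = None,
) -> EdgeRangeResult:
    """Inter-individual methylation range per group at one edge.

    Ranges are max − min over informative samples only, with no trimming
    of extremes.  The edge passes the sample filter only when every
    group has at least ``min_informative_samples`` informative samples;
    the screen statistic is the min (or max) of the group ranges, and
    the edge is a candidate when it passes the filter and the statistic
    reaches ``range_threshold``.
    """
    params = params or ScreenParams()
    groups: dict[str, list[float]] = {}
    for s in summaries:
        groups.setdefault(s.group, [])
        if s.informative and s.mean_meth is not None:
            groups[s.group].append(s.mean_meth)
    n_inf = {g: len(v) for g, v in groups.items()}
    rng = {g: (max(v) - min(v) if v else None) for g, v in groups.items()}
    passed = bool(groups) and all(
        n >= params.min_informative_samples for n in n_inf.values()
    )
    if passed:
        vals = [r for r in rng.values() if r is not None]
        stat = min(vals) if params.statistic == "min" else max(vals)
    else:
        stat = None
    candidate = passed and stat is not None and stat >= params.range_threshold
    return EdgeRangeResult(window.element_id, window.chrom, window.edge,
                           n_inf, rng, passed, stat, candidate)


def screen_catalogue(
    elements: Sequence[RepeatElement],
    coverages: Mapping[str, Mapping[str, Mapping[int, CpGCall]]],
    sample_metas: Sequence[SampleMeta],
    params: ScreenParams | None = None,
    cpg_positions: Mapping[str, Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Run the edge-methylation variability screen over a catalogue.

    ``coverages`` maps sample_id → per-chromosome CpG calls.  CpG
    positions default to the union of dyad positions observed across
    samples; pass ``cpg_positions`` (e.g. from the genome sequence) to
    decouple windows from coverage.

    Returns one row per surviving outward edge with all intermediate
    filter outcomes, ranked by screen statistic descending.  An element
    is a candidate when any of its edges is.
    """
    params = params or ScreenParams()
    if not sample_metas:
        raise ValueError("no samples provided")
    if cpg_positions is None:
        union: dict[str, set[int]] = {}
        for cov in coverages.values():
            for chrom, calls in cov.items():
                union.setdefault(chrom, set()).update(calls)
        cpg_positions = {c: sorted(p) for c, p in union.items()}
    missing = {e.chrom for e in elements} - set(cpg_positions)
    if missing:
        logger.warning("no CpG coverage on chromosome(s): %s",
                       ", ".join(sorted(missing)))
    rows = []
    for el in sorted(elements, key=lambda e: (e.chrom, e.span_start)):
        pos = cpg_positions.get(el.chrom, ())
        for window in build_edge_windows(el, pos, params):
            summaries = [
                sample_edge_methylation(window, coverages[m.sample_id], m, params)
                for m in sample_metas
            ]
            res = edge_range(window, summaries, params)
            row = {
                "element_id": res.element_id,
                "chrom": el.chrom,
                "start": el.span_start,
                "end": el.span_end,
                "strand": el.strand,
                "structure": el.structure.value,
                "edge": res.edge.value,
                "n_window_cpgs": len(window.cpg_positions),
                "passed_sample_filter": res.passed_sample_filter,
                "screen_statistic": res.screen_statistic,
                "candidate": res.candidate,
            }
            for g in sorted({m.group for m in sample_metas}):
                row[f"n_informative_{g}"] = res.group_n_informative.get(g, 0)
                row[f"range_{g}"] = res.group_range.get(g)
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["screen_statistic", "element_id", "edge"],
            ascending=[False, True, True],
            na_position="last",
        ).reset_index(drop=True)
        cand_elements = set(df.loc[df["candidate"], "element_id"])
        df["element_candidate"] = df["element_id"].isin(cand_elements)
    return df


def candidate_elements(screen_table: pd.DataFrame) -> list[int]:
    """Element IDs with at least one candidate edge, best edge first."""
    if screen_table.empty:
        return []
    cand = screen_table[screen_table["candidate"]]
    return list(dict.fromkeys(cand["element_id"]))


def prepare_non_iap_elements(
    features: Iterable[RepeatFeature],
    merge_dist: int = 100,
) -> list[RepeatElement]:
    """Combine adjacent same-class, same-strand repeat fragments.

    The LINE/SINE/non-ERV screen variant does not mend structure; it
    only joins fragments of the same repeat class within ``merge_dist``
    bp on the same strand into single elements.  Edge windows for these
    elements should use ``edge_max_dist=200`` (the first ``n_edge_cpgs``
    CpGs within 200 bp of each edge).
    """
    from .catalogue import _make_element

    feats = sorted(features, key=lambda f: (f.chrom, f.strand,
                                            f.rep_class_family, f.start))
    elements: list[RepeatElement] = []
    group: list[RepeatFeature] = []
    next_id = 0

    def flush() -> None:
        nonlocal next_id
        if group:
            el = _make_element(next_id, list(group), None)
            # no LTR structure here; FULL marks both edges outward-facing
            el.structure = StructureClass.FULL
            elements.append(el)
            next_id += 1

    for f in feats:
        if group and (
            f.chrom != group[-1].chrom
            or f.strand != group[-1].strand
            or f.rep_class_family != group[-1].rep_class_family
            or f.start - max(g.end for g in group) > merge_dist
        ):
            flush()
            group = []
        group.append(f)
    flush()
    elements.sort(key=lambda e: (e.chrom, e.span_start))
    return elements


def read_sample_sheet(path: str) -> list[tuple[SampleMeta, str]]:
    """Sample sheet TSV with columns sample_id, group, path."""
    df = pd.read_csv(path, sep="\t")
    return [(SampleMeta(str(r.sample_id), str(r.group)), str(r.path))
            for r in df.itertuples()]
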