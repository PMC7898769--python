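"""k-mer enrichment and motif assembly over LTR sequence sets.

The procedure finds sequences over-represented in a foreground set of
LTRs (e.g. the 5' LTRs of constitutively variably methylated elements)
relative to a background set (all other element 5' LTRs):

1. every k-mer (default k = 15) present in at least two foreground
   sequences is collected (presence counting: once per sequence);
2. fold enrichment = foreground presence fraction / background presence
   fraction (zero background gets a pseudocount);
3. k-mers passing the presence (≥ 5 sequences) and fold (≥ 20×) filters
   are grouped into connected components under the k−1 suffix/prefix
   overlap relation and merged into extended sequences;
4. each extended sequence is trimmed to the substring maximising fold
   enrichment.

Counting is strand-specific: sequences are taken 5'→3' in element
orientation and no reverse-complement canonicalisation is applied
(LTR regulatory sequences are orientation-specific); pass
``canonical=True`` to count both strands as one k-mer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class KmerParams:
    """Thresholds of the enrichment procedure (defaults per the screen).

    min_initial_presence
        k-mers in fewer foreground sequences than this are never counted.
    min_filter_presence / min_fold
        The enrichment filter: keep k-mers in ≥ this many foreground
        sequences with ≥ this fold enrichment.
    max_bg_fraction
        Final motifs present in more than this fraction of all LTRs
        fail the background cap (default 2%).
    pseudocount
        Added to a zero background presence so folds stay finite.
    trim_min_len
        Shortest substring considered when trimming (avoids trivially
        short, promiscuous substrings).
    """

    k: int = 15
    min_initial_presence: int = 2
    min_filter_presence: int = 5
    min_fold: float = 20.0
    max_bg_fraction: float = 0.02
    pseudocount: float = 0.5
    trim_min_len: int = 10
    canonical: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if min(self.min_initial_presence, self.min_filter_presence,
               self.min_fold, self.pseudocount, self.trim_min_len) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class KmerRecord:
    seq: str
    fg_presence: int
    bg_presence: int = 0
    fold: float = 0.0


def sequence_kmers(seq: str, k: int, canonical: bool = False) -> set[str]:
    """The set of k-mers present in one sequence; k-mers containing a
    non-ACGT symbol are skipped."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if any(c not in "ACGT" for c in km):
            continue
        if canonical:
            km = min(km, _revcomp(km))
        out.add(km)
    return out


def kmer_presence_counts(
    sequences: Iterable[str], k: int, canonical: bool = False
) -> Counter:
    """Presence count per k-mer: the number of sequences containing it
    at least once (multiplicity within a sequence does not count)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    counts: Counter = Counter()
    for seq in sequences:
        counts.update(sequence_kmers(seq, k, canonical))
    return counts


def compute_fold(fg_presence: int, bg_presence: int, n_fg: int, n_bg: int,
                 pseudocount: float = 0.5) -> float:
    """Fold enrichment of foreground vs background presence fractions.

    A zero background presence is replaced by ``pseudocount`` so the
    fold stays finite; a zero foreground presence gives fold 0.
    """
    if n_fg <= 0 or n_bg <= 0:
        raise ValueError("set sizes must be positive")
    if fg_presence == 0:
        return 0.0
    bg = bg_presence if bg_presence > 0 else pseudocount
    return (fg_presence / n_fg) / (bg / n_bg)


def enrich_kmers(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    params: KmerParams | None = None,
) -> list[KmerRecord]:
    """Foreground k-mers with presence counts and fold enrichment.

    Only k-mers present in at least ``min_initial_presence`` foreground
    sequences are returned (the initial enumeration step).
    """
    params = params or KmerParams()
    fg_counts = kmer_presence_counts(fg_seqs, params.k, params.canonical)
    kept = {km for km, c in fg_counts.items() if c >= params.min_initial_presence}
    bg_counts: Counter = Counter()
    bg_sets = [sequence_kmers(s, params.k, params.canonical) for s in bg_seqs]
    for s in bg_sets:
        bg_counts.update(s & kept)
    records = []
    for km in sorted(kept):
        rec = KmerRecord(km, fg_counts[km], bg_counts[km])
        rec.fold = compute_fold(rec.fg_presence, rec.bg_presence,
                                len(fg_seqs), len(bg_seqs), params.pseudocount)
        records.append(rec)
    return records


def filter_kmers(records: Iterable[KmerRecord],
                 params: KmerParams | None = None) -> list[KmerRecord]:
    """Keep k-mers with fg presence ≥ min_filter_presence and fold ≥ min_fold."""
    params = params or KmerParams()
    return [r for r in records
            if r.fg_presence >= params.min_filter_presence and r.fold >= params.min_fold]


def overlap_graph(records: Sequence[KmerRecord], k: int) -> nx.Graph:
    """Undirected graph with an edge where one k-mer's (k−1)-suffix equals
    the other's (k−1)-prefix (either direction)."""
    g = nx.Graph()
    by_prefix: dict[str, list[str]] = {}
    for r in records:
        g.add_node(r.seq, record=r)
        by_prefix.setdefault(r.seq[: k - 1], []).append(r.seq)
    for r in records:
        for other in by_prefix.get(r.seq[1:], ()):
            if other != r.seq:
                g.add_edge(r.seq, other)
    return g


def group_by_overlap(records: Sequence[KmerRecord],
                     k: int) -> list[list[KmerRecord]]:
    """Connected components of the k−1 overlap graph (singletons allowed),
    ordered by total fg presence descending then lexicographically."""
    g = overlap_graph(records, k)
    comps = []
    for comp in nx.connected_components(g):
        members = sorted((g.nodes[s]["record"] for s in comp), key=lambda r: r.seq)
        comps.append(members)
    comps.sort(key=lambda ms: (-sum(r.fg_presence for r in ms), ms[0].seq))
    return comps


def _greedy_best_path(dg: nx.DiGraph, weight: dict[str, int]) -> list[str]:
    """Best simple path: from every start node, greedily extend forward to
    the unvisited successor with the highest weight; the path with the
    largest summed weight wins (ties: more nodes, then lexicographic)."""
    best: list[str] = []
    best_key = None
    for start in sorted(dg.nodes):
        path = [start]
        seen = {start}
        while True:
            nxt = [v for v in dg.successors(path[-1]) if v not in seen]
            if not nxt:
                break
            nv = max(nxt, key=lambda v: (weight[v], v))
            path.append(nv)
            seen.add(nv)
        key = (sum(weight[v] for v in path), len(path), [v for v in path])
        if best_key is None or (key[0], key[1]) > (best_key[0], best_key[1]) or (
            (key[0], key[1]) == (best_key[0], best_key[1]) and key[2] < best_key[2]
        ):
            best, best_key = path, key
    return best


def merge_component(component: Sequence[KmerRecord], k: int
                    ) -> list[tuple[str, list[KmerRecord]]]:
    """Merge a k−1-overlap component into extended sequence(s).

    k-mers are laid out along a maximal simple path of the directed
    overlap graph (edge u→v when u's suffix equals v's prefix), chosen
    greedily to maximise total foreground presence.  On branching
    graphs, members not on the chosen path are merged recursively, so a
    component may yield several (extended_seq, members) pairs.  Every
    member k-mer is a substring of its extended sequence.
    """
    if len(component) == 1:
        return [(component[0].seq, list(component))]
    dg = nx.DiGraph()
    by_seq = {r.seq: r for r in component}
    for r in component:
        dg.add_node(r.seq)
    prefixes: dict[str, list[str]] = {}
    for s in by_seq:
        prefixes.setdefault(s[: k - 1], []).append(s)
    for s in by_seq:
        for t in prefixes.get(s[1:], ()):
            if t != s:
                dg.add_edge(s, t)
    weight = {s: by_seq[s].fg_presence for s in by_seq}
    path = _greedy_best_path(dg, weight)
    extended = path[0] + "".join(s[-1] for s in path[1:])
    results = [(extended, [by_seq[s] for s in path])]
    leftover = [by_seq[s] for s in by_seq if s not in set(path)]
    if leftover:
        for sub in group_by_overlap(leftover, k):
            results.extend(merge_component(sub, k))
    return results


@dataclass
class MergedMotif:
    """An assembled enriched sequence, trimmed to maximum enrichment."""

    member_kmers: tuple[str, ...]
    extended_seq: str
    trimmed_seq: str
    fg_presence: int
    bg_presence: int
    fold: float
    passes_bg_cap: bool | None = None
    untrimmed: bool = False  # extended_seq shorter than trim_min_len


def substring_presence(sub: str, seqs: Sequence[str]) -> int:
    """Number of sequences containing ``sub`` at least once."""
    return sum(sub in s for s in seqs)


def trim_to_max_enrichment(
    extended_seq: str,
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    params: KmerParams | None = None,
    members: Sequence[KmerRecord] = (),
) -> MergedMotif:
    """Trim an extended sequence to the fold-maximising substring.

    All substrings of length ≥ ``trim_min_len`` are scored by fold
    enrichment (presence fractions with the usual pseudocount); ties
    prefer the longer substring, then the 5'-most.  An extended sequence
    shorter than ``trim_min_len`` is returned untrimmed and flagged.
    """
    params = params or KmerParams()
    fg_up = [s.upper() for s in fg_seqs]
    bg_up = [s.upper() for s in bg_seqs]
    n = len(extended_seq)

    def score(sub: str) -> tuple[float, int, int]:
        fg = substring_presence(sub, fg_up)
        bg = substring_presence(sub, bg_up)
        return compute_fold(fg, bg, len(fg_up), len(bg_up), params.pseudocount), fg, bg

    if n < params.trim_min_len:
        fold, fg, bg = score(extended_seq)
        return MergedMotif(tuple(r.seq for r in members), extended_seq,
                           extended_seq, fg, bg, fold, untrimmed=True)
    best = None  # (fold, length, -start, sub, fg, bg)
    for length in range(params.trim_min_len, n + 1):
        for start in range(n - length + 1):
            sub = extended_seq[start:start + length]
            fold, fg, bg = score(sub)
            key = (fold, length, -start)
            if best is None or key > best[0]:
                best = (key, sub, fg, bg)
    (fold, _, _), sub, fg, bg = best
    return MergedMotif(tuple(r.seq for r in members), extended_seq, sub, fg, bg, fold)


def discover_motifs(
    fg_seqs: Sequence[str],
    bg_seqs: Sequence[str],
    params: KmerParams | None = None,
) -> list[MergedMotif]:
    """The full pipeline: enumerate → enrich → filter → group → merge → trim.

    Output is ordered by (fold descending, trimmed sequence).
    """
    params = params or KmerParams()
    records = enrich_kmers(fg_seqs, bg_seqs, params)
    kept = filter_kmers(records, params)
    motifs: list[MergedMotif] = []
    for comp in group_by_overlap(kept, params.k):
        for extended, members in merge_component(comp, params.k):
            motifs.append(trim_to_max_enrichment(extended, fg_seqs, bg_seqs,
                                                 params, members))
    motifs.sort(key=lambda m: (-m.fold, m.trimmed_seq))
    return motifs


def presence_report(
    motifs: Sequence[MergedMotif],
    fg_seqs: Sequence[str],
    secondary_seqs: Sequence[str],
    all_seqs: Sequence[str],
    params: KmerParams | None = None,
) -> tuple[pd.DataFrame, int]:
    """Per-motif presence in the foreground, a secondary set, and all LTRs.

    Returns the report table and the number of foreground sequences
    containing at least one motif.  ``passes_bg_cap`` is set per motif
    from presence in ``all_seqs`` (≤ ``max_bg_fraction``).
    """
    params = params or KmerParams()
    fg_up = [s.upper() for s in fg_seqs]
    sec_up = [s.upper() for s in secondary_seqs]
    all_up = [s.upper() for s in all_seqs]
    rows = []
    fg_hit = [False] * len(fg_up)
    for m in motifs:
        fg = substring_presence(m.trimmed_seq, fg_up)
        sec = substring_presence(m.trimmed_seq, sec_up)
        allc = substring_presence(m.trimmed_seq, all_up)
        all_frac = allc / len(all_up) if all_up else 0.0
        m.passes_bg_cap = all_frac <= params.max_bg_fraction
        for i, s in enumerate(fg_up):
            if m.trimmed_seq in s:
                fg_hit[i] = True
        rows.append({
            "trimmed_seq": m.trimmed_seq,
            "extended_seq": m.extended_seq,
            "n_member_kmers": len(m.member_kmers),
            "fg_presence": fg,
            "fg_fraction": fg / len(fg_up) if fg_up else 0.0,
            "secondary_presence": sec,
            "secondary_fraction": sec / len(sec_up) if sec_up else 0.0,
            "all_presence": allc,
            "all_fraction": all_frac,
            "fold": m.fold,
            "passes_bg_cap": m.passes_bg_cap,
        })
    return pd.DataFrame(rows), sum(fg_hit)
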