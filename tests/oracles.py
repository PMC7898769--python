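"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's indexing, pass bookkeeping and
vectorisation: plain scans and one merge at a time, recomputing
everything from scratch after every change.
"""

from __future__ import annotations

from vmscreen.catalogue import (
    RepeatElement,
    RepeatFeature,
    StructureClass,
    classify_structure,
)


def _obounds(el: RepeatElement) -> tuple[int, int]:
    if el.strand == "+":
        return el.span_start, el.span_end
    return -el.span_end, -el.span_start


def _sides(structure: StructureClass) -> list[str]:
    return {
        StructureClass.FRAG_NO5: ["5p"],
        StructureClass.FRAG_NO3: ["3p"],
        StructureClass.FRAG_INTERNAL_ONLY: ["5p", "3p"],
    }.get(structure, [])


def _rank(structure: StructureClass, side: str) -> int | None:
    missing = (
        {StructureClass.FRAG_NO3, StructureClass.FRAG_INTERNAL_ONLY}
        if side == "5p"
        else {StructureClass.FRAG_NO5, StructureClass.FRAG_INTERNAL_ONLY}
    )
    if structure in missing:
        return 1
    if structure is StructureClass.SOLO_LTR:
        return 2
    if structure is StructureClass.FULL:
        return 3
    return None


def oracle_mend(elements, max_gap=2000, registry=None):
    """Naive mending: per pass, scan fragments in genomic order (5' mend
    before 3'), pick each one's best partner by exhaustive comparison,
    consume each partner once per pass; repeat passes to a fixpoint."""
    pool = [
        RepeatElement(e.element_id, e.chrom, e.strand, list(e.features),
                      classify_structure(e, registry))
        for e in elements
    ]
    while True:
        pool.sort(key=lambda e: (e.chrom, e.span_start))
        consumed: list[RepeatElement] = []
        pairs = []
        for el in pool:
            if any(el is c for c in consumed):
                continue
            hit = None
            for side in _sides(el.structure):
                best = None
                best_key = None
                for p in pool:
                    if p is el or p.chrom != el.chrom or p.strand != el.strand:
                        continue
                    if any(p is c for c in consumed):
                        continue
                    r = _rank(p.structure, side)
                    if r is None:
                        continue
                    s0, e0 = _obounds(el)
                    ps, pe = _obounds(p)
                    if side == "5p":
                        if ps > s0:
                            continue
                        gap = s0 - pe
                    else:
                        if pe < e0:
                            continue
                        gap = ps - e0
                    if gap > max_gap:
                        continue
                    key = (r, max(gap, 0), abs(gap), ps)
                    if best_key is None or key < best_key:
                        best, best_key = p, key
                if best is not None:
                    hit = best
                    break
            if hit is not None:
                consumed.extend([el, hit])
                pairs.append((el, hit))
        if not pairs:
            return sorted(pool, key=lambda e: (e.chrom, e.span_start))
        survivors = [e for e in pool if not any(e is c for c in consumed)]
        for el, partner in pairs:
            five = el if _obounds(el)[0] <= _obounds(partner)[0] else partner
            feats = [
                RepeatFeature(f.chrom, f.start, f.end, f.strand,
                              f.rep_name, f.rep_class_family, five.element_id)
                for f in el.features + partner.features
            ]
            new = RepeatElement(five.element_id, el.chrom, el.strand,
                                feats, StructureClass.FULL)
            new.structure = classify_structure(new, registry)
            survivors.append(new)
        pool = survivors


def oracle_screen(elements, coverages, metas, params):
    """Plain-Python recomputation of the edge screen from raw counts."""
    out = {}
    positions = {}
    for cov in coverages.values():
        for chrom, calls in cov.items():
            positions.setdefault(chrom, set()).update(calls)
    for el in elements:
        pos = sorted(p for p in positions.get(el.chrom, ())
                     if el.span_start <= p < el.span_end)
        edges = []
        if el.structure is StructureClass.FULL:
            edges = ["5p", "3p"]
        elif el.structure is StructureClass.SOLO_LTR:
            edges = ["5p"]
        elif el.structure is StructureClass.FRAG_NO5:
            edges = ["3p"]
        elif el.structure is StructureClass.FRAG_NO3:
            edges = ["5p"]
        for edge in edges:
            left_edge = (edge == "5p") == (el.strand == "+")
            window = pos[: params.n_edge_cpgs] if left_edge else pos[-params.n_edge_cpgs:]
            if not pos:
                window = []
            groups = {}
            per_sample = {}
            for m in metas:
                calls = coverages[m.sample_id].get(el.chrom, {})
                meth = total = covered = 0
                for p in window:
                    c = calls.get(p)
                    if c is None:
                        continue
                    t = c.n_meth + c.n_unmeth
                    if t == 0:
                        continue
                    covered += 1
                    meth += c.n_meth
                    total += t
                informative = (total >= params.min_calls
                               and covered >= params.min_covered_cpgs)
                mean = meth / total if total else None
                per_sample[m.sample_id] = (mean, total, covered, informative)
                groups.setdefault(m.group, [])
                if informative:
                    groups[m.group].append(mean)
            ranges = {g: (max(v) - min(v) if v else None)
                      for g, v in groups.items()}
            passed = all(len(v) >= params.min_informative_samples
                         for v in groups.values())
            stat = (min(r for r in ranges.values()) if passed
                    and all(r is not None for r in ranges.values()) else None)
            cand = passed and stat is not None and stat >= params.range_threshold
            out[(el.element_id, edge)] = {
                "per_sample": per_sample,
                "ranges": ranges,
                "passed": passed,
                "stat": stat,
                "candidate": cand,
            }
    return out


def oracle_kmer_presence(sequences, k):
    """Presence counting by explicit substring scan."""
    counts = {}
    for seq in sequences:
        seq = seq.upper()
        seen = set()
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if set(km) <= set("ACGT"):
                seen.add(km)
        for km in seen:
            counts[km] = counts.get(km, 0) + 1
    return counts


def oracle_overlap_components(kmers, k):
    """Connected components from the full pairwise overlap matrix."""
    kmers = list(kmers)
    n = len(kmers)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and (kmers[i][1:] == kmers[j][:k - 1]
                           or kmers[j][1:] == kmers[i][:k - 1]):
                adj[i][j] = True
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], set()
        while stack:
            u = stack.pop()
            if seen[u]:
                continue
            seen[u] = True
            comp.add(kmers[u])
            stack.extend(v for v in range(n) if adj[u][v] and not seen[v])
        comps.append(frozenset(comp))
    return set(comps)


def oracle_trim(extended, fg, bg, min_len, pseudocount=0.5):
    """Exhaustive substring enumeration for the enrichment-maximising trim."""
    fg = [s.upper() for s in fg]
    bg = [s.upper() for s in bg]
    best = None
    for length in range(min_len, len(extended) + 1):
        for start in range(len(extended) - length + 1):
            sub = extended[start:start + length]
            fgp = sum(sub in s for s in fg)
            bgp = sum(sub in s for s in bg)
            if fgp == 0:
                fold = 0.0
            else:
                fold = (fgp / len(fg)) / ((bgp or pseudocount) / len(bg))
            key = (fold, length, -start)
            if best is None or key > best[0]:
                best = (key, sub)
    return best[1], best[0][0]
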