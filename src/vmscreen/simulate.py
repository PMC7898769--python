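"""Synthetic test bed: a toy genome with embedded LTR retrotransposons,
a fragmented annotation with known mend-truth, and per-sample bisulphite
coverage with planted methylation regimes.

The generator emulates the study design end to end on a desk-scale
genome: fully-structured elements (LTR–internal–LTR, identical flanking
LTRs) and solo LTRs are laid into a random background; the annotation
can be artificially fragmented (splitting element IDs at subelement
boundaries, including exact 500 kb boundary splits); per-CpG coverage
counts are drawn Poisson–Binomial around per-sample true methylation
levels; and 15-nt motifs can be planted into a subset of LTRs.

Methylation regimes:

HYPER
    Hypermethylated background: per-sample levels drawn from a
    concentrated Beta near 1 (the default for non-element CpGs too).
CVM
    Constitutive variable methylation: each individual draws one level
    from Uniform(0.05, 0.95), shared across cell-type groups.
TSVM
    Tissue-specific variable methylation: the first group draws
    per-individual Uniform(0.05, 0.95) levels, the other groups stay
    hypermethylated.

Every operation draws from a named substream of one global seed, so
adding operations never shifts existing draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .catalogue import MendParams, RepeatElement, RepeatFeature, StructureClass, _make_element
from .registry import SubelementRegistry
from .screen import SampleMeta

LTR_NAME = "IAPLTR1_Mm"
INT_NAME = "IAPEz-int"
REP_CLASS = "LTR/ERVK"

_STREAMS = {"layout": 0, "sequence": 1, "levels": 2, "fragment": 3,
            "coverage": 4, "motif": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions: two cell-type groups of 8
    samples each (one individual contributes one sample per group),
    ~10× per-CpG coverage, a hypermethylated background, and a 10%
    minority of constitutively variable elements.
    """

    genome_length: int = 300_000
    n_elements: int = 30
    ltr_length: int = 300
    internal_length: int = 1200
    solo_ltr_fraction: float = 0.25
    fragmentation_rate: float = 0.4
    min_spacing: int = 3000  # > max_gap so mending never bridges true elements
    cpg_spacing: int = 25  # guarantees >= 8 CpGs per LTR
    mutation_rate: float = 0.03
    n_samples: int = 8  # individuals; each yields one sample per group
    groups: tuple[str, ...] = ("B", "T")
    coverage_mean: float = 10.0
    meth_background: tuple[float, float] = (475.0, 25.0)  # Beta(a,b), mean 0.95
    vm_fraction: float = 0.1
    tsvm_fraction: float = 0.0
    motif: str | None = None
    n_motif_carriers: int = 0
    straddle_boundary: bool = False
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.genome_length, self.ltr_length, self.internal_length) <= 0:
            raise ValueError("lengths must be positive")
        for frac in (self.solo_ltr_fraction, self.fragmentation_rate,
                     self.vm_fraction, self.tsvm_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0,1]")
        if self.vm_fraction + self.tsvm_fraction > 1:
            raise ValueError("vm_fraction + tsvm_fraction must be <= 1")
        if self.motif is not None and set(self.motif.upper()) - set("ACGT"):
            raise ValueError("motif must be over {A,C,G,T}")

    @property
    def full_span(self) -> int:
        return 2 * self.ltr_length + self.internal_length

    @property
    def sample_metas(self) -> list[SampleMeta]:
        return [SampleMeta(f"{g}{i + 1}", g)
                for g in self.groups for i in range(self.n_samples)]


@dataclass
class ElementTruth:
    element_id: int
    structure: str
    start: int
    end: int
    regime: str  # HYPER | CVM | TSVM
    levels: dict[str, list[float]]  # group -> per-individual true level
    motif_offset: int | None = None  # offset within the 5' LTR


@dataclass
class SimTruth:
    """Ground truth of one synthetic dataset."""

    elements: list[ElementTruth]
    row_parent: dict[int, int] = field(default_factory=dict)  # annotation id -> true id

    def by_id(self) -> dict[int, ElementTruth]:
        return {e.element_id: e for e in self.elements}

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"elements": [asdict(e) for e in self.elements],
                       "row_parent": self.row_parent}, fh, indent=1)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.int8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _make_ltr_consensus(rng: np.random.Generator, length: int, spacing: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """LTR consensus with CG dinucleotides planted every ``spacing`` bp.

    Returns (sequence codes, protected positions) where protected
    positions carry the planted CpGs and are exempt from mutation so
    every LTR copy keeps its CpG density floor.
    """
    seq = _random_seq(rng, length)
    protected = np.zeros(length, dtype=bool)
    for i in range(spacing // 2, length - 1, spacing):
        seq[i], seq[i + 1] = 1, 2  # C, G
        protected[i:i + 2] = True
    return seq, protected


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float,
            protected: np.ndarray | None = None) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(len(seq)) < rate
    if protected is not None:
        mask &= ~protected
    out[mask] = (out[mask] + rng.integers(1, 4, size=mask.sum(), dtype=np.int8)) % 4
    return out


def _draw_levels(params: SimParams, regime: str, rng: np.random.Generator
                 ) -> dict[str, list[float]]:
    a, b = params.meth_background
    n = params.n_samples
    if regime == "CVM":
        shared = rng.uniform(0.05, 0.95, size=n)
        return {g: shared.tolist() for g in params.groups}
    if regime == "TSVM":
        out = {params.groups[0]: rng.uniform(0.05, 0.95, size=n).tolist()}
        for g in params.groups[1:]:
            out[g] = rng.beta(a, b, size=n).tolist()
        return out
    return {g: rng.beta(a, b, size=n).tolist() for g in params.groups}


def simulate_genome(params: SimParams
                    ) -> tuple[dict[str, str], list[RepeatElement], SimTruth]:
    """Build the toy genome and its true element catalogue.

    Background sequence is i.i.d. uniform over {A,C,G,T}; elements are
    placed left to right with at least ``min_spacing`` bp between
    envelopes.  Fully-structured elements carry identical flanking LTRs
    (per-element mutated copies of one consensus).  Deterministic given
    the seed.
    """
    lay = _rng(params.seed, "layout")
    seqr = _rng(params.seed, "sequence")
    lvl = _rng(params.seed, "levels")
    mot = _rng(params.seed, "motif")

    n = params.n_elements
    n_solo = int(round(params.solo_ltr_fraction * n))
    structures = np.array([StructureClass.SOLO_LTR] * n_solo
                          + [StructureClass.FULL] * (n - n_solo), dtype=object)
    lay.shuffle(structures)
    spans = np.array([params.ltr_length if s is StructureClass.SOLO_LTR
                      else params.full_span for s in structures])

    required = int(spans.sum()) + (n + 1) * params.min_spacing
    if required > params.genome_length:
        raise ValueError(
            f"elements do not fit: genome_length must be >= {required}"
        )
    slack = params.genome_length - required
    extra = lay.multinomial(slack, np.full(n + 1, 1 / (n + 1))) if slack else np.zeros(n + 1, int)
    gaps = params.min_spacing + extra

    starts = []
    pos = 0
    straddle_pending = params.straddle_boundary and params.genome_length > 500_000
    for i in range(n):
        start = pos + int(gaps[i])
        if straddle_pending and start + int(spans[i]) > 500_000:
            # first element to reach the 500 kb boundary is placed across it
            start = max(pos + 10, 500_000 - int(spans[i]) // 2)
            straddle_pending = False
        starts.append(start)
        pos = start + int(spans[i])
    if pos + params.min_spacing > params.genome_length:
        raise ValueError(
            f"elements do not fit: genome_length must be >= {pos + params.min_spacing}"
        )

    genome = _random_seq(seqr, params.genome_length)
    ltr_consensus, protected = _make_ltr_consensus(seqr, params.ltr_length,
                                                   params.cpg_spacing)
    int_consensus = _random_seq(seqr, params.internal_length)

    n_cvm = int(round(params.vm_fraction * n))
    n_tsvm = int(round(params.tsvm_fraction * n))
    regimes = np.array(["CVM"] * n_cvm + ["TSVM"] * n_tsvm
                       + ["HYPER"] * (n - n_cvm - n_tsvm), dtype=object)
    lay.shuffle(regimes)

    # motif carriers are drawn from CVM elements (the foreground set)
    carriers: set[int] = set()
    if params.motif and params.n_motif_carriers:
        cvm_idx = [i for i in range(n) if regimes[i] == "CVM"]
        if params.n_motif_carriers > len(cvm_idx):
            raise ValueError("more motif carriers requested than CVM elements")
        carriers = set(mot.choice(cvm_idx, size=params.n_motif_carriers,
                                  replace=False).tolist())
    motif_codes = None
    if params.motif:
        motif_codes = np.frombuffer(params.motif.upper().encode(), dtype=np.int8).copy()
        lut = np.full(128, -1, dtype=np.int8)
        for b, c in zip(b"ACGT", range(4)):
            lut[b] = c
        motif_codes = lut[motif_codes]

    elements: list[RepeatElement] = []
    truths: list[ElementTruth] = []
    strands = lay.choice(["+", "-"], size=n)
    for i in range(n):
        start = starts[i]
        strand = str(strands[i])
        ltr = _mutate(seqr, ltr_consensus, params.mutation_rate, protected)
        motif_offset = None
        if i in carriers:
            off = int(mot.integers(0, params.ltr_length - len(motif_codes) + 1))
            ltr = ltr.copy()
            ltr[off:off + len(motif_codes)] = motif_codes
            motif_offset = off
        feats = []
        if structures[i] is StructureClass.SOLO_LTR:
            genome[start:start + params.ltr_length] = (
                ltr if strand == "+" else _revcomp_codes(ltr))
            feats.append(RepeatFeature(params.chrom, start,
                                       start + params.ltr_length, strand,
                                       LTR_NAME, REP_CLASS, i))
            end = start + params.ltr_length
        else:
            internal = _mutate(seqr, int_consensus, params.mutation_rate)
            L, I = params.ltr_length, params.internal_length
            body = np.concatenate([ltr, internal, ltr])
            genome[start:start + len(body)] = (
                body if strand == "+" else _revcomp_codes(body))
            end = start + len(body)
            # element-oriented 5' LTR first; convert to genomic coordinates
            coords = [(0, L, LTR_NAME), (L, L + I, INT_NAME),
                      (L + I, 2 * L + I, LTR_NAME)]
            for s0, e0, name in coords:
                if strand == "+":
                    gs, ge = start + s0, start + e0
                else:
                    gs, ge = end - e0, end - s0
                feats.append(RepeatFeature(params.chrom, gs, ge, strand,
                                           name, REP_CLASS, i))
        elements.append(_make_element(i, feats, SubelementRegistry.default()))
        truths.append(ElementTruth(
            element_id=i,
            structure=elements[-1].structure.value,
            start=start,
            end=end,
            regime=str(regimes[i]),
            levels=_draw_levels(params, str(regimes[i]), lvl),
            motif_offset=motif_offset,
        ))
    truth = SimTruth(elements=truths,
                     row_parent={i: i for i in range(n)})
    return {params.chrom: _to_str(genome)}, elements, truth


_RC = np.array([3, 2, 1, 0], dtype=np.int8)


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


def fragment_annotation(
    elements: list[RepeatElement],
    truth: SimTruth,
    params: SimParams,
) -> list[RepeatFeature]:
    """Artificially fragment the true annotation (inverse of mending).

    With probability ``fragmentation_rate`` a fully-structured element's
    rows are split into ≥ 2 element IDs at subelement boundaries.  When
    an element's envelope crosses a 500 kb multiple, it is additionally
    split into two IDs exactly at the boundary (the binning artefact),
    splitting the covering feature in two.  ``truth.row_parent`` is
    updated to map every annotation ID back to its true element.
    """
    rng = _rng(params.seed, "fragment")
    next_id = max((e.element_id for e in elements), default=-1) + 1
    out: list[RepeatFeature] = []
    truth.row_parent = {}

    def emit(feats: list[RepeatFeature], eid: int, parent: int) -> None:
        nonlocal next_id
        truth.row_parent[eid] = parent
        out.extend(RepeatFeature(f.chrom, f.start, f.end, f.strand, f.rep_name,
                                 f.rep_class_family, eid) for f in feats)

    for el in elements:
        parent = el.element_id
        boundary = next(
            (b for b in range(500_000, el.span_end, 500_000) if b > el.span_start),
            None,
        )
        feats = list(el.features)
        if boundary is not None:
            left = [f for f in feats if f.end <= boundary]
            right = [f for f in feats if f.start >= boundary]
            split = [f for f in feats if f.start < boundary < f.end]
            if not split and (not left or not right):
                emit(feats, el.element_id, parent)
                continue
            if split:
                f = split[0]
                left.append(RepeatFeature(f.chrom, f.start, boundary, f.strand,
                                          f.rep_name, f.rep_class_family, f.element_id))
                right.append(RepeatFeature(f.chrom, boundary, f.end, f.strand,
                                           f.rep_name, f.rep_class_family, f.element_id))
            emit(sorted(left, key=lambda f: f.start), el.element_id, parent)
            emit(sorted(right, key=lambda f: f.start), next_id, parent)
            next_id += 1
            continue
        if (el.structure is StructureClass.FULL and len(feats) >= 3
                and rng.random() < params.fragmentation_rate):
            # split at one or both internal subelement boundaries
            n_cuts = 1 + int(rng.random() < 0.5)
            cut_points = sorted(rng.choice([1, 2], size=n_cuts, replace=False).tolist())
            parts = []
            prev = 0
            for c in cut_points:
                parts.append(feats[prev:c])
                prev = c
            parts.append(feats[prev:])
            parts = [p for p in parts if p]
            emit(parts[0], el.element_id, parent)
            for p in parts[1:]:
                emit(p, next_id, parent)
                next_id += 1
        else:
            emit(feats, el.element_id, parent)
    out.sort(key=lambda f: (f.chrom, f.start))
    return out


def cpg_sites(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """Plus-strand positions of every CG dinucleotide per chromosome."""
    out = {}
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype=np.int8)
        cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        out[chrom] = np.flatnonzero(cg)
    return out


def simulate_coverage(
    genome: dict[str, str],
    truth: SimTruth,
    params: SimParams,
) -> dict[str, dict[str, dict[int, tuple[int, int]]]]:
    """Per-sample per-CpG methylation counts.

    For CpG c in sample s: total calls ~ Poisson(coverage_mean) and
    methylated calls ~ Binomial(total, p), where p is the owning
    element's per-sample true level (regime-dependent) or, for
    background CpGs, a fresh draw from the hypermethylated Beta.
    Returns {sample_id: {chrom: {pos: (n_meth, n_unmeth)}}};
    zero-coverage CpGs are omitted (as in real coverage files).
    """
    rng = _rng(params.seed, "coverage")
    sites = cpg_sites(genome)
    a, b = params.meth_background
    by_id = truth.by_id()
    spans = sorted((t.start, t.end, t.element_id) for t in truth.elements)
    starts = np.array([s[0] for s in spans])
    ends = np.array([s[1] for s in spans])
    ids = np.array([s[2] for s in spans])

    out: dict[str, dict[str, dict[int, tuple[int, int]]]] = {}
    for gi, group in enumerate(params.groups):
        for ind in range(params.n_samples):
            sample_id = f"{group}{ind + 1}"
            cov: dict[str, dict[int, tuple[int, int]]] = {}
            for chrom, pos in sites.items():
                idx = np.searchsorted(starts, pos, side="right") - 1
                inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
                p = rng.beta(a, b, size=len(pos))  # background regime
                for j in np.flatnonzero(inside):
                    t = by_id[int(ids[idx[j]])]
                    p[j] = t.levels[group][ind]
                totals = rng.poisson(params.coverage_mean, size=len(pos))
                meth = rng.binomial(totals, p)
                covered = totals > 0
                cov[chrom] = {
                    int(q): (int(m), int(t - m))
                    for q, m, t in zip(pos[covered], meth[covered], totals[covered])
                }
            out[sample_id] = cov
    return out


def plant_motifs(
    ltr_sequences: list[str],
    motif: str,
    carrier_indices: list[int],
    seed: int = 0,
    offsets: list[int] | None = None,
) -> tuple[list[str], dict[int, int]]:
    """Substitute ``motif`` in place into the carrier sequences.

    Offsets are drawn uniformly (or given); non-carriers are untouched.
    Returns the new sequences and {carrier index: offset}.
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A,C,G,T}")
    rng = _rng(seed, "motif")
    out = list(ltr_sequences)
    positions: dict[int, int] = {}
    for j, idx in enumerate(carrier_indices):
        if not 0 <= idx < len(out):
            raise IndexError(f"carrier index {idx} out of range")
        seq = out[idx]
        if len(seq) < len(motif):
            raise ValueError("motif longer than carrier sequence")
        off = (offsets[j] if offsets is not None
               else int(rng.integers(0, len(seq) - len(motif) + 1)))
        out[idx] = seq[:off] + motif + seq[off + len(motif):]
        positions[idx] = off
    return out, positions


# ------------------------------------------------------------- file output

def write_genome_fasta(genome: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_coverage_files(
    coverages: dict[str, dict[str, dict[int, tuple[int, int]]]],
    params: SimParams,
    out_dir: str,
) -> str:
    """Write per-sample six-column coverage TSVs plus the sample sheet.

    Returns the sample-sheet path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = out / "samples.tsv"
    with open(sheet, "w") as sh:
        sh.write("sample_id\tgroup\tpath\n")
        for meta in params.sample_metas:
            path = out / f"{meta.sample_id}.cov.tsv"
            with open(path, "w") as fh:
                for chrom in sorted(coverages[meta.sample_id]):
                    calls = coverages[meta.sample_id][chrom]
                    for pos in sorted(calls):
                        m, u = calls[pos]
                        pct = 100.0 * m / (m + u) if m + u else 0.0
                        fh.write(f"{chrom}\t{pos}\t{pos}\t{pct:.2f}\t{m}\t{u}\n")
            sh.write(f"{meta.sample_id}\t{meta.group}\t{path}\n")
    return str(sheet)


def coverage_as_calls(cov: dict[str, dict[int, tuple[int, int]]]):
    """Convert a generator coverage dict into screen CpGCall maps."""
    from .screen import CpGCall

    return {chrom: {pos: CpGCall(chrom, pos, m, u)
                    for pos, (m, u) in calls.items()}
            for chrom, calls in cov.items()}
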