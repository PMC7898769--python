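"""End-to-end pipeline: mend → screen → extract candidate LTRs → k-mers.

Each stage's survivor counts are logged at INFO, and a run manifest
(parameters, input checksums, per-stage outputs) is written so runs are
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .catalogue import (
    MendParams,
    StructureClass,
    extract_ltr_sequence,
    group_into_elements,
    mend_fragmented,
    parse_rm_annotation,
    patch_500kb_splits,
    summarize_catalogue,
    write_bed6,
    write_catalogue_tsv,
)
from .kmers import KmerParams, discover_motifs, presence_report
from .registry import SubelementRegistry
from .screen import ScreenParams, candidate_elements, load_coverage, screen_catalogue

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    annotation: str
    genome: str | None = None
    sample_sheet: str | None = None
    out_dir: str = "vmscreen_out"
    registry_path: str | None = None
    iap_only: bool = True
    mend: MendParams = field(default_factory=MendParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    kmers: KmerParams = field(default_factory=KmerParams)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs = {k: v for k, v in doc.items()
                  if k in ("annotation", "genome", "sample_sheet", "out_dir",
                           "registry_path", "iap_only")}
        for key, klass in (("mend", MendParams), ("screen", ScreenParams),
                           ("kmers", KmerParams)):
            if key in doc:
                kwargs[key] = klass(**doc[key])
        return cls(**kwargs)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def mend_annotation(config: PipelineConfig):
    """Stage 1: parse, patch 500 kb splits, and mend the annotation."""
    registry = (SubelementRegistry.from_yaml(config.registry_path)
                if config.registry_path else SubelementRegistry.default())
    features = parse_rm_annotation(config.annotation, registry,
                                   iap_only=config.iap_only)
    logger.info("parsed %d annotation rows", len(features))
    elements = group_into_elements(features, registry, config.mend)
    before = summarize_catalogue(elements)
    logger.info("grouped into %d elements (%.0f%% fragmented)",
                before.n_elements, 100 * before.fragmented_fraction)
    elements = patch_500kb_splits(elements, config.mend, registry)
    elements = mend_fragmented(elements, config.mend, registry)
    after = summarize_catalogue(elements)
    logger.info("mended catalogue: %d elements (%.0f%% fragmented)",
                after.n_elements, 100 * after.fragmented_fraction)
    return elements, registry, {"before": before.to_dict(), "after": after.to_dict()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write every stage output plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "params": {
            "mend": asdict(config.mend),
            "screen": asdict(config.screen),
            "kmers": asdict(config.kmers),
        },
        "inputs": {},
        "stages": [],
    }
    for name in ("annotation", "genome", "sample_sheet"):
        path = getattr(config, name)
        if path:
            if not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")
            manifest["inputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    # ---- stage 1: mend
    elements, registry, counts = mend_annotation(config)
    write_catalogue_tsv(elements, str(out / "catalogue.tsv"))
    write_bed6(elements, str(out / "catalogue.bed"))
    manifest["stages"].append({"stage": "mend", **counts,
                               "outputs": ["catalogue.tsv", "catalogue.bed"]})

    # ---- stage 2: screen
    screen_df = pd.DataFrame()
    cand_ids: list[int] = []
    if config.sample_sheet:
        from .screen import read_sample_sheet

        sheet = read_sample_sheet(config.sample_sheet)
        metas = [m for m, _ in sheet]
        coverages = {m.sample_id: load_coverage(p) for m, p in sheet}
        logger.info("loaded coverage for %d samples", len(coverages))
        screen_df = screen_catalogue(elements, coverages, metas, config.screen)
        screen_df.to_csv(out / "screen.tsv", sep="\t", index=False)
        cand_ids = candidate_elements(screen_df)
        by_id = {e.element_id: e for e in elements}
        with open(out / "candidates.bed", "w") as fh:
            for eid in cand_ids:
                el = by_id[eid]
                fh.write(f"{el.chrom}\t{el.span_start}\t{el.span_end}"
                         f"\t{eid}\t0\t{el.strand}\n")
        n_edges = len(screen_df)
        n_pass = int(screen_df["passed_sample_filter"].sum()) if n_edges else 0
        logger.info("screen: %d edges, %d passed sample filter, %d candidate elements",
                    n_edges, n_pass, len(cand_ids))
        manifest["stages"].append({
            "stage": "screen", "n_edges": n_edges,
            "n_passed_sample_filter": n_pass,
            "n_candidate_elements": len(cand_ids),
            "outputs": ["screen.tsv", "candidates.bed"],
        })

    # ---- stages 3+4: extract candidate 5' LTRs and run k-mer enrichment
    if config.genome and cand_ids:
        import pyfaidx

        genome = (pyfaidx.Fasta(config.genome)
                  if str(config.genome).endswith((".fa", ".fasta", ".fa.gz"))
                  else config.genome)
        by_id = {e.element_id: e for e in elements}
        fg_seqs, bg_seqs = [], []
        fg_ids = set(cand_ids)
        for el in elements:
            if el.structure not in (StructureClass.FULL, StructureClass.SOLO_LTR):
                continue
            try:
                seq = extract_ltr_sequence(el, "5p", genome, registry)
            except (ValueError, KeyError):
                continue
            (fg_seqs if el.element_id in fg_ids else bg_seqs).append(seq)
        with open(out / "fg_ltrs.fasta", "w") as fh:
            for i, s in enumerate(fg_seqs):
                fh.write(f">fg_{i}\n{s}\n")
        logger.info("extracted %d foreground and %d background 5' LTRs",
                    len(fg_seqs), len(bg_seqs))
        manifest["stages"].append({"stage": "extract_ltrs",
                                   "n_fg": len(fg_seqs), "n_bg": len(bg_seqs),
                                   "outputs": ["fg_ltrs.fasta"]})

        motifs = discover_motifs(fg_seqs, bg_seqs, config.kmers)
        report, n_carriers = presence_report(motifs, fg_seqs, [],
                                             fg_seqs + bg_seqs, config.kmers)
        report.to_csv(out / "motifs.tsv", sep="\t", index=False)
        with open(out / "motifs.fasta", "w") as fh:
            for i, m in enumerate(motifs):
                fh.write(f">motif_{i} fold={m.fold:.1f}\n{m.trimmed_seq}\n")
        logger.info("k-mers: %d motifs; %d/%d foreground LTRs carry >= 1 motif",
                    len(motifs), n_carriers, len(fg_seqs))
        manifest["stages"].append({
            "stage": "kmers", "n_motifs": len(motifs),
            "n_fg_with_motif": n_carriers,
            "outputs": ["motifs.tsv", "motifs.fasta"],
        })

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def iap_type_frequency_report(
    elements,
    registry: SubelementRegistry | None = None,
    subsets: dict[str, set[int]] | None = None,
) -> pd.DataFrame:
    """Element-type frequency table (relative to the most common type).

    Fully-structured elements are labelled ``LTR – internal`` with the
    common "IAP"/"IAPLTR" prefixes stripped; incomplete elements join
    their present subelement types with ``||``.  Frequencies are
    reported genome-wide and, when ``subsets`` maps labels to element-ID
    sets, per subset.
    """
    def short(name: str) -> str:
        for prefix in ("IAPLTR", "IAP"):
            if name.startswith(prefix):
                return "LTR" + name[len(prefix):] if prefix == "IAPLTR" else name[len(prefix):]
        return name

    def type_label(el) -> str:
        names = [f.rep_name for f in el.oriented_features]
        uniq = list(dict.fromkeys(names))
        if el.structure is StructureClass.SOLO_LTR:
            return short(uniq[0])
        if el.structure is StructureClass.FULL:
            ltr = short(names[0])
            internals = [short(n) for n in dict.fromkeys(
                f.rep_name for f in el.features
                if (registry or SubelementRegistry.default()).is_internal(f.rep_name)
                or f.rep_name.endswith("-int"))]
            return f"{ltr} – {internals[0] if internals else '?'}"
        return "||".join(short(n) for n in uniq)

    labels = {el.element_id: type_label(el) for el in elements}
    counts = pd.Series(list(labels.values())).value_counts()
    top = counts.max() if len(counts) else 1
    df = pd.DataFrame({
        "type": counts.index,
        "n_genome": counts.values,
        "freq_genome": counts.values / len(elements) if len(elements) else 0.0,
        "rel_freq_genome": counts.values / top,
    })
    for name, ids in (subsets or {}).items():
        sub = pd.Series([labels[i] for i in ids if i in labels]).value_counts()
        df[f"n_{name}"] = df["type"].map(sub).fillna(0).astype(int)
        df[f"freq_{name}"] = df[f"n_{name}"] / max(len(ids), 1)
    return df
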