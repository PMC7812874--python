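"""End-to-end screen: scan -> detect -> prefilter -> validate -> annotate ->
classify -> summarize.

The pipeline mirrors the staged published screen: descriptor scanning for
5S-like loci, split-hit detection of insertion-bearing genes against a set
of normal 5S references, size/ambiguity prefiltering, exclusion of
chimeric and internally duplicated sequences, universal-core numbering and
segment extraction, structural typing, and a catalog summary.  Every
filter logs its rejections; reruns with identical inputs and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import (Molecule, StructuralType, catalog_frame,
                       classify_structural_types, summarize_catalog,
                       summary_text, write_catalog)
from .descriptor import Descriptor, load_descriptor, packaged_descriptor, scan_descriptor
from .detect import (SplitParams, detect_chimera, detect_internal_duplication,
                     find_split_candidates, prefilter_records)
from .io import Record, annotation_features, write_gff3
from .iupac import reverse_complement
from .numbering import AlignmentError
from .pairwise import LOCAL_SCORING
from .schema import load_schema
from .annotate import annotate_record


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and record."""


@dataclass(frozen=True)
class PipelineConfig:
    schema_variants: tuple[str, ...] = ("bacterial", "archaeal")
    descriptor_names: tuple[str, ...] = ("thermoanaerobacterales", "halobacteria")
    descriptor_paths: tuple[str, ...] = ()      # extra descriptor files
    extra_references: dict = field(default_factory=dict)  # id -> sequence
    split: SplitParams = field(default_factory=SplitParams)
    min_record_len: int = 130
    forbid_ambiguous: bool = True
    min_segment_len: int = 10
    identity_threshold: float = 0.6
    run_scan: bool = True
    # validity-locus thresholds: partial hits this strong trigger the
    # chimera/duplication screen even without a split candidate
    flag_min_hit_len: int = 40
    flag_min_identity: float = 0.7

    def validate(self) -> None:
        for v in self.schema_variants:
            load_schema(v)
        for n in self.descriptor_names:
            packaged_descriptor(n)
        for p in self.descriptor_paths:
            if not Path(p).exists():
                raise PipelineError(f"startup: descriptor file missing: {p}")


def config_from_yaml(path) -> PipelineConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    split = SplitParams(**doc.pop("split", {})) if "split" in doc else SplitParams()
    doc = {k: tuple(v) if isinstance(v, list) else v for k, v in doc.items()}
    return PipelineConfig(split=split, **doc)


@dataclass
class FlaggedLocus:
    genome_id: str
    start: int
    end: int
    verdict: str       # "duplicated" | "chimeric" | "clean"
    details: str = ""


@dataclass
class PipelineResult:
    molecules: list[Molecule]
    types: list[StructuralType]
    catalog: object                  # pandas DataFrame
    summary: dict
    stage_counts: dict
    rejections: list[tuple[str, str]]
    flagged: list[FlaggedLocus]
    scan_hits: list
    candidates: list
    gene_spans: dict
    log_lines: list[str]


# ---------------------------------------------------------------------------

def _references(config: PipelineConfig) -> dict[str, tuple[str, str]]:
    """reference id -> (variant, sequence)"""
    refs: dict[str, tuple[str, str]] = {}
    for v in config.schema_variants:
        sch = load_schema(v)
        refs[sch.reference_id] = (v, sch.reference_sequence)
    for rid, seq in sorted(config.extra_references.items()):
        refs[str(rid)] = ("bacterial", str(seq))
    return refs


def _descriptors(config: PipelineConfig) -> list[Descriptor]:
    out = [packaged_descriptor(n) for n in config.descriptor_names]
    out += [load_descriptor(p) for p in config.descriptor_paths]
    return out


def _merge_spans(spans: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1] + gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def run_pipeline(genomes: list[Record], config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full screen over ``genomes`` and return the catalog."""
    config = config or PipelineConfig()
    config.validate()
    refs = _references(config)
    descriptors = _descriptors(config) if config.run_scan else []
    log: list[str] = [f"pipeline parameters: {json.dumps(_config_dict(config), sort_keys=True)}"]
    counts: dict[str, int] = {}
    rejections: list[tuple[str, str]] = []
    flagged: list[FlaggedLocus] = []
    scan_hits = []
    all_candidates = []

    # -- stage 1: descriptor scan ------------------------------------------
    for rec in genomes:
        for d in descriptors:
            hits = scan_descriptor(rec.seq, d, both_strands=True, seq_id=rec.id)
            scan_hits.extend(hits)
            log.append(f"scan: {rec.id} x {d.name}: {len(hits)} hits")
    counts["scan_hits"] = len(scan_hits)

    # -- stage 2: split-hit detection --------------------------------------
    per_genome: dict[str, dict] = {}
    ref_chimera_set = {rid: seq for rid, (_, seq) in refs.items()}
    for rec in genomes:
        normal_spans: list[tuple[int, int]] = []
        partials: list = []
        cands: dict[tuple, object] = {}
        for rid, (variant, rseq) in sorted(refs.items()):
            result = find_split_candidates(rseq, rec.seq, config.split,
                                           reference_id=rid, genome_id=rec.id)
            for c in result.candidates:
                key = (c.strand, c.insertion_start, c.insertion_end)
                prev = cands.get(key)
                score = c.five_prime.score + c.three_prime.score
                if prev is None or score > prev[0]:
                    cands[key] = (score, c, variant)
            normal_spans += [(h.subject_start, h.subject_end)
                             for h in result.normal_matches]
            partials += result.partial_hits
        kept = [(c, v) for (_, c, v) in cands.values()]
        kept.sort(key=lambda cv: (cv[0].insertion_start, cv[0].strand))
        per_genome[rec.id] = {"cands": kept, "normals": normal_spans,
                              "partials": partials, "seq": rec.seq}
        all_candidates += [c for c, _ in kept]
        log.append(f"detect: {rec.id}: {len(kept)} split candidates, "
                   f"{len(normal_spans)} normal matches, "
                   f"{len(partials)} partial hits")
    counts["split_candidates"] = len(all_candidates)

    # -- stage 3: candidate record extraction (locus merge) ----------------
    records: dict[str, str] = {}
    record_meta: dict[str, tuple[str, int, int, str, str]] = {}
    for gid, info in sorted(per_genome.items()):
        by_strand: dict[str, list] = {}
        for c, variant in info["cands"]:
            by_strand.setdefault(c.strand, []).append((c, variant))
        for strand, group in sorted(by_strand.items()):
            spans = _merge_spans([(c.gene_start, c.gene_end) for c, _ in group])
            for s, e in spans:
                inside = [(c, v) for c, v in group
                          if c.gene_start >= s and c.gene_end <= e]
                # variant of the best-scoring candidate at this locus
                variant = max(inside, key=lambda cv: cv[0].five_prime.score
                              + cv[0].three_prime.score)[1]
                seq = info["seq"][s:e]
                if strand == "-":
                    seq = reverse_complement(seq)
                rid = f"{gid}:{s}-{e}({strand})"
                records[rid] = seq
                record_meta[rid] = (gid, s, e, strand, variant)
    counts["candidate_records"] = len(records)

    # -- stage 4: prefilter -------------------------------------------------
    kept_records, prefilter_log = prefilter_records(
        records, min_len=config.min_record_len,
        forbid_ambiguous=config.forbid_ambiguous)
    rejections += [(r.record_id, f"prefilter: {r.reason}") for r in prefilter_log]
    counts["prefilter_kept"] = len(kept_records)
    counts["prefilter_rejected"] = len(prefilter_log)
    assert counts["candidate_records"] == (counts["prefilter_kept"]
                                           + counts["prefilter_rejected"])
    log.append(f"prefilter: kept {len(kept_records)} / {len(records)}")

    # -- stage 5: validity (duplication, chimera) ---------------------------
    valid_records: dict[str, str] = {}
    rejected_validity: dict[str, str] = {}   # rid -> verdict
    for rid, seq in sorted(kept_records.items()):
        dup = detect_internal_duplication(seq)
        if dup.duplicated:
            rejected_validity[rid] = "duplicated"
            rejections.append((rid, f"validity: internal duplication "
                                    f"(identity {dup.identity:.2f})"))
            continue
        chi = detect_chimera(seq, ref_chimera_set)
        if chi.chimeric:
            rejected_validity[rid] = "chimeric"
            rejections.append((rid, f"validity: chimera ({chi.details})"))
            continue
        valid_records[rid] = seq
    counts["valid_records"] = len(valid_records)
    log.append(f"validate: kept {len(valid_records)} / {len(kept_records)}")

    # -- stage 5b: flag suspicious non-candidate loci -----------------------
    # loci are only exempt from the suspicion screen when a candidate record
    # there passed the validity screen (a record rejected earlier -- by the
    # prefilter, or as a chimera that merely brushed a contaminated locus --
    # never received a verdict for the locus as a whole)
    surviving_spans: dict[str, list[tuple[int, int]]] = {}
    for rid in valid_records:
        gid, s, e, _, _ = record_meta[rid]
        surviving_spans.setdefault(gid, []).append((s, e))
    for gid, info in sorted(per_genome.items()):
        candidate_spans = _merge_spans(surviving_spans.get(gid, []))
        strong = [h for h in info["partials"]
                  if h.length >= config.flag_min_hit_len
                  and h.identity >= config.flag_min_identity]
        spans = _merge_spans(
            [(h.subject_start, h.subject_end) for h in strong]
            + [(s, e) for s, e in info["normals"]], gap=10)
        for s, e in spans:
            if not any(h.subject_start >= s and h.subject_end <= e
                       for h in strong):
                continue  # pure normal-match locus
            if any(not (e <= cs or s >= ce) for cs, ce in candidate_spans):
                continue  # already claimed by a split candidate
            s0, e0 = max(0, s - 20), min(len(info["seq"]), e + 20)
            locus_seq = info["seq"][s0:e0]
            # orient the locus by its strongest supporting hit so the
            # half-sequence chimera comparison sees the gene-sense strand
            inside = [h for h in strong
                      if h.subject_start >= s and h.subject_end <= e]
            if inside and max(inside, key=lambda h: h.score).strand == "-":
                locus_seq = reverse_complement(locus_seq)
            verdict, details = "clean", ""
            if len(locus_seq) >= 60:
                dup = detect_internal_duplication(locus_seq)
                if dup.duplicated:
                    verdict = "duplicated"
                    details = f"identity {dup.identity:.2f}"
            covers_normal = any(ns >= s and ne <= e
                                for ns, ne in info["normals"])
            if verdict == "clean" and covers_normal:
                continue  # a full-length normal match explains this locus
            if verdict == "clean":
                chi = detect_chimera(locus_seq, ref_chimera_set)
                verdict = "chimeric" if chi.chimeric else "clean"
                details = chi.details if chi.chimeric else ""
            flagged.append(FlaggedLocus(gid, s0, e0, verdict, details))
            log.append(f"flag: {gid}:{s0}-{e0} -> {verdict}")
    # a contaminant counts as flagged whether it surfaced as a suspicious
    # locus or as a candidate record rejected by the validity screen; a
    # rejected record whose span overlaps a same-verdict locus is the same
    # event and is not counted twice
    n_extra = {"duplicated": 0, "chimeric": 0}
    for rid, verdict in rejected_validity.items():
        gid, s, e, _, _ = record_meta[rid]
        covered = any(f.verdict == verdict and f.genome_id == gid
                      and not (f.end <= s or f.start >= e) for f in flagged)
        if not covered:
            n_extra[verdict] += 1
    counts["flagged_duplications"] = (
        sum(f.verdict == "duplicated" for f in flagged) + n_extra["duplicated"])
    counts["flagged_chimeras"] = (
        sum(f.verdict == "chimeric" for f in flagged) + n_extra["chimeric"])

    # -- stage 6: annotation -----------------------------------------------
    molecules: list[Molecule] = []
    gene_spans: dict[str, tuple[str, int, int, str]] = {}
    for rid, seq in sorted(valid_records.items()):
        gid, s, e, strand, variant = record_meta[rid]
        schema = load_schema(variant)
        try:
            _, segments = annotate_record(seq, schema, record_id=rid,
                                          taxon=gid,
                                          min_len=config.min_segment_len)
        except AlignmentError as err:
            rejections.append((rid, f"annotate: {err}"))
            continue
        if not segments:
            rejections.append((rid, "annotate: no expansion segment >= "
                                    f"{config.min_segment_len} nt"))
            continue
        molecules.append(Molecule(record_id=rid, taxon=gid,
                                  segments=tuple(segments)))
        gene_spans[rid] = (gid, s, e, strand)
    counts["annotated_molecules"] = len(molecules)
    log.append(f"annotate: {len(molecules)} molecules with segments")

    # -- stage 7: classification -------------------------------------------
    types = classify_structural_types(molecules, config.identity_threshold)
    counts["structural_types"] = len(types)

    # -- stage 8: summary ----------------------------------------------------
    catalog = catalog_frame(molecules, types)
    summary = summarize_catalog(catalog)
    log.append(f"summary: {json.dumps(summary, sort_keys=True)}")
    return PipelineResult(molecules=molecules, types=types, catalog=catalog,
                          summary=summary, stage_counts=counts,
                          rejections=sorted(rejections), flagged=flagged,
                          scan_hits=scan_hits, candidates=all_candidates,
                          gene_spans=gene_spans, log_lines=log)


def _config_dict(config: PipelineConfig) -> dict:
    d = {k: v for k, v in vars(config).items()}
    d["split"] = {k: v for k, v in vars(config.split).items() if k != "scoring"}
    d["extra_references"] = sorted(d["extra_references"])
    for k, v in list(d.items()):
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def write_outputs(result: PipelineResult, out_dir) -> dict[str, Path]:
    """Write catalog TSV, GFF3, summary and log; deterministic bytes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["catalog"] = out / "catalog.tsv"
    write_catalog(result.catalog, paths["catalog"])
    paths["gff3"] = out / "annotations.gff3"
    write_gff3(annotation_features(result.molecules, result.gene_spans),
               paths["gff3"])
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(summary_text(result.summary))
    paths["summary_json"] = out / "summary.json"
    paths["summary_json"].write_text(
        json.dumps({"summary": result.summary,
                    "stage_counts": result.stage_counts},
                   sort_keys=True, indent=2) + "\n")
    paths["log"] = out / "pipeline.log"
    paths["log"].write_text("\n".join(result.log_lines) + "\n")
    return paths
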