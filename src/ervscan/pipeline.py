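"""Stage orchestration: discover -> classify -> motifs -> express.

Each ``run_*`` function is pure plumbing over the analysis modules and
returns plain data structures; the CLI layer only handles file I/O.  Every
output row is sorted deterministically so identical configurations yield
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import curation, elements, motifs, placement, search
from .codonalign import align_codon_aware
from .config import PipelineConfig
from .seqio import GffRecord

SOURCE_TRANSLATED = "translated_search"
SOURCE_PROFILE = "profile_scan"

QUERY_KIND = {"PR": "RVP", "RVT_1": "RVT_1", "GAG": "GAG"}


@dataclass
class DiscoveryResult:
    annotations: list[GffRecord] = field(default_factory=list)
    loci: list[curation.Locus] = field(default_factory=list)
    candidates: list[elements.CandidateElement] = field(default_factory=list)


def _search_params(config: PipelineConfig) -> search.SearchParams:
    return search.SearchParams(
        matrix_name=config.matrix_name, gap_open=config.gap_open,
        gap_extend=config.gap_extend, min_score=config.min_score,
        merge_gap=config.merge_gap,
        profile_threshold=config.profile_threshold)


def _ltr_params(config: PipelineConfig) -> elements.LtrParams:
    return elements.LtrParams(
        l_min=config.ltr_min, l_max=config.ltr_max,
        min_identity=config.ltr_identity,
        d_min=config.ltr_spacing_min, d_max=config.ltr_spacing_max)


def reference_profiles(references: Mapping[str, str],
                       pr_span: tuple[int, int],
                       rt_span: tuple[int, int]) -> list[search.Profile]:
    """PSSMs for the protease and RT core built from reference translations.

    The reference library is substitution-only, so equal-offset slices are
    already aligned.
    """
    pr_rows = [search.translate(seq[pr_span[0]:pr_span[1]])
               for seq in references.values()]
    rt_rows = [search.translate(seq[rt_span[0]:rt_span[1]])
               for seq in references.values()]
    return [search.build_profile(pr_rows, kind="RVP"),
            search.build_profile(rt_rows, kind="RVT_1")]


def run_discover(genome: Mapping[str, str], queries: Mapping[str, str],
                 config: PipelineConfig,
                 profiles: Sequence[search.Profile] = (),
                 ) -> DiscoveryResult:
    """Translated search + LTR pairing + profile scan + curation + loci."""
    params = _search_params(config)
    ltr_params = _ltr_params(config)
    result = DiscoveryResult()
    annotations: list[GffRecord] = []
    for target_id in sorted(genome):
        seq = genome[target_id]
        # BLAST-like route
        for query_id in sorted(queries):
            if query_id == "GAG":
                continue   # gag is only used for co-expression checks
            query = queries[query_id]
            hits = search.translated_search(target_id, seq, query_id, query,
                                            params)
            merged = search.merge_frame_hits(hits, params)
            for hit in merged:
                ext = search.flush_extend(hit, len(query), len(seq))
                annotations.append(GffRecord(
                    seqid=target_id, source=SOURCE_TRANSLATED,
                    type=QUERY_KIND.get(query_id, query_id),
                    start=ext.start, end=ext.end, score=hit.score,
                    strand=hit.strand,
                    attributes={"query": query_id,
                                "hit_start": str(hit.start),
                                "hit_end": str(hit.end),
                                # mixed frames = frame-split gene, i.e. an
                                # indel broke the reading frame
                                "frame": "mixed" if hit.is_merged
                                else str(hit.frame),
                                "clipped": str(int(ext.clipped_start
                                                   or ext.clipped_end))}))
        # LTR harvester-like route
        cands = elements.find_ltr_pairs(target_id, seq, ltr_params)
        result.candidates.extend(cands)
        domain_hits = []
        for profile in profiles:
            domain_hits.extend(search.profile_scan(target_id, seq, profile,
                                                   params))
        elements.assign_domains(cands, domain_hits)
        retained = elements.cooccurrence_filter(cands)
        for hit in retained:
            annotations.append(GffRecord(
                seqid=target_id, source=SOURCE_PROFILE, type=hit.kind,
                start=hit.start, end=hit.end, score=hit.score,
                strand=hit.strand, attributes={"frame": str(hit.frame)}))
        for cand in cands:
            annotations.append(GffRecord(
                seqid=target_id, source=SOURCE_PROFILE, type="element",
                start=cand.start, end=cand.end, score=cand.identity,
                strand="+",
                attributes={"ltr5": f"{cand.ltr5[0]}-{cand.ltr5[1]}",
                            "ltr3": f"{cand.ltr3[0]}-{cand.ltr3[1]}"}))
    annotations.sort(key=lambda a: (a.seqid, a.start, a.end, a.type, a.source))
    result.annotations = annotations
    locus_input = [a for a in annotations if a.type in ("RVP", "RVT_1")]
    result.loci = curation.group_loci(locus_input, max_gap=config.locus_max_gap)
    return result


@dataclass
class ClassificationResult:
    reference_tree: placement.ReferenceTree | None = None
    placements: dict[str, placement.Placement] = field(default_factory=dict)
    locus_verdicts: pd.DataFrame | None = None
    motif_calls: list[motifs.MotifCall] = field(default_factory=list)
    motif_table: pd.DataFrame | None = None


def extract_pr_sequences(genome: Mapping[str, str],
                         discovery: DiscoveryResult,
                         ) -> tuple[dict[str, str], set[str]]:
    """Nucleotide sequences of translated-search protease annotations.

    Also returns the ids whose source hit spanned multiple reading frames
    (frame-split genes; treated as frameshift evidence downstream).
    """
    out = {}
    mixed: set[str] = set()
    for ann in discovery.annotations:
        if ann.source != SOURCE_TRANSLATED or ann.type != "RVP":
            continue
        seq = genome[ann.seqid][ann.start:ann.end]
        if ann.strand == "-":
            from .seqio import revcomp
            seq = revcomp(seq)
        name = f"{ann.seqid}:{ann.start}-{ann.end}"
        out[name] = seq
        if ann.attributes.get("frame") == "mixed":
            mixed.add(name)
    return out, mixed


def run_classify(genome: Mapping[str, str], discovery: DiscoveryResult,
                 references: Mapping[str, str],
                 reference_labels: Mapping[str, str],
                 config: PipelineConfig,
                 pr_query: str | None = None) -> ClassificationResult:
    """Codon-align queries with references, place them, call motifs."""
    result = ClassificationResult()
    queries_nt, mixed_frame = extract_pr_sequences(genome, discovery)
    # re-scan each extracted region at a permissive threshold: a frame-split
    # alignment to the protease query is frameshift evidence even when one
    # fragment scored below the genome-wide search threshold
    if pr_query is None and references:
        first = references[sorted(references)[0]]
        pr_query = search.translate(first[:318])
    if pr_query:
        rescan_params = search.SearchParams(min_score=55.0)
        for name, nt in queries_nt.items():
            if name in mixed_frame or len(nt) < 3:
                continue
            local_hits = search.translated_search(name, nt, "pr", pr_query,
                                                  rescan_params)
            frames = {(h.strand, h.frame) for h in local_hits}
            if len(frames) >= 2:
                mixed_frame.add(name)
    ref_align = align_codon_aware(references)
    ref_tree = placement.build_reference_tree(ref_align.aa_rows,
                                              reference_labels)
    result.reference_tree = ref_tree
    engine = placement.PlacementEngine(ref_tree, ref_align.aa_rows)
    if not queries_nt:
        result.locus_verdicts = pd.DataFrame(
            columns=["locus_id", "verdict", "conflict", "dissenters"])
        result.motif_table = motifs.tabulate_motifs([])
        return result

    # gap-induction curation against the joint alignment
    joint = align_codon_aware({**references, **queries_nt})
    retained, removed = curation.gap_induction_filter(
        joint.aa_rows, threshold=config.gap_induction_threshold)
    kept_queries = {k: v for k, v in queries_nt.items() if k in retained}
    aligned = align_codon_aware({**references, **kept_queries}) \
        if set(kept_queries) != set(queries_nt) else joint

    for qid in sorted(kept_queries):
        seg_row = aligned.aa_rows[qid]
        # express the query over the frozen reference columns
        query_aa = "".join(ch for ch in seg_row
                           if ch not in ("-", "!"))
        row = placement.align_query_to_reference(ref_align.aa_rows, query_aa)
        result.placements[qid] = engine.place(
            qid, row, min_overlap=config.min_overlap,
            threshold=config.placement_threshold)

    # locus verdicts
    rows = []
    for locus in discovery.loci:
        member_ids = [f"{m.seqid}:{m.start}-{m.end}" for m in locus.members
                      if m.source == SOURCE_TRANSLATED and m.type == "RVP"]
        verdicts = {mid: result.placements[mid].verdict
                    for mid in member_ids if mid in result.placements}
        if not verdicts:
            continue
        verdict, conflict, dissenters = placement.reconcile_locus(verdicts)
        curation.set_locus_classifications(locus, verdicts)
        rows.append({"locus_id": locus.locus_id, "verdict": verdict,
                     "conflict": conflict,
                     "dissenters": ",".join(dissenters)})
    result.locus_verdicts = pd.DataFrame(
        rows, columns=["locus_id", "verdict", "conflict", "dissenters"])

    # motif calls on the joint codon alignment, anchored on the references
    ref_ids = sorted(references)
    calls = motifs.extract_motifs(aligned, reference_ids=ref_ids)
    calls = [c for c in calls if c.seq_id in kept_queries]
    for call in calls:
        call.interrupted = motifs.flag_interruptions(aligned, call.seq_id)
        if call.interrupted == "none" and call.seq_id in mixed_frame:
            call.interrupted = "frameshift"
        if call.interrupted == "none":
            motifs.classify_activity(call)
    result.motif_calls = calls
    result.motif_table = motifs.tabulate_motifs(
        [c for c in calls if c.interrupted == "none"])
    return result
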