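"""Synthetic genomes, reference libraries and read sets with known truth.

Everything downstream is tested against data generated here: a host genome
with planted LTR-flanked proviruses carrying chosen protease motifs, a
clade-structured consensus library evolved along a known tree, and
condition-stratified read sets with planted per-locus abundances.  All
randomness flows from one :class:`numpy.random.Generator` seeded by the
configuration, so identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam
from skbio import TreeNode

from .errors import ConfigurationError, InputError, SimulationError
from .seqio import GffRecord

NT = "ACGT"
TRANSITIONS = {"A": "G", "G": "A", "C": "T", "T": "C"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

# Fixed ancestor proteins.  The protease is 106 residues with the active-site
# loop at residues 22-26 and the helix at residues 87-91 (1-based).
PR_B1_START = 21          # 0-based residue index of the 5-mer loop
PR_C2_START = 86
ANCESTOR_PR = (
    "WVPLTQLKQPISFIKPNQAGL"        # 0-20
    "DTGAD"                        # 21-25, replaced per element
    "ITVLNRKDFQVIGANGQTHTFGGIGGFINTKEYKNVEIEVLNKRVRATIMSAPLIAQNVQ"  # 26-85
    "GRDLL"                        # 86-90, replaced per element
    "GQLQPLISEYLNLEH"              # 91-105
)
ANCESTOR_RT = (
    "CGAKFFTWLLTLSSVKSDEAVYFLGSMNMSDFTIGYKRDEAAGGEVENKQ"
    "LIVSAVSVLGLGFDYEVLLAGTAGNGIVNLIGKKVFFGGGVTSFKVAGAV"
    "VGDHKDDVRQGDEHKFLDEPKGGVPEAENNASRIYQNRGVIYHDFSPPRI"
)
ANCESTOR_GAG = (
    "LFGQTSKENIVYGAPVVVFQLARSKAERFPAFVTQHNTWGVTDEYQLMPG"
    "QSSIAGAKHKKMTPENVHKEKKHNDGYELCTTTAQESERLISTCVLRPII"
)

assert len(ANCESTOR_PR) == 106

_CODONS_FOR: dict[str, list[str]] = {}


def _init_codon_choices() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        _CODONS_FOR.setdefault(aa, []).append(codon)
    for aa in _CODONS_FOR:
        _CODONS_FOR[aa].sort()


_init_codon_choices()


def default_queries() -> dict[str, str]:
    """Protein queries matching the planted ancestor (PR, RT core, Gag)."""
    return {"PR": ANCESTOR_PR, "RVT_1": ANCESTOR_RT, "GAG": ANCESTOR_GAG}


def encode_protein(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as nucleotides with random synonymous codons."""
    out = []
    for aa in protein:
        choices = _CODONS_FOR.get(aa)
        if not choices:
            raise InputError(f"cannot encode residue {aa!r}")
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def random_nt(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(NT))[rng.integers(0, 4, size=length)])


@dataclass
class SimulationConfig:
    genome_length: int = 2_000_000
    n_elements: int = 50
    ltr_length: int = 300
    element_span: tuple[int, int] = (6000, 9000)
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    stop_probability: float = 0.0
    frameshift_probability: float = 0.0
    solo_ltr_probability: float = 0.0
    motifs: Sequence[tuple[str, str]] = (("DTGAD", "GRDLL"),)
    clades: Sequence[str] = ("HML2",)
    target_id: str = "chr1"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate", "stop_probability",
                     "frameshift_probability", "solo_ltr_probability"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.element_span[0] > self.element_span[1]:
            raise ConfigurationError("element_span range inverted")
        if self.element_span[0] < 2 * self.ltr_length + 1200:
            raise ConfigurationError("element span too small for LTRs + ORFs")


@dataclass
class TruthRecord:
    element_id: str
    target_id: str
    start: int
    end: int
    clade: str
    b1: str
    c2: str
    status: str                     # intact | stop | frameshift | solo_ltr
    pr_interval: tuple[int, int] | None = None
    rt_interval: tuple[int, int] | None = None
    expression: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference library evolution
# ---------------------------------------------------------------------------

def _mutate_coding(seq: str, p_sub: float, rng: np.random.Generator,
                   protected: set[int] | None = None) -> str:
    """Per-site substitution with 2:1 transition bias, avoiding new stops.

    ``protected`` holds nt offsets that must not change.  Codon structure is
    assumed to start at offset 0.
    """
    if p_sub <= 0:
        return seq
    chars = list(seq)
    protected = protected or set()
    hits = np.flatnonzero(rng.random(len(chars)) < p_sub)
    for i in hits:
        if i in protected:
            continue
        old = chars[i]
        if old not in TRANSITIONS:
            continue
        # transition twice as likely as each transversion: weights 2,1,1
        u = rng.random()
        if u < 0.5:
            new = TRANSITIONS[old]
        else:
            others = [c for c in NT if c != old and c != TRANSITIONS[old]]
            new = others[0] if u < 0.75 else others[1]
        codon_start = (i // 3) * 3
        trial = chars[codon_start:codon_start + 3]
        trial[i - codon_start] = new
        if "".join(trial) in STOP_CODONS:
            continue   # keep ORF intact
        chars[i] = new
    return "".join(chars)


def make_reference_set(tree: TreeNode | str, ancestor_nt: str | None = None,
                       rng_seed: int = 0) -> dict[str, str]:
    """Evolve one sequence per labeled leaf along a branch-length tree.

    Substitution probability per site on a branch of length ``b`` is
    ``1 - exp(-b)``; stops are rejected so translations keep open frames.
    """
    if isinstance(tree, str):
        tree = TreeNode.read([tree])
    rng = np.random.default_rng(rng_seed)
    protected: set[int] = set()
    if ancestor_nt is None:
        ancestor_nt = encode_protein(ANCESTOR_PR + ANCESTOR_RT, rng)
        # active-site motifs are conserved across the reference library
        for res in range(PR_B1_START, PR_B1_START + 5):
            protected.update(range(3 * res, 3 * res + 3))
        for res in range(PR_C2_START, PR_C2_START + 5):
            protected.update(range(3 * res, 3 * res + 3))
    for tip in tree.tips():
        if not tip.name:
            raise ConfigurationError("reference tree has an unlabeled leaf")
    leaves: dict[str, str] = {}

    def descend(node: TreeNode, seq: str) -> None:
        for child in node.children:
            b = child.length or 0.0
            if b < 0:
                raise ConfigurationError("negative branch length")
            p_sub = 1.0 - math.exp(-b)
            mutated = _mutate_coding(seq, p_sub, rng, protected)
            if child.is_tip():
                leaves[child.name] = mutated
            else:
                descend(child, mutated)

    descend(tree, ancestor_nt)
    return leaves


# ---------------------------------------------------------------------------
# provirus planting
# ---------------------------------------------------------------------------

def _build_element(config: SimulationConfig, b1: str, c2: str, span: int,
                   rng: np.random.Generator,
                   clade_nt: str | None = None,
                   ) -> tuple[str, dict[str, tuple[int, int]], str]:
    """Assemble one provirus; returns (sequence, feature intervals, status).

    When ``clade_nt`` (a reference PR+RT coding sequence) is given the
    element descends from it, so downstream placement can recover the clade;
    otherwise PR and RT are re-encoded from the ancestor proteins.
    """
    ltr = random_nt(config.ltr_length, rng)
    gag_nt = encode_protein(ANCESTOR_GAG, rng)
    pr_len = 3 * len(ANCESTOR_PR)
    if clade_nt is not None:
        pr_nt = clade_nt[:pr_len]
        rt_nt = clade_nt[pr_len:pr_len + 3 * len(ANCESTOR_RT)]
    else:
        pr_nt = encode_protein(ANCESTOR_PR, rng)
        rt_nt = encode_protein(ANCESTOR_RT, rng)
    # overwrite the motif codons with the assigned motifs
    for start_res, motif in ((PR_B1_START, b1), (PR_C2_START, c2)):
        enc = encode_protein(motif, rng)
        pr_nt = (pr_nt[:3 * start_res] + enc
                 + pr_nt[3 * start_res + len(enc):])
    internal_len = span - 2 * config.ltr_length
    coding = gag_nt + pr_nt + rt_nt
    if internal_len < len(coding):
        raise SimulationError("element span cannot hold the coding region")
    filler = random_nt(internal_len - len(coding), rng)

    # substitution divergence, motif codons protected, PR ORF kept open
    protected = set()
    pr_off = len(gag_nt)
    for res in range(PR_B1_START, PR_B1_START + len(b1)):
        protected.update(range(pr_off + 3 * res, pr_off + 3 * res + 3))
    for res in range(PR_C2_START, PR_C2_START + len(c2)):
        protected.update(range(pr_off + 3 * res, pr_off + 3 * res + 3))
    coding = _mutate_coding(coding, config.substitution_rate, rng, protected)

    # independent injection draws: P(intact) = (1 - stop_p)(1 - fs_p)
    stop_draw = rng.random() < config.stop_probability
    fs_draw = rng.random() < config.frameshift_probability
    status = "stop" if stop_draw else ("frameshift" if fs_draw else "intact")
    pr_start = pr_off
    pr_nt_cur = coding[pr_start:pr_start + 3 * 106]
    if status == "stop":
        # replace one non-motif codon with TAA
        candidates = [i for i in range(5, 101)
                      if not (PR_B1_START <= i < PR_B1_START + len(b1))
                      and not (PR_C2_START <= i < PR_C2_START + len(c2))]
        codon = candidates[int(rng.integers(len(candidates)))]
        pr_nt_cur = (pr_nt_cur[:3 * codon] + "TAA" + pr_nt_cur[3 * codon + 3:])
    elif status == "frameshift":
        # delete one nucleotide mid-ORF, away from the motifs
        lo = 3 * (PR_B1_START + len(b1) + 3)
        hi = 3 * (PR_C2_START - 3)
        pos = int(rng.integers(lo, hi))
        pr_nt_cur = pr_nt_cur[:pos] + pr_nt_cur[pos + 1:]
    coding = coding[:pr_start] + pr_nt_cur + coding[pr_start + 3 * 106:]

    ltr5 = _mutate_coding(ltr, config.substitution_rate, rng)
    ltr3 = _mutate_coding(ltr, config.substitution_rate, rng)
    internal = coding + filler
    seq = ltr5 + internal + ltr3
    features = {
        "ltr5": (0, config.ltr_length),
        "gag": (config.ltr_length, config.ltr_length + len(gag_nt)),
        "pr": (config.ltr_length + pr_off,
               config.ltr_length + pr_off + len(pr_nt_cur)),
        "rt": (config.ltr_length + pr_off + len(pr_nt_cur),
               config.ltr_length + pr_off + len(pr_nt_cur) + len(rt_nt)),
        "ltr3": (len(seq) - config.ltr_length, len(seq)),
    }
    return seq, features, status


def plant_proviruses(config: SimulationConfig,
                     clade_references: Mapping[str, str] | None = None,
                     ) -> tuple[dict[str, str], list[TruthRecord],
                                list[GffRecord]]:
    """Plant LTR-flanked proviruses in an i.i.d. background genome.

    ``clade_references`` optionally maps clade labels to reference PR+RT
    coding sequences; elements then descend from their clade's reference.
    """
    rng = np.random.default_rng(config.rng_seed)
    genome = list(random_nt(config.genome_length, rng))
    placements: list[tuple[int, int]] = []
    truth: list[TruthRecord] = []
    gff: list[GffRecord] = []
    for idx in range(config.n_elements):
        b1, c2 = config.motifs[idx % len(config.motifs)]
        clade = config.clades[idx % len(config.clades)]
        solo = rng.random() < config.solo_ltr_probability
        if solo:
            seq = random_nt(config.ltr_length, rng)
            features = {"ltr5": (0, config.ltr_length)}
            status = "solo_ltr"
        else:
            span = int(rng.integers(config.element_span[0],
                                    config.element_span[1] + 1))
            clade_nt = (clade_references or {}).get(clade)
            seq, features, status = _build_element(config, b1, c2, span, rng,
                                                   clade_nt=clade_nt)
        placed = False
        for _ in range(1000):
            start = int(rng.integers(0, config.genome_length - len(seq)))
            end = start + len(seq)
            # keep elements >10 kb apart so each forms its own locus
            if all(end + 12000 <= s or start >= e + 12000
                   for s, e in placements):
                placed = True
                break
        if not placed:
            raise SimulationError("could not place element without overlap")
        placements.append((start, end))
        genome[start:end] = list(seq)
        element_id = f"element_{idx:03d}"
        rec = TruthRecord(
            element_id=element_id, target_id=config.target_id,
            start=start, end=end, clade=clade,
            b1="" if solo else b1, c2="" if solo else c2, status=status)
        attrs = {"ID": element_id, "clade": clade, "status": status,
                 "b1": rec.b1, "c2": rec.c2}
        gff.append(GffRecord(config.target_id, "synthetic", "ERV_element",
                             start, end, None, "+", ".", dict(attrs)))
        for kind, key in (("LTR", "ltr5"), ("GAG", "gag"), ("PR", "pr"),
                          ("RT", "rt"), ("LTR", "ltr3")):
            if key not in features:
                continue
            f0, f1 = features[key]
            gff.append(GffRecord(
                config.target_id, "synthetic", kind,
                start + f0, start + f1, None, "+", ".",
                {"ID": f"{element_id}_{key}", "Parent": element_id}))
            if key == "pr":
                rec.pr_interval = (start + f0, start + f1)
            if key == "rt":
                rec.rt_interval = (start + f0, start + f1)
        truth.append(rec)
    truth.sort(key=lambda r: r.start)
    gff.sort(key=lambda r: (r.start, r.end, r.type))
    return {config.target_id: "".join(genome)}, truth, gff


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class SampleDesign:
    sample_id: str
    condition: str
    library_size: int
    abundances: dict[str, float]    # locus/element id -> relative abundance
    pairing_key: str | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ConfigurationError("library size must be positive")
        if any(a < 0 for a in self.abundances.values()):
            raise ConfigurationError("abundances must be >= 0")


def simulate_reads(genome: Mapping[str, str],
                   loci: Sequence[tuple[str, str, int, int]],
                   design: Sequence[SampleDesign],
                   out_dir,
                   read_length: int = 75,
                   rng_seed: int = 0) -> "pd.DataFrame":
    """Error-free single-end reads per sample, written as sorted SAM files.

    Reads are drawn from loci with probability proportional to
    ``abundance x locus length`` and placed uniformly.  Returns the truth
    expression table (expected count and FPKM per locus per sample).
    """
    import os

    import pandas as pd

    rng = np.random.default_rng(rng_seed)
    os.makedirs(out_dir, exist_ok=True)
    locus_index = {locus_id: (target, start, end)
                   for locus_id, target, start, end in loci}
    rows = []
    for sample in design:
        ids = sorted(locus_index)
        weights = np.array([
            sample.abundances.get(lid, 0.0)
            * (locus_index[lid][2] - locus_index[lid][1]) for lid in ids])
        total = weights.sum()
        if total <= 0:
            raise SimulationError(
                f"zero total abundance for sample {sample.sample_id}")
        probs = weights / total
        counts = rng.multinomial(sample.library_size, probs)
        reads = []
        for lid, n_reads in zip(ids, counts):
            target, start, end = locus_index[lid]
            span = max(1, (end - start) - read_length)
            starts = start + rng.integers(0, span, size=n_reads)
            for k, s in enumerate(starts):
                seq = genome[target][s:s + read_length]
                reads.append((target, int(s), seq,
                              f"{sample.sample_id}:{lid}:{k}"))
            expected_fpkm = (n_reads / ((end - start) / 1000.0)
                             / (sample.library_size / 1e6))
            rows.append({"sample_id": sample.sample_id,
                         "condition": sample.condition,
                         "pairing_key": sample.pairing_key,
                         "sex": sample.sex,
                         "locus_id": lid,
                         "true_count": int(n_reads),
                         "true_fpkm": expected_fpkm,
                         "library_size": sample.library_size})
        reads.sort(key=lambda r: (r[0], r[1], r[3]))
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(seq)}
                   for name, seq in genome.items()],
        }
        path = os.path.join(out_dir, f"{sample.sample_id}.sam")
        with pysam.AlignmentFile(path, "wh", header=header) as sam:
            tid = {name: i for i, name in enumerate(genome)}
            for target, s, seq, name in reads:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = seq
                a.flag = 0
                a.reference_id = tid[target]
                a.reference_start = s
                a.mapping_quality = 60
                a.cigarstring = f"{len(seq)}M"
                sam.write(a)
    return pd.DataFrame(rows)
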