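"""Read annotation: V/J assignment by local alignment, junction extraction, clonotyping.

Each read is aligned against every germline V segment (read prefix by
default) and, downstream of the winning V block, against every J segment.
The junction is the read interval from the V anchor codon start through the
J anchor codon end (AIRR convention: C...F/W inclusive); a productive
annotation is in-frame, stop-free, and keeps both anchor residues.
Clonotypes are keyed by (V gene, J gene, junction nucleotide sequence).

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import _sw
from .germline import GermlineReference, GermlineSegment, translate

OK = "ok"
NO_V = "no_v"
NO_J = "no_j"
ANCHOR_MISSING = "anchor_missing"
UNPRODUCTIVE = "unproductive"


@dataclass(frozen=True)
class Scoring:
    """Affine-gap alignment scores; a length-L gap costs open + (L-1) * extend."""

    match: int = 2
    mismatch: int = -2
    gap_open: int = -4
    gap_extend: int = -1


@dataclass(frozen=True)
class AlignmentHit:
    segment_name: str
    score: int
    read_start: int
    read_end: int
    seg_start: int
    seg_end: int

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not (self.read_start < self.read_end and self.seg_start < self.seg_end):
            raise ValueError("alignment block must be non-empty")


@dataclass(frozen=True)
class Annotation:
    read_id: str
    v_call: str | None
    j_call: str | None
    junction_nt: str | None
    junction_aa: str | None
    productive: bool
    status: str


@dataclass(frozen=True)
class Clonotype:
    v_gene: str
    j_gene: str
    junction_nt: str
    junction_aa: str
    count: int
    frequency: float


@dataclass
class RepertoireSample:
    sample_id: str
    group: str | None
    clonotypes: list[Clonotype]
    total_reads: int
    annotated_reads: int
    productive_reads: int

    @property
    def n_unique_cdr3(self) -> int:
        return len({c.junction_nt for c in self.clonotypes})


@dataclass
class AnnotateParams:
    scoring: Scoring = field(default_factory=Scoring)
    min_score_v: int = 40  # a 20-bp exact match passes
    min_score_j: int = 30
    full_search: bool = False  # search V/J over the whole read instead of prefix/suffix
    v_prefix_margin: int = 12  # extra read bases past the longest V when prefix-searching


def smith_waterman(query: str, target: str, scoring: Scoring = Scoring()) -> AlignmentHit | None:
    """Optimal local alignment of ``query`` vs ``target``; None if best score is 0.

    ``read_*`` coordinates refer to the query, ``seg_*`` to the target.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    q = _sw.encode(query)
    t = _sw.encode(target)
    qmap = np.full(len(target), -1, dtype=np.int64)
    score, q0, q1, t0, t1 = _sw.sw_traceback(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, qmap
    )
    if score <= 0:
        return None
    return AlignmentHit(
        segment_name="", score=int(score), read_start=int(q0), read_end=int(q1), seg_start=int(t0), seg_end=int(t1)
    )


class _SegmentIndex:
    """Name-sorted, pre-encoded segments for repeated multi-alignment."""

    def __init__(self, segments: Sequence[GermlineSegment]):
        if not segments:
            raise ValueError("segments must be non-empty")
        self.segments = sorted(segments, key=lambda s: s.name)
        encoded = [_sw.encode(s.sequence) for s in self.segments]
        self.flat = np.concatenate(encoded)
        self.offsets = np.zeros(len(encoded) + 1, dtype=np.int64)
        self.offsets[1:] = np.cumsum([len(e) for e in encoded])
        self.max_len = max(len(e) for e in encoded)
        self._scores = np.zeros(len(encoded), dtype=np.int64)

    def best(self, read_enc: np.ndarray, scoring: Scoring) -> tuple[GermlineSegment, int] | None:
        _sw.sw_score_multi(
            read_enc,
            self.flat,
            self.offsets,
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
            self._scores,
        )
        k = int(np.argmax(self._scores))  # first max = smallest name on ties
        score = int(self._scores[k])
        if score <= 0:
            return None
        return self.segments[k], score


def assign_segment(
    read: str,
    segments: Sequence[GermlineSegment],
    scoring: Scoring = Scoring(),
    min_score: int = 40,
) -> AlignmentHit | None:
    """Best-scoring segment for ``read``; ties broken by smallest name; None below ``min_score``."""
    index = segments if isinstance(segments, _SegmentIndex) else _SegmentIndex(segments)
    read_enc = _sw.encode(read)
    found = index.best(read_enc, scoring)
    if found is None or found[1] < min_score:
        return None
    seg, _ = found
    hit = smith_waterman(read, seg.sequence, scoring)
    assert hit is not None
    return AlignmentHit(
        segment_name=seg.name,
        score=hit.score,
        read_start=hit.read_start,
        read_end=hit.read_end,
        seg_start=hit.seg_start,
        seg_end=hit.seg_end,
    )


def _anchor_on_read(read: str, seg: GermlineSegment, scoring: Scoring) -> tuple[int, AlignmentHit] | None:
    """Read position of the segment's anchor base on the optimal local alignment."""
    q = _sw.encode(read)
    t = _sw.encode(seg.sequence)
    qmap = np.full(len(seg.sequence), -1, dtype=np.int64)
    score, q0, q1, t0, t1 = _sw.sw_traceback(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, qmap
    )
    if score <= 0:
        return None
    hit = AlignmentHit(
        segment_name=seg.name, score=int(score), read_start=int(q0), read_end=int(q1), seg_start=int(t0), seg_end=int(t1)
    )
    pos = int(qmap[seg.anchor])
    if pos < 0:
        return -1, hit
    return pos, hit


def extract_junction(
    read: str,
    v_hit: AlignmentHit,
    j_hit: AlignmentHit,
    ref: GermlineReference,
    scoring: Scoring = Scoring(),
    read_id: str = "",
    j_offset: int = 0,
) -> Annotation:
    """Map the V and J anchors through their alignments and cut the junction.

    ``j_offset`` shifts ``j_hit`` read coordinates (used when J was aligned
    against a read suffix). A V block starting at/after the J block, or an
    anchor outside its aligned block, yields status ``anchor_missing``.
    """
    v_seg = ref.find(v_hit.segment_name)
    j_seg = ref.find(j_hit.segment_name)
    v_call, j_call = v_seg.gene, j_seg.gene
    if v_hit.read_start >= j_hit.read_start + j_offset:
        return Annotation(read_id, v_call, j_call, None, None, False, ANCHOR_MISSING)

    got_v = _anchor_on_read(read, v_seg, scoring)
    got_j = _anchor_on_read(read[j_offset:], j_seg, scoring)
    if got_v is None or got_j is None or got_v[0] < 0 or got_j[0] < 0:
        return Annotation(read_id, v_call, j_call, None, None, False, ANCHOR_MISSING)
    v_anchor_on_read = got_v[0]
    j_anchor_on_read = got_j[0] + j_offset
    end = j_anchor_on_read + 3
    if end > len(read) or v_anchor_on_read >= j_anchor_on_read:
        return Annotation(read_id, v_call, j_call, None, None, False, ANCHOR_MISSING)
    junction_nt = read[v_anchor_on_read:end]
    if len(junction_nt) % 3 != 0:
        return Annotation(read_id, v_call, j_call, junction_nt, None, False, UNPRODUCTIVE)
    junction_aa = translate(junction_nt)
    productive = (
        "*" not in junction_aa and junction_aa[0] == "C" and junction_aa[-1] in "FW"
    )
    status = OK if productive else UNPRODUCTIVE
    return Annotation(read_id, v_call, j_call, junction_nt, junction_aa, productive, status)


class Annotator:
    """Reusable annotator holding pre-encoded segment indexes for one reference."""

    def __init__(self, ref: GermlineReference, params: AnnotateParams | None = None):
        self.ref = ref
        self.params = params or AnnotateParams()
        self._v_index = _SegmentIndex(ref.v_segments)
        self._j_index = _SegmentIndex(ref.j_segments)

    def annotate_read(self, read: str, read_id: str = "") -> Annotation:
        p = self.params
        if not read:
            return Annotation(read_id, None, None, None, None, False, NO_V)
        v_region = read if p.full_search else read[: self._v_index.max_len + p.v_prefix_margin]
        try:
            v_enc = _sw.encode(v_region)
        except ValueError:
            return Annotation(read_id, None, None, None, None, False, NO_V)
        found_v = self._v_index.best(v_enc, p.scoring)
        if found_v is None or found_v[1] < p.min_score_v:
            return Annotation(read_id, None, None, None, None, False, NO_V)
        v_seg, _ = found_v
        got_v = _anchor_on_read(v_region, v_seg, p.scoring)
        assert got_v is not None
        v_pos, v_hit = got_v

        j_offset = 0 if p.full_search else v_hit.read_end
        j_region = read[j_offset:]
        if not j_region:
            return Annotation(read_id, v_seg.gene, None, None, None, False, NO_J)
        found_j = self._j_index.best(_sw.encode(j_region), p.scoring)
        if found_j is None or found_j[1] < p.min_score_j:
            return Annotation(read_id, v_seg.gene, None, None, None, False, NO_J)
        j_seg, _ = found_j
        got_j = _anchor_on_read(j_region, j_seg, p.scoring)
        assert got_j is not None
        j_pos, j_hit = got_j

        if v_pos < 0 or j_pos < 0:
            return Annotation(read_id, v_seg.gene, j_seg.gene, None, None, False, ANCHOR_MISSING)
        v_anchor_on_read = v_pos
        j_anchor_on_read = j_pos + j_offset
        end = j_anchor_on_read + 3
        if end > len(read) or v_anchor_on_read >= j_anchor_on_read:
            return Annotation(read_id, v_seg.gene, j_seg.gene, None, None, False, ANCHOR_MISSING)
        junction_nt = read[v_anchor_on_read:end]
        if len(junction_nt) % 3 != 0:
            return Annotation(read_id, v_seg.gene, j_seg.gene, junction_nt, None, False, UNPRODUCTIVE)
        junction_aa = translate(junction_nt)
        productive = "*" not in junction_aa and junction_aa[0] == "C" and junction_aa[-1] in "FW"
        return Annotation(
            read_id, v_seg.gene, j_seg.gene, junction_nt, junction_aa, productive,
            OK if productive else UNPRODUCTIVE,
        )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence); truncated records raise with the file named."""
    with _open_maybe_gzip(path) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title.split()[0], seq.upper()
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def annotate_reads(
    reads: Iterable[tuple[str, str]],
    ref: GermlineReference,
    params: AnnotateParams | None = None,
    sample_id: str = "sample",
    group: str | None = None,
) -> tuple[RepertoireSample, list[tuple[str, int, Annotation]]]:
    """Annotate (id, sequence) pairs and aggregate productive ones into clonotypes.

    Duplicate sequences are annotated once. Returns the repertoire plus a
    per-unique-sequence table of (sequence, duplicate_count, annotation).
    """
    annotator = Annotator(ref, params)
    counts: Counter[str] = Counter()
    first_id: dict[str, str] = {}
    total = 0
    for rid, seq in reads:
        total += 1
        counts[seq] += 1
        if seq not in first_id:
            first_id[seq] = rid
    unique_rows: list[tuple[str, int, Annotation]] = []
    tab: dict[tuple[str, str, str], tuple[int, str]] = {}
    annotated = 0
    productive_total = 0
    for seq in sorted(counts):  # deterministic, order-independent
        c = counts[seq]
        ann = annotator.annotate_read(seq, read_id=first_id[seq])
        unique_rows.append((seq, c, ann))
        if ann.status in (OK, UNPRODUCTIVE):
            annotated += c
        if ann.productive:
            assert ann.v_call and ann.j_call and ann.junction_nt and ann.junction_aa
            key = (ann.v_call, ann.j_call, ann.junction_nt)
            prev = tab.get(key)
            tab[key] = (c + (prev[0] if prev else 0), ann.junction_aa)
            productive_total += c
    clonotypes = [
        Clonotype(v, j, nt, aa, c, c / productive_total)
        for (v, j, nt), (c, aa) in sorted(tab.items())
    ]
    sample = RepertoireSample(
        sample_id=sample_id,
        group=group,
        clonotypes=clonotypes,
        total_reads=total,
        annotated_reads=annotated,
        productive_reads=productive_total,
    )
    return sample, unique_rows


def build_repertoire(
    fastq: str | Path,
    ref: GermlineReference,
    params: AnnotateParams | None = None,
    sample_id: str | None = None,
    group: str | None = None,
) -> RepertoireSample:
    """Annotate a FASTQ file into a repertoire sample.

    An empty file yields an empty repertoire with zero totals.
    """
    sid = sample_id or Path(fastq).stem.replace(".fastq", "")
    sample, _ = annotate_reads(read_fastq(fastq), ref, params, sample_id=sid, group=group)
    return sample


def write_airr(
    unique_rows: list[tuple[str, int, Annotation]], path: str | Path
) -> None:
    """AIRR Rearrangement TSV at unique-sequence level with duplicate_count."""
    cols = ["sequence_id", "sequence", "v_call", "j_call", "junction", "junction_aa", "productive", "duplicate_count"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for seq, c, ann in unique_rows:
            fh.write(
                "\t".join(
                    [
                        ann.read_id,
                        seq,
                        ann.v_call or "",
                        ann.j_call or "",
                        ann.junction_nt or "",
                        ann.junction_aa or "",
                        "T" if ann.productive else "F",
                        str(c),
                    ]
                )
                + "\n"
            )


def write_clonotypes(sample: RepertoireSample, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "junction_nt": c.junction_nt,
                "junction_aa": c.junction_aa,
                "count": c.count,
                "frequency": c.frequency,
            }
            for c in sample.clonotypes
        ]
    ).to_csv(path, index=False)


def read_clonotypes(path: str | Path, sample_id: str, group: str | None = None) -> RepertoireSample:
    import pandas as pd

    df = pd.read_csv(path)
    clonotypes = [
        Clonotype(r.v_gene, r.j_gene, r.junction_nt, r.junction_aa, int(r.count), float(r.frequency))
        for r in df.itertuples()
    ]
    total = int(df["count"].sum()) if len(df) else 0
    return RepertoireSample(sample_id, group, clonotypes, total, total, total)
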