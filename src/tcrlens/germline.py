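"""Germline V/J segment reference: model, FASTA I/O, and a synthetic mini-reference.

Coordinates are 0-based, half-open everywhere. Each segment carries an
``anchor``: the offset of the first base of its conserved codon (the
second-CYS for V segments, the J-PHE/J-TRP of the FGXG motif for J
segments). The junction extracted downstream runs from the V anchor through
the J anchor codon inclusive.

Two FASTA header dialects are supported:

* ``plain`` — ``>name|V|18``: name, segment type, explicit anchor offset.
* ``imgt`` — pipe-delimited headers with the allele name in the second
  field (e.g. ``>X57616|TRBV6-4*01|...``); anchors are auto-detected
  (V: last in-frame TGT/TGC codon; J: first codon starting a [FW]-G-X-G
  motif in any frame).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGT]+$")

STOP_CODONS = {"TAA", "TAG", "TGA"}
CYS_CODONS = {"TGT", "TGC"}
PHE_CODONS = {"TTT", "TTC"}
TRP_CODON = "TGG"
GLY_CODONS = {"GGT", "GGC", "GGA", "GGG"}


class GermlineParseError(ValueError):
    """Raised when a reference FASTA record cannot be parsed."""


def translate(nt: str) -> str:
    """Translate a DNA string (length divisible by 3) to one-letter amino acids."""
    return str(Seq(nt).translate())


def gene_label(name: str) -> str:
    """Collapse an allele name to its gene-level label (strip the ``*NN`` suffix)."""
    return name.split("*", 1)[0]


@dataclass(frozen=True)
class GermlineSegment:
    """One V or J reference allele with its anchor codon coordinate."""

    name: str
    segment_type: Literal["V", "J"]
    sequence: str
    anchor: int

    def __post_init__(self) -> None:
        if self.segment_type not in ("V", "J"):
            raise ValueError(f"{self.name}: segment_type must be 'V' or 'J'")
        if not self.sequence or not _DNA_RE.match(self.sequence):
            raise ValueError(f"{self.name}: sequence must be non-empty over ACGT")
        if not 0 <= self.anchor <= len(self.sequence) - 3:
            raise ValueError(
                f"{self.name}: anchor {self.anchor} out of range for length {len(self.sequence)}"
            )
        codon = self.anchor_codon
        if self.segment_type == "V" and codon not in CYS_CODONS:
            raise ValueError(f"{self.name}: V anchor codon {codon} does not encode C")
        if self.segment_type == "J" and not (codon in PHE_CODONS or codon == TRP_CODON):
            raise ValueError(f"{self.name}: J anchor codon {codon} does not encode F/W")

    @property
    def gene(self) -> str:
        return gene_label(self.name)

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.anchor : self.anchor + 3]


@dataclass
class GermlineReference:
    """A set of germline V and J segments (D records, if present, are kept as raw pairs)."""

    v_segments: list[GermlineSegment]
    j_segments: list[GermlineSegment]
    d_records: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.v_segments or not self.j_segments:
            raise ValueError("reference needs at least one V and one J segment")
        names = [s.name for s in self.v_segments + self.j_segments]
        if len(names) != len(set(names)):
            raise ValueError("duplicate segment names in reference")

    def find(self, name: str) -> GermlineSegment:
        for seg in self.v_segments + self.j_segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def by_gene(self, segment_type: str, gene: str) -> GermlineSegment:
        pool = self.v_segments if segment_type == "V" else self.j_segments
        for seg in pool:
            if seg.gene == gene:
                return seg
        raise KeyError(gene)


def detect_v_anchor(sequence: str) -> int | None:
    """Offset of the last in-frame TGT/TGC codon, or None."""
    best = None
    for off in range(0, len(sequence) - 2, 3):
        if sequence[off : off + 3] in CYS_CODONS:
            best = off
    return best


def detect_j_anchor(sequence: str) -> int | None:
    """Offset of the first codon beginning a [FW]-G-X-G motif in any frame, or None."""
    for off in range(len(sequence) - 11):
        c0 = sequence[off : off + 3]
        if not (c0 in PHE_CODONS or c0 == TRP_CODON):
            continue
        if sequence[off + 3 : off + 6] in GLY_CODONS and sequence[off + 9 : off + 12] in GLY_CODONS:
            return off
    return None


def _segment_type_from_allele(allele: str) -> str | None:
    m = re.search(r"TR[ABGD]?([VDJ])", allele)
    return m.group(1) if m else None


def read_reference(path: str | Path, dialect: str = "plain") -> GermlineReference:
    """Load a germline reference FASTA.

    ``plain`` headers are ``name|type|anchor`` triplets with explicit
    anchors; ``imgt`` headers are pipe-delimited with the allele name in
    field 2, anchors auto-detected. Records whose anchor cannot be located
    are rejected with a logged warning; malformed headers raise
    :class:`GermlineParseError`.
    """
    if dialect not in ("plain", "imgt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    v_segs: list[GermlineSegment] = []
    j_segs: list[GermlineSegment] = []
    d_recs: list[tuple[str, str]] = []
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.description
        sequence = str(record.seq).upper()
        if dialect == "plain":
            parts = header.split("|")
            if len(parts) != 3:
                raise GermlineParseError(f"malformed plain header {header!r}: expected name|type|anchor")
            name, seg_type, anchor_s = (p.strip() for p in parts)
            if seg_type == "D":
                d_recs.append((name, sequence))
                continue
            try:
                anchor = int(anchor_s)
            except ValueError as exc:
                raise GermlineParseError(f"record {name!r}: anchor {anchor_s!r} is not an integer") from exc
        else:
            parts = header.split("|")
            if len(parts) < 2 or not parts[1].strip():
                raise GermlineParseError(f"malformed imgt header {header!r}: no allele name in field 2")
            name = parts[1].strip()
            seg_type = _segment_type_from_allele(name)
            if seg_type is None:
                raise GermlineParseError(f"record {name!r}: cannot infer segment type from name")
            if seg_type == "D":
                d_recs.append((name, sequence))
                continue
            anchor_opt = detect_v_anchor(sequence) if seg_type == "V" else detect_j_anchor(sequence)
            if anchor_opt is None:
                logger.warning("segment %s rejected: no %s anchor located", name, seg_type)
                continue
            anchor = anchor_opt
        try:
            seg = GermlineSegment(name=name, segment_type=seg_type, sequence=sequence, anchor=anchor)
        except ValueError as exc:
            if dialect == "plain":
                raise GermlineParseError(str(exc)) from exc
            logger.warning("segment %s rejected: %s", name, exc)
            continue
        (v_segs if seg_type == "V" else j_segs).append(seg)
    return GermlineReference(v_segments=v_segs, j_segments=j_segs, d_records=d_recs)


def write_reference(ref: GermlineReference, path: str | Path) -> None:
    """Write a reference in the plain dialect (``name|type|anchor``), 60-char wrapped lines."""
    with open(path, "w") as fh:
        for seg in ref.v_segments + ref.j_segments:
            fh.write(f">{seg.name}|{seg.segment_type}|{seg.anchor}\n")
            for i in range(0, len(seg.sequence), 60):
                fh.write(seg.sequence[i : i + 60] + "\n")
        for name, sequence in ref.d_records:
            fh.write(f">{name}|D|-\n")
            for i in range(0, len(sequence), 60):
                fh.write(sequence[i : i + 60] + "\n")


# codons safe for synthetic segment bodies: no stop, no cysteine (so the declared
# V anchor stays the last in-frame TGT/TGC), no TTT/TTC/TGG (no spurious J anchors)
_SAFE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - STOP_CODONS
    - CYS_CODONS
    - PHE_CODONS
    - {TRP_CODON}
)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n))


def bundled_mini_reference(n_v: int = 20, n_j: int = 13, seed: int = 7) -> GermlineReference:
    """Deterministic synthetic reference for tests and demos.

    V segments ``TRBVs1..TRBVs{n_v}`` end with an in-frame TGT anchor codon
    followed by a short germline junction contribution; J segments
    ``TRBJs1..TRBJs{n_j}`` carry a TTT-G-G-X-G... region encoding the FGXG
    motif. Pure function of (n_v, n_j, seed).
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("n_v and n_j must be >= 1")
    rng = np.random.default_rng(seed)
    v_segs = []
    for i in range(1, n_v + 1):
        n_lead = int(rng.integers(11, 15))  # codons before the anchor
        n_tail = int(rng.integers(2, 4))  # codons of germline CDR3 contribution
        seq = _random_codons(rng, n_lead) + "TGT" + _random_codons(rng, n_tail)
        v_segs.append(
            GermlineSegment(name=f"TRBVs{i}*01", segment_type="V", sequence=seq, anchor=3 * n_lead)
        )
    j_segs = []
    for i in range(1, n_j + 1):
        n_pre = int(rng.integers(2, 4))  # codons ahead of the F anchor
        x = _SAFE_CODONS[int(rng.integers(0, len(_SAFE_CODONS)))]
        gly = ["GGT", "GGC", "GGA", "GGG"]
        g1 = gly[int(rng.integers(0, 4))]
        g2 = gly[int(rng.integers(0, 4))]
        tail = _random_codons(rng, int(rng.integers(5, 8)))
        seq = _random_codons(rng, n_pre) + "TTT" + g1 + x + g2 + tail
        j_segs.append(
            GermlineSegment(name=f"TRBJs{i}*01", segment_type="J", sequence=seq, anchor=3 * n_pre)
        )
    return GermlineReference(v_segments=v_segs, j_segments=j_segs)
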