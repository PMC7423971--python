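"""Per-sample repertoire descriptive statistics.

Covers the four-bin abundance partition, the D50 diversity index, CDR3
length / amino-acid composition / hydrophilicity summaries, and shared-CDR3
counting. Statistics are read-weighted by default (each read contributes
once); clone-weighted variants are available via ``weight="clone"``.

Frequencies in the abundance bins are expressed in PERCENT: a clonotype
with 1 read out of 200,000 has frequency 0.0005%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .annotate import Clonotype, RepertoireSample

# Hopp-Woods hydrophilicity values (positive = hydrophilic).
HOPP_WOODS: dict[str, float] = {
    "R": 3.0, "K": 3.0, "D": 3.0, "E": 3.0, "S": 0.3, "N": 0.2, "Q": 0.2,
    "G": 0.0, "P": 0.0, "T": -0.4, "A": -0.5, "H": -0.5, "C": -1.0,
    "M": -1.3, "V": -1.5, "I": -1.8, "L": -1.8, "Y": -2.3, "F": -2.5, "W": -3.4,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class AbundanceBins:
    """Read-share of four frequency/rank bins; shares sum to 1."""

    bin_rare: float  # frequency < 0.001 %
    bin_low: float  # 0.001 % <= frequency <= 0.005 %
    bin_mid: float  # frequency > 0.005 % and rank > 100
    bin_top100: float  # rank <= 100 by count (overrides frequency bins)

    def as_dict(self) -> dict[str, float]:
        return {
            "bin_rare": self.bin_rare,
            "bin_low": self.bin_low,
            "bin_mid": self.bin_mid,
            "bin_top100": self.bin_top100,
        }


@dataclass(frozen=True)
class DiversityReport:
    d50: float
    n_unique_cdr3: int
    basis: Literal["clonotype", "vj_combination"]


def d50(abundances: Iterable[float]) -> float:
    """Percentage of top-ranked entries whose cumulative abundance reaches 50%.

    Sort descending; the smallest k with cumulative sum >= half the total;
    returns 100 * k / n. Scale-invariant and tie-insensitive.
    """
    counts = np.asarray(list(abundances), dtype=float)
    if counts.size == 0 or (counts < 0).any() or counts.sum() <= 0:
        raise ValueError("need at least one positive abundance and no negatives")
    srt = np.sort(counts)[::-1]
    cum = np.cumsum(srt)
    k = int(np.searchsorted(cum, cum[-1] / 2.0)) + 1
    return 100.0 * k / counts.size


def vj_abundances(sample: RepertoireSample) -> dict[tuple[str, str], int]:
    """Read counts aggregated to gene-level V-J combinations."""
    agg: dict[tuple[str, str], int] = {}
    for c in sample.clonotypes:
        key = (c.v_gene, c.j_gene)
        agg[key] = agg.get(key, 0) + c.count
    return agg


def diversity(sample: RepertoireSample, basis: str = "vj_combination") -> DiversityReport:
    if basis == "vj_combination":
        counts = list(vj_abundances(sample).values())
    elif basis == "clonotype":
        counts = [c.count for c in sample.clonotypes]
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return DiversityReport(d50=d50(counts), n_unique_cdr3=sample.n_unique_cdr3, basis=basis)


def bin_abundances(sample: RepertoireSample, weight: str = "read") -> AbundanceBins:
    """Partition clonotypes into the four abundance bins and return bin shares.

    Rank is by count descending (ties by junction_nt); rank <= 100 wins over
    the frequency thresholds. ``weight="read"`` returns read-share per bin,
    ``weight="clone"`` the share of clonotypes.
    """
    if not sample.clonotypes:
        raise ValueError("empty clonotype table")
    if weight not in ("read", "clone"):
        raise ValueError(f"unknown weight {weight!r}")
    ranked = sorted(sample.clonotypes, key=lambda c: (-c.count, c.junction_nt))
    total = sum(c.count for c in ranked)
    shares = {"bin_rare": 0.0, "bin_low": 0.0, "bin_mid": 0.0, "bin_top100": 0.0}
    for rank, c in enumerate(ranked, start=1):
        pct = 100.0 * c.count / total
        if rank <= 100:
            b = "bin_top100"
        elif pct < 0.001:
            b = "bin_rare"
        elif pct <= 0.005:
            b = "bin_low"
        else:
            b = "bin_mid"
        shares[b] += c.count / total if weight == "read" else 1.0 / len(ranked)
    return AbundanceBins(**shares)


def _weights(sample: RepertoireSample, weight: str) -> list[tuple[Clonotype, float]]:
    if weight == "read":
        return [(c, float(c.count)) for c in sample.clonotypes]
    if weight == "clone":
        return [(c, 1.0) for c in sample.clonotypes]
    raise ValueError(f"unknown weight {weight!r}")


def cdr3_length_distribution(sample: RepertoireSample, weight: str = "read") -> pd.Series:
    """Distribution over junction amino-acid length; mass sums to 1."""
    acc: Counter[int] = Counter()
    tot = 0.0
    for c, w in _weights(sample, weight):
        acc[len(c.junction_aa)] += w
        tot += w
    if tot == 0:
        raise ValueError("empty clonotype table")
    return pd.Series({k: v / tot for k, v in sorted(acc.items())}, name="mass")


def aa_composition(sample: RepertoireSample, weight: str = "read") -> pd.Series:
    """Weighted residue frequencies across junction_aa; sums to 1."""
    acc: Counter[str] = Counter()
    tot = 0.0
    for c, w in _weights(sample, weight):
        for aa in c.junction_aa:
            acc[aa] += w
            tot += w
    if tot == 0:
        raise ValueError("empty clonotype table")
    return pd.Series({aa: acc.get(aa, 0.0) / tot for aa in AMINO_ACIDS}, name="frequency")


@dataclass(frozen=True)
class HydrophilicitySummary:
    mean: float
    hydrophilic_fraction: float  # mass of residues with scale value > 0


def hydrophilicity_profile(
    sample: RepertoireSample,
    scale: dict[str, float] | None = None,
    weight: str = "read",
) -> HydrophilicitySummary:
    """Weighted mean hydrophilicity of junction residues under a residue->value scale.

    The bundled default is the Hopp-Woods table. Residues missing from the
    scale raise ``KeyError``.
    """
    table = HOPP_WOODS if scale is None else scale
    num = 0.0
    pos = 0.0
    tot = 0.0
    for c, w in _weights(sample, weight):
        for aa in c.junction_aa:
            if aa not in table:
                raise KeyError(f"residue {aa!r} missing from hydrophilicity scale")
            v = table[aa]
            num += w * v
            if v > 0:
                pos += w
            tot += w
    if tot == 0:
        raise ValueError("empty clonotype table")
    return HydrophilicitySummary(mean=num / tot, hydrophilic_fraction=pos / tot)


def shared_cdr3(
    a: RepertoireSample, b: RepertoireSample, key: str = "nt"
) -> tuple[int, list[str]]:
    """Count and list junctions present in both samples (symmetric)."""
    if key == "nt":
        sa = {c.junction_nt for c in a.clonotypes}
        sb = {c.junction_nt for c in b.clonotypes}
    elif key == "aa":
        sa = {c.junction_aa for c in a.clonotypes}
        sb = {c.junction_aa for c in b.clonotypes}
    else:
        raise ValueError(f"unknown key {key!r}")
    common = sorted(sa & sb)
    return len(common), common


def sample_summary(sample: RepertoireSample) -> dict:
    """One-row summary used by the cohort-level stats CSV."""
    bins = bin_abundances(sample)
    hydro = hydrophilicity_profile(sample)
    lengths = cdr3_length_distribution(sample)
    mean_len = float(sum(k * v for k, v in lengths.items()))
    return {
        "sample_id": sample.sample_id,
        "group": sample.group,
        "total_reads": sample.total_reads,
        "annotated_reads": sample.annotated_reads,
        "productive_reads": sample.productive_reads,
        "n_clonotypes": len(sample.clonotypes),
        "n_unique_cdr3": sample.n_unique_cdr3,
        "d50_clonotype": d50([c.count for c in sample.clonotypes]),
        "d50_vj": d50(list(vj_abundances(sample).values())),
        **bins.as_dict(),
        "mean_cdr3_length": mean_len,
        "mean_hydrophilicity": hydro.mean,
        "hydrophilic_fraction": hydro.hydrophilic_fraction,
    }
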