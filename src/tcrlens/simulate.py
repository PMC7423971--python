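"""Synthetic case/control TCR-beta repertoire cohorts with ground truth.

The generator produces, per sample, a clone table (V/J assignment, junction,
true frequency), a read table (read id -> clone id) and plain 4-line FASTQ.
Case samples receive a multiplicative mass boost on their top clones
(clonal expansion, lowering expected D50); group-exclusive V-J combinations
can be spiked into a chosen number of samples of one group only.

Randomness: the global seed expands into one cohort-level stream (spike
sample selection) plus one stream per sample via
``numpy.random.SeedSequence(seed).spawn(...)`` (a splitmix64-based
derivation), so cohorts are reproducible sample-by-sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .germline import (
    STOP_CODONS,
    GermlineReference,
    GermlineSegment,
    translate,
)

CASE = "case"
CONTROL = "control"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_QUAL = "I"  # constant Phred 40; the pipeline does not use qualities


@dataclass(frozen=True)
class SpikedCombination:
    """A V-J combination forced into ``n_positive_samples`` of one group only."""

    v_gene: str
    j_gene: str
    group: Literal["case", "control"]
    n_positive_samples: int
    frequency: float

    def __post_init__(self) -> None:
        if self.group not in (CASE, CONTROL):
            raise ValueError(f"group must be {CASE!r} or {CONTROL!r}")
        if self.n_positive_samples < 1:
            raise ValueError("n_positive_samples must be >= 1")
        if not 0 < self.frequency < 1:
            raise ValueError("spiked frequency must be in (0, 1)")


@dataclass
class CohortSpec:
    """Simulator parameters; serializes to/from JSON."""

    n_cases: int = 10
    n_controls: int = 10
    clones_per_sample: int = 300
    reads_per_sample: int = 20000
    abundance_alpha: float = 1.2
    expansion_boost: float = 3.0
    expansion_top_k: int = 20
    spiked_combinations: list[SpikedCombination] = field(default_factory=list)
    error_rate: float = 0.0
    trim_max: int = 6
    insert_max: int = 9
    jitter_concentration: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "clones_per_sample", "reads_per_sample", "expansion_top_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.abundance_alpha < 0:
            raise ValueError("abundance_alpha must be >= 0")
        if self.expansion_boost < 1:
            raise ValueError("expansion_boost must be >= 1")
        if self.trim_max < 0 or self.insert_max < 0:
            raise ValueError("trim_max and insert_max must be >= 0")
        self.spiked_combinations = [
            s if isinstance(s, SpikedCombination) else SpikedCombination(**s)
            for s in self.spiked_combinations
        ]
        for s in self.spiked_combinations:
            size = self.n_cases if s.group == CASE else self.n_controls
            if s.n_positive_samples > size:
                raise ValueError(
                    f"spike {s.v_gene}/{s.j_gene}: n_positive_samples {s.n_positive_samples} "
                    f"exceeds {s.group} group size {size}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        return cls(**json.loads(text))


def recombine(v: GermlineSegment, j: GermlineSegment, trim_v: int, trim_j: int, n_insert: str) -> str:
    """V(D)J-style join: 3' V trim, untemplated insert, 5' J trim.

    The anchor codons are always retained; trims that would cut into one
    raise ``ValueError``.
    """
    if trim_v < 0 or trim_j < 0:
        raise ValueError("trims must be >= 0")
    if trim_v > len(v.sequence) - (v.anchor + 3):
        raise ValueError(f"trim_v={trim_v} would delete the V anchor codon of {v.name}")
    if trim_j > j.anchor:
        raise ValueError(f"trim_j={trim_j} would delete the J anchor codon of {j.name}")
    return v.sequence[: len(v.sequence) - trim_v] + n_insert + j.sequence[trim_j:]


def sample_abundances(
    n_clones: int,
    alpha: float,
    rng: np.random.Generator,
    jitter_concentration: float = 0.0,
) -> np.ndarray:
    """Power-law clone frequencies: rank^(-alpha) normalized, optionally Dirichlet-jittered.

    ``jitter_concentration`` c > 0 draws Dirichlet(base * c), whose mean is
    the power-law base; c = 0 returns the base exactly.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    ranks = np.arange(1, n_clones + 1, dtype=float)
    base = ranks ** (-alpha)
    base /= base.sum()
    if jitter_concentration > 0:
        freqs = rng.dirichlet(base * jitter_concentration)
        freqs = np.maximum(freqs, 1e-12)
        freqs /= freqs.sum()
        return freqs
    return base


def _junction(v: GermlineSegment, j: GermlineSegment, trim_v: int, trim_j: int, insert: str) -> str:
    return v.sequence[v.anchor : len(v.sequence) - trim_v] + insert + j.sequence[trim_j : j.anchor + 3]


def _productive(junction_nt: str) -> bool:
    if len(junction_nt) % 3 != 0:
        return False
    aa = translate(junction_nt)
    return "*" not in aa


def _draw_clone(
    v: GermlineSegment,
    j: GermlineSegment,
    rng: np.random.Generator,
    trim_max: int,
    insert_max: int,
    max_tries: int = 200,
) -> tuple[str, str, int, int, str]:
    """Draw trims/insert until the junction is in-frame and stop-free."""
    v_slack = min(trim_max, len(v.sequence) - (v.anchor + 3))
    j_slack = min(trim_max, j.anchor)
    for _ in range(max_tries):
        trim_v = int(rng.integers(0, v_slack + 1))
        trim_j = int(rng.integers(0, j_slack + 1))
        n_ins = int(rng.integers(0, insert_max + 1))
        insert = "".join("ACGT"[b] for b in rng.integers(0, 4, n_ins))
        # pad the insert to restore frame, capped at insert_max + 2
        jx = _junction(v, j, trim_v, trim_j, insert)
        pad = (-len(jx)) % 3
        if pad:
            insert += "".join("ACGT"[b] for b in rng.integers(0, 4, pad))
            jx = _junction(v, j, trim_v, trim_j, insert)
        if _productive(jx):
            seq = recombine(v, j, trim_v, trim_j, insert)
            return seq, jx, trim_v, trim_j, insert
    raise RuntimeError(f"could not draw a productive junction for {v.name}/{j.name}")


@dataclass
class SimulatedSample:
    sample_id: str
    group: str
    clones: pd.DataFrame  # clone_id, v_gene, j_gene, junction_nt, sequence, frequency
    reads: pd.DataFrame  # read_id, clone_id
    sequences: list[str]  # read sequences, parallel to ``reads``


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    metadata: pd.DataFrame  # sample_id, group
    samples: list[SimulatedSample]


def _sample_clone_table(
    spec: CohortSpec,
    ref: GermlineReference,
    sample_id: str,
    group: str,
    spikes: list[SpikedCombination],
    reserved: set[tuple[str, str]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = spec.clones_per_sample
    v_pool, j_pool = ref.v_segments, ref.j_segments
    rows = []
    for k in range(n):
        for _ in range(1000):
            v = v_pool[int(rng.integers(0, len(v_pool)))]
            j = j_pool[int(rng.integers(0, len(j_pool)))]
            if (v.gene, j.gene) not in reserved:
                break
        else:  # pragma: no cover - only if reserved covers the whole grid
            raise RuntimeError("V-J grid exhausted by spiked combinations")
        seq, jx, *_ = _draw_clone(v, j, rng, spec.trim_max, spec.insert_max)
        rows.append((f"{sample_id}.c{k:04d}", v.gene, j.gene, jx, seq))
    freqs = sample_abundances(n, spec.abundance_alpha, rng, spec.jitter_concentration)
    order = np.argsort(freqs)[::-1]
    freqs = freqs[order]
    if group == CASE and spec.expansion_boost > 1:
        k = min(spec.expansion_top_k, n)
        freqs = freqs.copy()
        freqs[:k] *= spec.expansion_boost
        freqs /= freqs.sum()
    df = pd.DataFrame(rows, columns=["clone_id", "v_gene", "j_gene", "junction_nt", "sequence"])
    df["frequency"] = freqs
    spike_mass = sum(s.frequency for s in spikes)
    if spike_mass >= 1:
        raise ValueError("spiked frequencies sum to >= 1")
    if spikes:
        df["frequency"] *= 1 - spike_mass
        spike_rows = []
        for m, s in enumerate(spikes):
            v = ref.by_gene("V", s.v_gene)
            j = ref.by_gene("J", s.j_gene)
            seq, jx, *_ = _draw_clone(v, j, rng, spec.trim_max, spec.insert_max)
            spike_rows.append((f"{sample_id}.s{m:02d}", v.gene, j.gene, jx, seq, s.frequency))
        df = pd.concat(
            [df, pd.DataFrame(spike_rows, columns=list(df.columns))],
            ignore_index=True,
        )
    assert abs(df["frequency"].sum() - 1.0) < 1e-9
    return df


def _mutate_reads(seqs: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. per-base substitutions to a (n_reads, length) base-index array."""
    if error_rate <= 0:
        return seqs
    mask = rng.random(seqs.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        shifts = rng.integers(1, 4, n_err)
        seqs = seqs.copy()
        seqs[mask] = (seqs[mask] + shifts) % 4
    return seqs


def _simulate_sample_reads(
    spec: CohortSpec, clones: pd.DataFrame, sample_id: str, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[str]]:
    counts = rng.multinomial(spec.reads_per_sample, clones["frequency"].to_numpy())
    if spec.spiked_combinations:
        spiked = clones["clone_id"].str.contains(r"\.s\d+$", regex=True)
        missed = spiked & (counts == 0)
        if missed.any():
            warnings.warn(
                f"{sample_id}: {int(missed.sum())} spiked clone(s) received zero reads "
                "(frequency x reads too small)",
                stacklevel=2,
            )
    read_clone: list[str] = []
    chunks: list[np.ndarray] = []
    seq_lens: list[int] = []
    for clone_id, seq, c in zip(clones["clone_id"], clones["sequence"], counts):
        if c == 0:
            continue
        base = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        idx = np.searchsorted(_BASES, base)  # ACGT are sorted, so this is an exact map
        tiled = np.tile(idx, (c, 1))
        tiled = _mutate_reads(tiled, spec.error_rate, rng)
        chunks.append(tiled)
        seq_lens.append(len(seq))
        read_clone.extend([clone_id] * c)
    order = rng.permutation(len(read_clone))
    sequences: list[str] = []
    flat_seqs: list[str] = []
    for tiled in chunks:
        chars = _BASES[tiled]
        flat_seqs.extend(chars[i].tobytes().decode("ascii") for i in range(chars.shape[0]))
    read_clone_arr = np.asarray(read_clone, dtype=object)[order]
    sequences = [flat_seqs[i] for i in order]
    reads = pd.DataFrame(
        {
            "read_id": [f"{sample_id}.r{i:06d}" for i in range(len(sequences))],
            "clone_id": read_clone_arr,
        }
    )
    return reads, sequences


def simulate_truth(spec: CohortSpec, ref: GermlineReference) -> tuple[pd.DataFrame, list[tuple[str, str, pd.DataFrame]]]:
    """Clone tables only (no reads): metadata plus per-sample truth. Fast path."""
    n = spec.n_cases + spec.n_controls
    root = np.random.SeedSequence(spec.seed)
    cohort_ss, *sample_ss = root.spawn(n + 1)
    cohort_rng = np.random.default_rng(cohort_ss)

    sample_ids = [f"case{i+1:02d}" for i in range(spec.n_cases)] + [
        f"ctrl{i+1:02d}" for i in range(spec.n_controls)
    ]
    groups = [CASE] * spec.n_cases + [CONTROL] * spec.n_controls

    reserved = {(s.v_gene, s.j_gene) for s in spec.spiked_combinations}
    for v_gene, j_gene in reserved:
        ref.by_gene("V", v_gene)  # raises KeyError if absent
        ref.by_gene("J", j_gene)
    spikes_by_sample: dict[str, list[SpikedCombination]] = {sid: [] for sid in sample_ids}
    for s in spec.spiked_combinations:
        pool = [sid for sid, g in zip(sample_ids, groups) if g == s.group]
        chosen = cohort_rng.choice(len(pool), size=s.n_positive_samples, replace=False)
        for i in sorted(chosen):
            spikes_by_sample[pool[i]].append(s)
        if s.frequency * spec.reads_per_sample < 1:
            warnings.warn(
                f"spike {s.v_gene}/{s.j_gene}: frequency x reads_per_sample < 1; "
                "may not appear in sampled reads",
                stacklevel=2,
            )

    out = []
    for sid, group, ss in zip(sample_ids, groups, sample_ss):
        rng = np.random.default_rng(ss)
        clones = _sample_clone_table(spec, ref, sid, group, spikes_by_sample[sid], reserved, rng)
        out.append((sid, group, clones))
    metadata = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    return metadata, out


def simulate_cohort(
    spec: CohortSpec, ref: GermlineReference, outdir: str | Path | None = None
) -> SimulatedCohort:
    """Full simulation: clone tables, reads, and (optionally) files on disk.

    With ``outdir`` set, writes one FASTQ per sample, ``metadata.csv``,
    ``truth_clones.tsv``, ``truth_reads.tsv`` and ``spec.json``.
    """
    n = spec.n_cases + spec.n_controls
    metadata, truths = simulate_truth(spec, ref)
    # independent read-stage streams, derived from the same root
    read_ss = np.random.SeedSequence(spec.seed).spawn(2 * n + 1)[n + 1 :]
    samples = []
    for (sid, group, clones), ss in zip(truths, read_ss):
        rng = np.random.default_rng(ss)
        reads, sequences = _simulate_sample_reads(spec, clones, sid, rng)
        samples.append(SimulatedSample(sid, group, clones, reads, sequences))
    cohort = SimulatedCohort(spec=spec, metadata=metadata, samples=samples)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sample in cohort.samples:
        fq = outdir / f"{sample.sample_id}.fastq"
        with open(fq, "w") as fh:
            for rid, seq in zip(sample.reads["read_id"], sample.sequences):
                fh.write(f"@{rid}\n{seq}\n+\n{_QUAL * len(seq)}\n")
        paths[sample.sample_id] = fq
    cohort.metadata.to_csv(outdir / "metadata.csv", index=False)
    pd.concat(
        [s.clones.assign(sample_id=s.sample_id) for s in cohort.samples], ignore_index=True
    ).to_csv(outdir / "truth_clones.tsv", sep="\t", index=False)
    pd.concat(
        [s.reads.assign(sample_id=s.sample_id) for s in cohort.samples], ignore_index=True
    ).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    (outdir / "spec.json").write_text(cohort.spec.to_json() + "\n")
    return paths


def _repertoire_from_clone_counts(clones: pd.DataFrame, counts, sample_id: str, group: str):
    """Collapse per-clone read counts into a RepertoireSample keyed by
    (v_gene, j_gene, junction_nt)."""
    from .annotate import Clonotype, RepertoireSample

    tab: dict[tuple[str, str, str], int] = {}
    for v, j, nt, c in zip(clones["v_gene"], clones["j_gene"], clones["junction_nt"], counts):
        if c == 0:
            continue
        key = (v, j, nt)
        tab[key] = tab.get(key, 0) + int(c)
    total = int(sum(tab.values()))
    clonotypes = [
        Clonotype(v, j, nt, translate(nt), c, c / total)
        for (v, j, nt), c in sorted(tab.items())
    ]
    return RepertoireSample(sample_id, group, clonotypes, total, total, total)


def repertoire_from_frequencies(
    clones: pd.DataFrame,
    n_reads: int,
    rng: np.random.Generator,
    sample_id: str = "sample",
    group: str | None = None,
):
    """Multinomial read sampling straight from a truth clone table.

    A fast path for statistics and calibration studies: skips read-sequence
    generation and alignment entirely (equivalent to the full pipeline at
    error_rate = 0, which maps every read back to its clone).
    """
    counts = rng.multinomial(n_reads, clones["frequency"].to_numpy())
    return _repertoire_from_clone_counts(clones, counts, sample_id, group)


def repertoire_from_truth(sample: SimulatedSample):
    """Build a RepertoireSample directly from ground truth (bypasses alignment).

    Clonotype counts are the realized read counts per clone, collapsed by
    (v_gene, j_gene, junction_nt). All simulated clones are productive by
    construction.
    """
    counts = (
        sample.reads["clone_id"]
        .value_counts()
        .reindex(sample.clones["clone_id"], fill_value=0)
        .to_numpy()
    )
    return _repertoire_from_clone_counts(sample.clones, counts, sample.sample_id, sample.group)
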