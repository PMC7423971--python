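"""Group-level V-J usage comparison.

Builds the samples x V-J-combination matrix (reads of each gene-level
combination per million productive reads of the sample), detects
group-exclusive ("asymmetric") combinations, and provides the univariate
tests, PCA ordination and PERMANOVA used to compare groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .annotate import RepertoireSample
from .repstats import vj_abundances

PER_MILLION = 1_000_000.0


@dataclass
class VJMatrix:
    """Samples x V-J combinations, values in reads-per-million; rows sum to 1e6."""

    values: pd.DataFrame  # index: sample_id, columns: "TRBVx|TRBJy"
    groups: pd.Series  # index: sample_id -> group label

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def group_mask(self, group: str) -> np.ndarray:
        return (self.groups == group).to_numpy()

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "VJMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        df.index.name = None
        groups = df.pop("group")
        return cls(values=df, groups=groups)


def combination_label(v_gene: str, j_gene: str) -> str:
    return f"{v_gene}|{j_gene}"


def build_vj_matrix(samples: Sequence[RepertoireSample]) -> VJMatrix:
    """Normalized V-J abundance matrix; columns lexicographic, all-zero columns dropped."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    rows = {}
    for s in samples:
        total = sum(c.count for c in s.clonotypes)
        if total == 0:
            raise ValueError(f"sample {s.sample_id} has no productive reads")
        rows[s.sample_id] = {
            combination_label(v, j): PER_MILLION * n / total
            for (v, j), n in vj_abundances(s).items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    df = df.reindex(sorted(df.columns), axis=1)
    df = df.loc[ids]
    groups = pd.Series({s.sample_id: s.group for s in samples})
    return VJMatrix(values=df, groups=groups.loc[ids])


@dataclass(frozen=True)
class AsymmetricHit:
    v_gene: str
    j_gene: str
    direction: Literal["case_only", "control_only"]
    n_positive_case: int
    n_positive_control: int
    mean_norm: float  # over positive samples only
    sd_norm: float  # ddof=1 over positive samples; 0 when a single positive


def detect_asymmetric(
    m: VJMatrix,
    min_positive: int = 3,
    positivity_threshold: float = 0.0,
    case_label: str = "case",
    control_label: str = "control",
) -> list[AsymmetricHit]:
    """Combinations positive (> threshold) in >= min_positive samples of one
    group and in zero samples of the other."""
    case_rows = m.values.loc[m.group_mask(case_label)]
    ctrl_rows = m.values.loc[m.group_mask(control_label)]
    if case_rows.empty or ctrl_rows.empty:
        raise ValueError("both groups must be present")
    hits: list[AsymmetricHit] = []
    for col in m.values.columns:
        v_gene, j_gene = col.split("|", 1)
        pos_case = case_rows[col] > positivity_threshold
        pos_ctrl = ctrl_rows[col] > positivity_threshold
        n_case, n_ctrl = int(pos_case.sum()), int(pos_ctrl.sum())
        if n_case >= min_positive and n_ctrl == 0:
            direction, vals = "case_only", case_rows.loc[pos_case, col]
        elif n_ctrl >= min_positive and n_case == 0:
            direction, vals = "control_only", ctrl_rows.loc[pos_ctrl, col]
        else:
            continue
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        hits.append(
            AsymmetricHit(
                v_gene=v_gene,
                j_gene=j_gene,
                direction=direction,
                n_positive_case=n_case,
                n_positive_control=n_ctrl,
                mean_norm=float(vals.mean()),
                sd_norm=sd,
            )
        )
    return hits


def asymmetric_hits_frame(hits: list[AsymmetricHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "v_gene": h.v_gene,
                "j_gene": h.j_gene,
                "direction": h.direction,
                "n_positive_case": h.n_positive_case,
                "n_positive_control": h.n_positive_control,
                "mean_norm": h.mean_norm,
                "sd_norm": h.sd_norm,
            }
            for h in hits
        ],
        columns=[
            "v_gene", "j_gene", "direction", "n_positive_case",
            "n_positive_control", "mean_norm", "sd_norm",
        ],
    )


def group_t_test(values_case: Sequence[float], values_control: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t, two-sided p."""
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if np.array_equal(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def counting_chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table (no continuity correction by default)."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be a non-negative 2x2 count table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PC1..PCk
    explained_variance_ratio: np.ndarray


def pca_ordination(m: VJMatrix, n_components: int = 2) -> PcaResult:
    """Scores of the column-centered matrix on its top principal axes.

    Sign convention: for each axis the loading with the largest magnitude is
    made positive. Explained-variance fractions are relative to the total
    variance, so they are non-increasing and sum to <= 1.
    """
    x = m.values.to_numpy(dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 columns")
    centered = x - x.mean(axis=0, keepdims=True)
    if not centered.any():
        raise ValueError("matrix is constant across samples")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_components, len(s))
    total_var = float((s**2).sum())
    for i in range(k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
            u[:, i] = -u[:, i]
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=pd.DataFrame(
            scores, index=m.values.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        explained_variance_ratio=(s[:k] ** 2) / total_var,
    )


def _pseudo_f(sq_dist: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared-distance matrix and integer labels."""
    n = sq_dist.shape[0]
    groups = np.unique(labels)
    a = len(groups)
    ss_total = sq_dist[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = sq_dist[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom == 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / (a - 1)) / denom


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str


def permanova(
    m: VJMatrix,
    distance: str = "bray_curtis",
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Two-group PERMANOVA on the V-J matrix.

    ``exhaustive=True`` enumerates every distinct assignment of group sizes
    to samples (p = #{F >= F_obs} / n_assignments, identity included);
    otherwise ``n_perm`` seeded label permutations give
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    metric = {"bray_curtis": "braycurtis", "euclidean": "euclidean"}.get(distance)
    if metric is None:
        raise ValueError(f"unknown distance {distance!r}")
    labels, uniques = pd.factorize(m.groups)
    if len(uniques) != 2 or min(np.bincount(labels)) < 2:
        raise ValueError("need two groups with >= 2 samples each")
    x = m.values.to_numpy(dtype=float)
    d = squareform(pdist(x, metric=metric))
    if not d.any():
        warnings.warn("all distances are zero; PERMANOVA p reported as 1", stacklevel=2)
        return PermanovaResult(pseudo_f=0.0, p_value=1.0, n_permutations=0, method="degenerate")
    sq = d**2
    f_obs = _pseudo_f(sq, labels)
    n = len(labels)
    if exhaustive:
        n1 = int((labels == 0).sum())
        ge = 0
        count = 0
        for idx in combinations(range(n), n1):
            perm = np.ones(n, dtype=int)
            perm[list(idx)] = 0
            count += 1
            if _pseudo_f(sq, perm) >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(
            pseudo_f=float(f_obs), p_value=ge / count, n_permutations=count, method="exhaustive"
        )
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _pseudo_f(sq, perm) >= f_obs - 1e-12:
            ge += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p_value=(1 + ge) / (1 + n_perm),
        n_permutations=n_perm,
        method="permutation",
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * n / (rank + 1))
        adj[i] = running
    return adj


def per_combination_t_tests(m: VJMatrix, case_label: str = "case", control_label: str = "control") -> pd.DataFrame:
    """Welch t per combination with raw and BH-adjusted p-values."""
    case_rows = m.values.loc[m.group_mask(case_label)]
    ctrl_rows = m.values.loc[m.group_mask(control_label)]
    recs = []
    for col in m.values.columns:
        t, p = group_t_test(case_rows[col].to_numpy(), ctrl_rows[col].to_numpy())
        recs.append({"combination": col, "t": t, "p": p})
    df = pd.DataFrame(recs)
    df["p_bh"] = benjamini_hochberg(df["p"].to_numpy())
    return df
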