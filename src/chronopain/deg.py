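"""Multi-stage differential-expression cascade for a gene x sample count
matrix with a 2x2 treatment (SAFit2 vs vehicle) x timing (early vs late)
design and per-sample behavioral covariates.

Stages, in order:

1. library-size normalization to log2 counts-per-million (CPM) with a
   small prior;
2. low-expression prefilter;
3. overall treatment model: per-gene OLS ``log2CPM ~ treatment + timing``
   with a two-sided t test on the treatment coefficient (nominal p), plus
   a linear-scale 1.2-fold-change cutoff;
4. nested late contrast: Welch t on late-timing samples only, with
   Benjamini-Hochberg FDR and the same fold cutoff;
5. phenotype-correlation filter: keep genes whose expression correlates
   with the mechanical threshold (Bonferroni over the tested set) but not
   with the guarding index (nominal);
6. exact set algebra over the named DEG sets;
7. early-vs-late delta ranking: genes whose SAFit2-minus-vehicle shift is
   larger in magnitude under early than late treatment.

The log2FC sign convention is SAFit2 minus vehicle everywhere. The fold
cutoff is interpreted on the linear scale (|log2FC| > log2 1.2) by
default; ``fc_scale="log2"`` switches to a cutoff directly on log2FC.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SampleInfo",
    "ContrastResult",
    "DEGSets",
    "log2cpm",
    "filter_low_expression",
    "overall_treatment_degs",
    "nested_late_contrast",
    "phenotype_correlation_filter",
    "set_algebra",
    "early_late_delta_ranking",
    "pca_scores",
]

TREATMENTS = ("SAFit2", "vehicle")
TIMINGS = ("early", "late")


@dataclass
class SampleInfo:
    """Per-sample design labels and phenotype covariates.

    ``table`` must be indexed by sample id with columns ``treatment``
    (SAFit2/vehicle), ``timing`` (early/late), ``threshold_log_g`` (mean
    log10 mechanical threshold near dissection) and ``guarding_index``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"treatment", "timing", "threshold_log_g", "guarding_index"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sample info missing columns: {sorted(missing)}")
        bad_t = set(df["treatment"]) - set(TREATMENTS)
        bad_g = set(df["timing"]) - set(TIMINGS)
        if bad_t or bad_g:
            raise ValueError(f"unknown labels: {bad_t | bad_g}")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        cov = df[["threshold_log_g", "guarding_index"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariates must be finite")
        self.table = df

    def subset(self, sample_ids: Sequence[str]) -> "SampleInfo":
        return SampleInfo(self.table.loc[list(sample_ids)])


@dataclass(frozen=True)
class ContrastResult:
    """Per-gene effect sizes and significance for one contrast."""

    stats: pd.DataFrame  # index gene; columns log2fc, p, q (q may be NaN)
    name: str

    def gene_set(
        self,
        alpha: float,
        on: Literal["p", "q"],
        fc_cut: float | None = None,
        fc_scale: Literal["linear", "log2"] = "linear",
    ) -> set[str]:
        df = self.stats
        keep = df[on] < alpha
        if fc_cut is not None:
            lim = np.log2(fc_cut) if fc_scale == "linear" else fc_cut
            keep &= df["log2fc"].abs() > lim
        return set(df.index[keep])


@dataclass
class DEGSets:
    """Named gene sets and their exact algebra."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def add(self, name: str, genes: Iterable[str]) -> None:
        self.sets[name] = set(genes)

    def cardinalities(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}


def _as_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return counts


def log2cpm(counts: pd.DataFrame, prior: float = 0.5) -> pd.DataFrame:
    """log2(CPM + prior) with CPM = count / library size * 1e6.

    Library size is the column sum; zero-library samples are dropped with a
    warning naming them.
    """
    counts = _as_matrix(counts)
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        warnings.warn(f"dropping zero-library samples: {zero}")
        counts = counts.drop(columns=zero)
        lib = lib.drop(zero)
    cpm = counts.div(lib, axis=1) * 1e6
    return np.log2(cpm + prior)


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_frac_samples: float = 0.5
) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in >= min_frac_samples of samples
    (both bounds inclusive); row order is preserved."""
    counts = _as_matrix(counts)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero library size")
    cpm = counts.div(lib, axis=1) * 1e6
    frac = (cpm >= min_cpm).mean(axis=1)
    kept = counts.loc[frac >= min_frac_samples]
    if kept.empty:
        raise ValueError("all genes removed by expression filter")
    return kept


def _check_design(info: SampleInfo) -> None:
    tab = pd.crosstab(info.table["treatment"], info.table["timing"])
    if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
        raise ValueError(
            "confounded design: need both treatments in both timings; "
            f"got cell counts\n{tab}"
        )


def overall_treatment_degs(
    logcpm: pd.DataFrame,
    info: SampleInfo,
    alpha_nominal: float = 0.05,
    fc_cut: float = 1.2,
    fc_scale: Literal["linear", "log2"] = "linear",
) -> tuple[ContrastResult, set[str]]:
    """Main treatment effect: per-gene OLS of log2CPM on treatment + timing.

    Returns the full per-gene table (log2fc = treatment coefficient,
    SAFit2 minus vehicle; two-sided t p-value; BH q for reference) and the
    DEG set at nominal p < alpha with the fold cutoff applied.
    """
    samples = list(logcpm.columns)
    meta = info.table.loc[samples]
    _check_design(info.subset(samples))
    y = logcpm.to_numpy(dtype=float)  # genes x samples
    treat = (meta["treatment"] == "SAFit2").to_numpy(dtype=float)
    late = (meta["timing"] == "late").to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(treat), treat, late])
    n, k = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x k
    resid = y - beta @ x.T
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=1) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, beta[:, 1] / se, np.inf * np.sign(beta[:, 1]))
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"log2fc": beta[:, 1], "p": p, "q": q}, index=logcpm.index
    )
    res = ContrastResult(df, name="overall_treatment")
    degs = res.gene_set(alpha_nominal, on="p", fc_cut=fc_cut, fc_scale=fc_scale)
    return res, degs


def up_down_split(
    result: ContrastResult, genes: set[str]
) -> tuple[set[str], set[str]]:
    """Split a DEG set into up- and down-regulated (SAFit2 vs vehicle)."""
    fc = result.stats.loc[sorted(genes), "log2fc"]
    return set(fc.index[fc > 0]), set(fc.index[fc < 0])


def nested_late_contrast(
    logcpm: pd.DataFrame,
    info: SampleInfo,
    alpha_fdr: float = 0.05,
    fc_cut: float = 1.2,
    fc_scale: Literal["linear", "log2"] = "linear",
) -> tuple[ContrastResult, set[str]]:
    """Late-timing-only contrast: per-gene Welch t, BH FDR, fold cutoff."""
    meta = info.table.loc[list(logcpm.columns)]
    late = meta.index[meta["timing"] == "late"]
    g_treat = late[meta.loc[late, "treatment"] == "SAFit2"]
    g_veh = late[meta.loc[late, "treatment"] == "vehicle"]
    if len(g_treat) < 2 or len(g_veh) < 2:
        raise ValueError("need >= 2 samples in each late group")
    a = logcpm[g_treat].to_numpy(dtype=float)
    b = logcpm[g_veh].to_numpy(dtype=float)
    tval, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame(
        {"log2fc": a.mean(axis=1) - b.mean(axis=1), "p": p, "q": q},
        index=logcpm.index,
    )
    res = ContrastResult(df, name="late_nested")
    degs = res.gene_set(alpha_fdr, on="q", fc_cut=fc_cut, fc_scale=fc_scale)
    return res, degs


def _pearson_p(x: np.ndarray, y2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of x against each row of y2d."""
    n = x.size
    xc = x - x.mean()
    yc = y2d - y2d.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc @ xc) / (sy * sx)
    r = np.clip(r, -1.0, 1.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = r * np.sqrt(dof / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(tval), dof)
    p = np.where(np.isnan(p), 1.0, p)
    return r, p


def phenotype_correlation_filter(
    logcpm: pd.DataFrame,
    info: SampleInfo,
    genes: set[str],
    alpha: float = 0.05,
) -> set[str]:
    """Keep genes correlated with the mechanical threshold but not with
    the guarding index.

    Threshold correlation is Bonferroni-corrected over the tested set
    (p < alpha / |genes|); the guarding exclusion is nominal (p >= alpha).
    """
    missing = genes - set(logcpm.index)
    if missing:
        raise ValueError(f"genes absent from matrix: {sorted(missing)[:5]}...")
    if not genes:
        return set()
    meta = info.table.loc[list(logcpm.columns)]
    thr = meta["threshold_log_g"].to_numpy(dtype=float)
    guard = meta["guarding_index"].to_numpy(dtype=float)
    for name, cov in (("threshold_log_g", thr), ("guarding_index", guard)):
        if np.std(cov) == 0:
            raise ValueError(f"constant covariate {name}: correlation undefined")
    order = sorted(genes)
    y = logcpm.loc[order].to_numpy(dtype=float)
    _, p_thr = _pearson_p(thr, y)
    _, p_guard = _pearson_p(guard, y)
    bonf = alpha / len(order)
    keep = (p_thr < bonf) & (p_guard >= alpha)
    return {g for g, k in zip(order, keep) if k}


_TOKEN = re.compile(r"\s*([A-Za-z_][\w]*|[()|&-])")


def set_algebra(sets: DEGSets, expr: str) -> set[str]:
    """Evaluate a set expression over named gene sets.

    Supports union ``|``, intersection ``&``, difference ``-`` (all
    left-associative, equal precedence) and parentheses, e.g.
    ``"(overall - late) & corr"``.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise ValueError(f"bad set expression near {expr[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()

    def parse(i: int) -> tuple[set[str], int]:
        acc, i = parse_atom(i)
        while i < len(tokens) and tokens[i] in "|&-":
            op = tokens[i]
            rhs, i = parse_atom(i + 1)
            acc = acc | rhs if op == "|" else acc & rhs if op == "&" else acc - rhs
        return acc, i

    def parse_atom(i: int) -> tuple[set[str], int]:
        if i >= len(tokens):
            raise ValueError("truncated set expression")
        tok = tokens[i]
        if tok == "(":
            inner, i = parse(i + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise ValueError("unbalanced parentheses")
            return inner, i + 1
        if tok in "|&-)":
            raise ValueError(f"unexpected token {tok!r}")
        if tok not in sets.sets:
            raise KeyError(f"unknown set name {tok!r}")
        return set(sets.sets[tok]), i + 1

    result, i = parse(0)
    if i != len(tokens):
        raise ValueError("trailing tokens in set expression")
    return result


def early_late_delta_ranking(
    logcpm: pd.DataFrame,
    info: SampleInfo,
    candidate_genes: set[str],
) -> pd.DataFrame:
    """Rank candidates by excess early-treatment modulation.

    For each gene, delta_early = mean(early, SAFit2) - mean(early, vehicle)
    and delta_late likewise; genes with |delta_early| > |delta_late| are
    selected and ranked by |delta_early| - |delta_late| descending, ties
    broken by gene id.
    """
    meta = info.table.loc[list(logcpm.columns)]
    _check_design(info.subset(list(logcpm.columns)))
    if not candidate_genes:
        warnings.warn("empty candidate set for delta ranking")
        return pd.DataFrame(
            columns=["delta_early", "delta_late", "excess"]
        ).rename_axis("gene")
    order = sorted(candidate_genes & set(logcpm.index))
    y = logcpm.loc[order]

    def cell(timing: str, treatment: str) -> np.ndarray:
        ids = meta.index[(meta["timing"] == timing) & (meta["treatment"] == treatment)]
        return y[ids].to_numpy(dtype=float).mean(axis=1)

    d_early = cell("early", "SAFit2") - cell("early", "vehicle")
    d_late = cell("late", "SAFit2") - cell("late", "vehicle")
    df = pd.DataFrame(
        {"delta_early": d_early, "delta_late": d_late,
         "excess": np.abs(d_early) - np.abs(d_late)},
        index=pd.Index(order, name="gene"),
    )
    df = df[df["excess"] > 0]
    return df.sort_values(
        ["excess", "gene"], ascending=[False, True], kind="mergesort"
    )


def pca_scores(logcpm: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the top principal components of gene-standardized
    log2CPM (reporting utility)."""
    y = logcpm.to_numpy(dtype=float)
    y = y - y.mean(axis=1, keepdims=True)
    sd = y.std(axis=1, keepdims=True)
    y = np.divide(y, sd, out=np.zeros_like(y), where=sd > 0)
    u, s, vt = np.linalg.svd(y, full_matrices=False)
    scores = (vt[:n_components].T * s[:n_components])
    return pd.DataFrame(
        scores,
        index=logcpm.columns,
        columns=[f"PC{i+1}" for i in range(scores.shape[1])],
    )
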