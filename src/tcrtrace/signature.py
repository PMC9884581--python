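"""Differential expression and the weighted memory-precursor signature score.

Differential expression uses a two-sided Wilcoxon rank-sum test on
log-normalized expression with Bonferroni correction (a deliberately
assumption-light surrogate for hurdle-model testing; externally computed DE
tables with ``lfc``/``p_adj`` columns can be substituted anywhere a DE table
is accepted). The memory signature is the set of genes upregulated in memory
versus effector precursors at BOTH timepoints (log₂ fold change above a
threshold, mitochondrial/ribosomal symbols excluded), each weighted by the
antilog of its average pre/post LFC. Cells receive per-gene z-scores against
the global log-mean expression, and a clonotype's score is the weighted sum
of its member cells' average z-scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, wilcoxon

from .clonotypes import Clonotype
from .dynamics import DynamicsRecord
from .io import ExpressionMatrix

DEFAULT_EXCLUSION_PREFIXES = ("MT-", "RPL", "RPS")
LFC_EPS = 1e-9


@dataclass
class GeneSignature:
    """Ordered gene list with positive per-gene weights."""

    genes: list[str]
    weights: np.ndarray
    provenance: str = "derived"  # "derived" | "random" | "external"
    antilog_base: float = 2.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != len(self.weights):
            raise ValueError("genes and weights must have equal length")
        if (self.weights <= 0).any():
            raise ValueError("signature weights must be positive")


@dataclass(frozen=True)
class ScoreRecord:
    key: str
    score_pre: float | None
    score_post: float | None
    delta: float | None
    n_cells_pre: int
    n_cells_post: int


class TimecourseResult(NamedTuple):
    records: list[ScoreRecord]
    fraction_increasing: float
    signed_rank_p: float


def rank_sum_de(
    expr: ExpressionMatrix,
    group1: Sequence[str],
    group2: Sequence[str],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene rank-sum differential expression of group1 over group2.

    Returns a gene-indexed table with ``lfc`` (log₂ ratio of de-logged
    means, pseudocount 1e-9), two-sided ``p``, Bonferroni ``p_adj`` and the
    expressing-cell fractions per group. Genes with zero expression in both
    groups are skipped (and not counted in the correction).
    """
    if expr.lognorm is None:
        raise ValueError("expression matrix must be normalized first")
    s1, s2 = set(group1), set(group2)
    overlap = s1 & s2
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} barcodes, e.g. {sorted(overlap)[:3]}")
    if len(s1) < min_cells or len(s2) < min_cells:
        raise ValueError(f"each group needs ≥ {min_cells} cells (got {len(s1)}, {len(s2)})")
    idx1 = expr.cell_indexer(list(group1))
    idx2 = expr.cell_indexer(list(group2))
    x1 = np.asarray(expr.lognorm[:, idx1].todense())
    x2 = np.asarray(expr.lognorm[:, idx2].todense())
    tested = (x1.sum(axis=1) > 0) | (x2.sum(axis=1) > 0)
    x1, x2 = x1[tested], x2[tested]
    genes = expr.genes[tested]
    m = int(tested.sum())
    if m == 0:
        raise ValueError("no gene expressed in either group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = mannwhitneyu(x1, x2, axis=1, alternative="two-sided", method="asymptotic")
    p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    mean1 = np.expm1(x1).mean(axis=1)
    mean2 = np.expm1(x2).mean(axis=1)
    lfc = np.log2((mean1 + LFC_EPS) / (mean2 + LFC_EPS))
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p": p,
            "p_adj": np.minimum(1.0, p * m),
            "pct_expr_1": (x1 > 0).mean(axis=1),
            "pct_expr_2": (x2 > 0).mean(axis=1),
        },
        index=pd.Index(genes, name="gene"),
    )


def derive_signature(
    de_pre: pd.DataFrame,
    de_post: pd.DataFrame,
    lfc_min: float = 0.25,
    exclusion_prefixes: Sequence[str] = DEFAULT_EXCLUSION_PREFIXES,
    antilog_base: float = 2.0,
    p_adj_max: float | None = 0.05,
) -> GeneSignature:
    """Dual-timepoint memory-precursor signature from two DE tables
    (memory group as group1 in both).

    A gene is retained when its LFC strictly exceeds ``lfc_min`` at both
    timepoints, it is significant at both timepoints (``p_adj < p_adj_max``;
    pass ``None`` to disable), and its symbol does not start with an
    exclusion prefix (mitochondrial/ribosomal by default). Each retained
    gene's weight is ``antilog_base ** ((lfc_pre + lfc_post) / 2)``. Genes
    are ordered by descending weight.
    """
    common = de_pre.index.intersection(de_post.index)
    pre = de_pre.loc[common]
    post = de_post.loc[common]
    keep = (pre["lfc"] > lfc_min) & (post["lfc"] > lfc_min)
    if p_adj_max is not None:
        keep &= (pre["p_adj"] < p_adj_max) & (post["p_adj"] < p_adj_max)
    excl = pd.Series(
        [any(str(g).startswith(pfx) for pfx in exclusion_prefixes) for g in common],
        index=common,
    )
    keep &= ~excl
    genes = common[keep]
    if len(genes) == 0:
        raise ValueError(
            "no gene passes the dual-timepoint criteria; review lfc_min/p_adj_max "
            "thresholds or the group definitions"
        )
    avg_lfc = (pre.loc[genes, "lfc"] + post.loc[genes, "lfc"]) / 2.0
    weights = np.power(antilog_base, avg_lfc.to_numpy())
    order = np.argsort(-weights, kind="stable")
    return GeneSignature(
        genes=[str(g) for g in genes[order]],
        weights=weights[order],
        provenance="derived",
        antilog_base=antilog_base,
    )


def gene_zscores(expr: ExpressionMatrix, genes: Sequence[str]) -> pd.DataFrame:
    """Per-cell z-scores of log-normalized expression against the global
    (all-cells) mean and population standard deviation of each gene.

    Genes with zero variance get z ≡ 0.
    """
    if expr.lognorm is None:
        raise ValueError("expression matrix must be normalized first")
    try:
        idx = expr.gene_indexer(list(genes))
    except KeyError as exc:
        raise KeyError(f"signature gene missing from matrix: {exc}") from exc
    x = np.asarray(expr.lognorm[idx].todense(), dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, index=pd.Index(list(genes), name="gene"), columns=expr.barcodes)


def clonotype_score(
    barcodes: Sequence[str], z: pd.DataFrame, sig: GeneSignature
) -> float:
    """Weighted sum over signature genes of the mean member-cell z-score."""
    cols = [b for b in barcodes if b in z.columns]
    if not cols:
        raise ValueError("no member cell present in the z-score matrix")
    missing = [g for g in sig.genes if g not in z.index]
    if missing:
        raise KeyError(f"signature genes missing from z matrix: {missing[:5]}")
    mean_z = z.loc[sig.genes, cols].mean(axis=1).to_numpy()
    return float(np.dot(sig.weights, mean_z))


def score_timecourse(
    clonotypes: Sequence[Clonotype],
    records: Sequence[DynamicsRecord],
    z_pre: pd.DataFrame,
    z_post: pd.DataFrame,
    sig: GeneSignature,
    min_cells: int = 2,
    drop_viral: bool = False,
) -> TimecourseResult:
    """Pre/post memory-signature scores per clonotype.

    Restricted to clonotypes with ≥ ``min_cells`` scoreable blood cells in
    total. ``fraction_increasing`` is the fraction of clonotypes with both
    scores whose delta is strictly positive; a paired Wilcoxon signed-rank
    p-value over the (pre, post) score pairs is reported alongside. With
    ``drop_viral``, clonotypes flagged viral in ``records`` are excluded.
    """
    viral_keys = {r.key for r in records if r.viral} if drop_viral else set()
    pre_cols = set(z_pre.columns)
    post_cols = set(z_post.columns)
    out: list[ScoreRecord] = []
    for ct in clonotypes:
        if ct.key in viral_keys:
            continue
        pre_bcs = [
            b
            for (pat, tp, comp), bcs in ct.members.items()
            if tp == "pre" and comp == "blood"
            for b in bcs
            if b in pre_cols
        ]
        post_bcs = [
            b
            for (pat, tp, comp), bcs in ct.members.items()
            if tp == "post" and comp == "blood"
            for b in bcs
            if b in post_cols
        ]
        if len(pre_bcs) + len(post_bcs) < min_cells:
            continue
        score_pre = clonotype_score(pre_bcs, z_pre, sig) if pre_bcs else None
        score_post = clonotype_score(post_bcs, z_post, sig) if post_bcs else None
        delta = (score_post - score_pre) if (score_pre is not None and score_post is not None) else None
        out.append(
            ScoreRecord(
                key=ct.key,
                score_pre=score_pre,
                score_post=score_post,
                delta=delta,
                n_cells_pre=len(pre_bcs),
                n_cells_post=len(post_bcs),
            )
        )
    if not out:
        raise ValueError("no scoreable clonotype (check min_cells and the z matrices)")
    deltas = np.array([r.delta for r in out if r.delta is not None])
    if deltas.size:
        fraction_increasing = float((deltas > 0).mean())
        try:
            signed_rank_p = float(wilcoxon(deltas).pvalue)
        except ValueError:  # all deltas zero
            signed_rank_p = 1.0
    else:
        fraction_increasing = float("nan")
        signed_rank_p = float("nan")
    return TimecourseResult(out, fraction_increasing, signed_rank_p)


def random_signature(expr: ExpressionMatrix, n_genes: int, seed: int) -> GeneSignature:
    """Uniform sample (without replacement) of detected genes, unit weights.

    The control signature used to verify the absence of a timepoint batch
    effect.
    """
    detected = expr.genes[np.asarray(expr.counts.sum(axis=1)).ravel() > 0]
    if n_genes > len(detected):
        raise ValueError(f"requested {n_genes} genes but only {len(detected)} detected")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(detected, size=n_genes, replace=False)
    return GeneSignature(
        genes=[str(g) for g in chosen],
        weights=np.ones(n_genes),
        provenance="random",
    )


def signature_set_expression(
    expr: ExpressionMatrix, barcodes: Sequence[str], genes: Sequence[str]
) -> pd.Series:
    """Per-cell total log-normalized expression over a gene set."""
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if expr.lognorm is None:
        raise ValueError("expression matrix must be normalized first")
    gidx = expr.gene_indexer(list(genes))
    cidx = expr.cell_indexer(list(barcodes))
    totals = np.asarray(expr.lognorm[gidx][:, cidx].sum(axis=0)).ravel()
    return pd.Series(totals, index=list(barcodes), name="signature_total")


# ---------------------------------------------------------------------------
# signature file format: '#'-prefixed metadata header, then gene<TAB>weight
# ---------------------------------------------------------------------------

def write_signature(sig: GeneSignature, path: str | Path) -> None:
    lines = [
        f"# provenance={sig.provenance}",
        f"# antilog_base={sig.antilog_base!r}",
        "gene\tweight",
    ]
    lines += [f"{g}\t{float(w)!r}" for g, w in zip(sig.genes, sig.weights)]
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


def read_signature(path: str | Path) -> GeneSignature:
    provenance, base = "external", 2.0
    genes: list[str] = []
    weights: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            if k.strip() == "provenance":
                provenance = v.strip()
            elif k.strip() == "antilog_base":
                base = float(v)
            continue
        if not line or line.startswith("gene\t"):
            continue
        g, w = line.split("\t")
        genes.append(g)
        weights.append(float(w))
    return GeneSignature(genes=genes, weights=np.array(weights),
                         provenance=provenance, antilog_base=base)


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t")


def score_table(records: Sequence[ScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def write_score_table(records: Sequence[ScoreRecord], path: str | Path) -> None:
    score_table(records).to_csv(path, sep="\t", index=False)
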