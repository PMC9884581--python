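"""Longitudinal clonotype classification, cluster flux and group comparison.

A clonotype is *treatment-expanded* when it has at least 2 cells in the
post-treatment blood sample and a strictly higher within-sample frequency
post than pre. Treatment-expanded clonotypes split by *origin*: ``novel``
(undetected pre-treatment; "clonal replacement") versus ``pre_existing``.
The comparator group of clonotypes that were expanded at baseline but did
not expand further is flagged ``baseline_expanded_static``.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .clonotypes import Clonotype, MatchResult, clonotypes_by_key, match_clonotypes

FLUX_MODES = ("incidence", "modal")
NE_DENOMINATORS = ("post_clonotypes", "expanded_clonotypes")


@dataclass
class DynamicsRecord:
    """Per-clonotype longitudinal classification within one patient."""

    key: str
    patient: str
    pre_count: int
    post_count: int
    pre_freq: float
    post_freq: float
    treatment_expanded: bool
    origin: str  # "novel" | "pre_existing"
    baseline_expanded_static: bool
    tumor_matched: bool = False
    viral: bool = False


def classify_dynamics(
    pre: Sequence[Clonotype],
    post: Sequence[Clonotype],
    patient: str,
    min_expanded_cells: int = 2,
    freq_mode: str = "proportion",
) -> list[DynamicsRecord]:
    """Classify the union of clonotypes observed in a patient's pre/post
    blood samples.

    Pre/post identity uses :func:`match_clonotypes`, so the single-chain
    fallback applies: a clonotype is *novel* only if no pre-treatment
    clonotype matches it under the fallback rule. ``freq_mode`` selects the
    expansion comparison: ``"proportion"`` (within-sample frequency, default)
    or ``"count"`` (raw cell counts).
    """
    if freq_mode not in ("proportion", "count"):
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    pre_f = [(c, c.size_in(patient, "pre", "blood")) for c in pre]
    pre_f = [(c, n) for c, n in pre_f if n > 0]
    post_f = [(c, n) for c, n in ((c, c.size_in(patient, "post", "blood")) for c in post) if n > 0]
    pre_total = sum(n for _, n in pre_f)
    post_total = sum(n for _, n in post_f)
    if pre_total == 0 or post_total == 0:
        raise ValueError(
            f"patient {patient!r}: zero-cell blood sample "
            f"(pre={pre_total}, post={post_total})"
        )
    pre_size = {c.key: n for c, n in pre_f}
    if pre_f and post_f:
        mr = match_clonotypes([c for c, _ in post_f], [c for c, _ in pre_f])
        post_to_pre = mr.a_to_b()
        matched_pre = mr.matched_b_keys()
    else:
        post_to_pre, matched_pre = {}, set()

    records: list[DynamicsRecord] = []
    for c, n_post in post_f:
        pre_keys = post_to_pre.get(c.key, set())
        n_pre = sum(pre_size[k] for k in pre_keys)
        pre_freq = n_pre / pre_total
        post_freq = n_post / post_total
        grew = post_freq > pre_freq if freq_mode == "proportion" else n_post > n_pre
        expanded = n_post >= min_expanded_cells and grew
        records.append(
            DynamicsRecord(
                key=c.key,
                patient=patient,
                pre_count=n_pre,
                post_count=n_post,
                pre_freq=pre_freq,
                post_freq=post_freq,
                treatment_expanded=expanded,
                origin="novel" if n_pre == 0 else "pre_existing",
                baseline_expanded_static=n_pre >= 2 and not expanded,
            )
        )
    for c, n_pre in pre_f:
        if c.key in matched_pre:
            continue  # already accounted through a matching post clonotype
        records.append(
            DynamicsRecord(
                key=c.key,
                patient=patient,
                pre_count=n_pre,
                post_count=0,
                pre_freq=n_pre / pre_total,
                post_freq=0.0,
                treatment_expanded=False,
                origin="pre_existing",
                baseline_expanded_static=n_pre >= 2,
            )
        )
    return sorted(records, key=lambda r: r.key)


def flux_table(
    records: Sequence[DynamicsRecord],
    clonotypes: Sequence[Clonotype] | Mapping[str, Clonotype],
    clusters: Mapping[str, str],
    mode: str = "incidence",
) -> pd.DataFrame:
    """Pre-cluster × post-cluster clonotype incidence matrix.

    Restricted to treatment-expanded clonotypes with at least one
    pre-treatment cell. ``incidence`` mode adds +1 to (c1, c2) whenever the
    clonotype has ≥1 pre cell in c1 and ≥1 post cell in c2; ``modal`` mode
    adds +1 only at the (modal pre cluster, modal post cluster), ties broken
    lexicographically.
    """
    if mode not in FLUX_MODES:
        raise ValueError(f"unknown flux mode {mode!r}")
    by_key = clonotypes if isinstance(clonotypes, Mapping) else clonotypes_by_key(clonotypes)
    counts: Counter[tuple[str, str]] = Counter()
    labels_pre: set[str] = set()
    labels_post: set[str] = set()

    def _cluster(bc: str) -> str:
        if bc not in clusters or clusters[bc] is None:
            raise ValueError(f"missing cluster label for cell {bc!r}")
        return clusters[bc]

    for rec in records:
        if not (rec.treatment_expanded and rec.pre_count >= 1):
            continue
        ct = by_key.get(rec.key)
        if ct is None:
            raise KeyError(f"clonotype {rec.key!r} not found")
        pre_cells = ct.cells_in(rec.patient, "pre", "blood")
        post_cells = ct.cells_in(rec.patient, "post", "blood")
        if not pre_cells or not post_cells:
            # pre cells were attributed through a single-chain partner; the
            # flux of this clonotype is not attributable to clusters
            continue
        pre_cl = [_cluster(b) for b in pre_cells]
        post_cl = [_cluster(b) for b in post_cells]
        if mode == "incidence":
            for c1 in set(pre_cl):
                for c2 in set(post_cl):
                    counts[(c1, c2)] += 1
                    labels_pre.add(c1)
                    labels_post.add(c2)
        else:
            modal_pre = sorted(Counter(pre_cl).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            modal_post = sorted(Counter(post_cl).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            counts[(modal_pre, modal_post)] += 1
            labels_pre.add(modal_pre)
            labels_post.add(modal_post)
    rows = sorted(labels_pre)
    cols = sorted(labels_post)
    table = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for (c1, c2), n in counts.items():
        table.loc[c1, c2] = n
    table.index.name = "pre_cluster"
    table.columns.name = "post_cluster"
    return table


def ne_rate(records: Sequence[DynamicsRecord], denominator: str = "post_clonotypes") -> float:
    """Rate of novel expanded clonotypes in one patient.

    Default denominator is the number of clonotypes observed post-treatment;
    the alternative normalizes by the number of treatment-expanded
    clonotypes.
    """
    if denominator not in NE_DENOMINATORS:
        raise ValueError(f"unknown denominator {denominator!r}")
    n_ne = sum(1 for r in records if r.treatment_expanded and r.origin == "novel")
    if denominator == "post_clonotypes":
        den = sum(1 for r in records if r.post_count > 0)
    else:
        den = sum(1 for r in records if r.treatment_expanded)
    if den == 0:
        raise ValueError("empty denominator: no qualifying post-treatment clonotypes")
    return n_ne / den


def compare_groups(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) comparison.

    Uses the exact null distribution for combined n ≤ 20 without ties and
    the tie-corrected normal approximation otherwise. Returns (U, p) with
    U the statistic of the first sample.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return float(res.statistic), max(p, np.finfo(float).tiny)


def dynamics_table(records: Sequence[DynamicsRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def write_dynamics_table(records: Sequence[DynamicsRecord], path: str | Path) -> None:
    dynamics_table(records).to_csv(path, sep="\t", index=False)


def write_flux_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
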