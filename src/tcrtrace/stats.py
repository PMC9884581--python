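"""Per-sample repertoire summaries: expansion categories, Gini clonality,
richness and detection depth."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clonotypes import Clonotype


@dataclass(frozen=True)
class RepertoireSummary:
    patient: str
    timepoint: str
    compartment: str
    n_cells: int
    n_clonotypes: int
    n_singleton: int
    n_expanded: int
    n_hyperexpanded: int
    gini: float


def expansion_class(count: int, hyper_threshold: int = 10) -> str:
    """Three-way clone-size category: ``singleton`` (1 cell), ``expanded``
    (2 to hyper_threshold-1) or ``hyperexpanded`` (≥ hyper_threshold)."""
    if count < 1:
        raise ValueError(f"clone size must be ≥ 1, got {count}")
    if hyper_threshold < 2:
        raise ValueError("hyper_threshold must be ≥ 2")
    if count == 1:
        return "singleton"
    if count >= hyper_threshold:
        return "hyperexpanded"
    return "expanded"


def gini(counts: Sequence[int]) -> float:
    """Gini coefficient of a clone-size vector.

    G = Σᵢ Σⱼ |xᵢ − xⱼ| / (2 n² x̄), computed via the sorted closed form;
    G ∈ [0, 1) and is invariant under positive scaling of the counts.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("gini of an empty clone-size vector is undefined")
    if (x <= 0).any():
        raise ValueError("clone sizes must be positive")
    n = x.size
    xs = np.sort(x)
    total = xs.sum()
    # Σᵢ Σⱼ |xᵢ − xⱼ| = 2 Σ_i (2i − n − 1) x_(i)  with i = 1..n ascending
    g = (2.0 * np.sum(np.arange(1, n + 1) * xs) - (n + 1) * total) / (n * total)
    return float(max(g, 0.0))


def sample_clone_sizes(
    clonotypes: Sequence[Clonotype], patient: str, timepoint: str, compartment: str
) -> np.ndarray:
    """Clone-size vector of one sample (clonotypes with ≥ 1 cell there)."""
    sizes = [
        ct.size_in(patient, timepoint, compartment)
        for ct in clonotypes
        if ct.size_in(patient, timepoint, compartment) > 0
    ]
    return np.asarray(sizes, dtype=int)


def detection_depth(
    clonotypes: Sequence[Clonotype], patient: str, timepoint: str, compartment: str
) -> int:
    """Number of cells with an assigned clonotype in the sample."""
    return int(sample_clone_sizes(clonotypes, patient, timepoint, compartment).sum())


def summarize_repertoire(
    clonotypes: Sequence[Clonotype],
    patient: str,
    timepoint: str,
    compartment: str,
    hyper_threshold: int = 10,
) -> RepertoireSummary:
    sizes = sample_clone_sizes(clonotypes, patient, timepoint, compartment)
    classes = [expansion_class(int(s), hyper_threshold) for s in sizes]
    return RepertoireSummary(
        patient=patient,
        timepoint=timepoint,
        compartment=compartment,
        n_cells=int(sizes.sum()),
        n_clonotypes=len(sizes),
        n_singleton=classes.count("singleton"),
        n_expanded=classes.count("expanded"),
        n_hyperexpanded=classes.count("hyperexpanded"),
        gini=gini(sizes) if len(sizes) else 0.0,
    )


def summary_table(summaries: Sequence[RepertoireSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def write_summary_table(summaries: Sequence[RepertoireSummary], path: str | Path) -> None:
    summary_table(summaries).to_csv(path, sep="\t", index=False)
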