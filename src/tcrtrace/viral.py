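"""Putative viral-reactivity annotation by exact TCRβ CDR3 matching.

A clonotype is flagged viral when its β-chain CDR3 amino-acid sequence
exactly equals a reference entry's CDR3β (case-sensitive; optionally also
requiring V-gene identity). Clonotypes lacking a β chain are never flagged.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clonotypes import Clonotype
from .io import ReferenceDB


@dataclass(frozen=True)
class ViralAnnotation:
    key: str
    viral: bool
    matched_species: tuple[str, ...]
    matched_epitopes: tuple[str, ...]


def annotate_viral(
    clonotypes: Sequence[Clonotype],
    db: ReferenceDB,
    require_v_gene: bool = False,
) -> list[ViralAnnotation]:
    """Flag clonotypes whose β CDR3 exactly matches a reference entry.

    All matching antigen species/epitopes are accumulated (sorted, unique).
    Deterministic and order-invariant.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    by_cdr3 = defaultdict(list)
    for e in db.entries:
        by_cdr3[e.cdr3_beta_aa].append(e)
    out: list[ViralAnnotation] = []
    for ct in clonotypes:
        species: set[str] = set()
        epitopes: set[str] = set()
        if ct.beta_cdr3 is not None:
            for e in by_cdr3.get(ct.beta_cdr3, ()):
                if require_v_gene and (
                    e.v_gene is None or ct.beta_v_gene is None or e.v_gene != ct.beta_v_gene
                ):
                    continue
                species.add(e.antigen_species)
                epitopes.add(e.epitope)
        out.append(
            ViralAnnotation(
                key=ct.key,
                viral=bool(species),
                matched_species=tuple(sorted(species)),
                matched_epitopes=tuple(sorted(epitopes)),
            )
        )
    return out


def viral_fraction(annotations: Sequence[ViralAnnotation]) -> float:
    """Fraction of clonotypes flagged viral."""
    if not annotations:
        raise ValueError("no annotations provided")
    return sum(a.viral for a in annotations) / len(annotations)


def annotation_table(annotations: Sequence[ViralAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": a.key,
                "viral": a.viral,
                "matched_species": ";".join(a.matched_species),
                "matched_epitopes": ";".join(a.matched_epitopes),
            }
            for a in annotations
        ]
    )


def write_annotation_table(annotations: Sequence[ViralAnnotation], path: str | Path) -> None:
    annotation_table(annotations).to_csv(path, sep="\t", index=False)
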