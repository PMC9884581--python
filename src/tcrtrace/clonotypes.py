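"""Clonotype calling and cross-sample/cross-compartment matching.

Cells sharing the same CDR3 amino-acid sequences are grouped into clonotypes.
Per cell, one α and one β chain are retained (highest UMI support; ties break
to the lexicographically smallest CDR3), so the clonotype key is the ordered
(α CDR3, β CDR3) pair with absent chains represented explicitly. Matching
between two clonotype sets requires equality of both CDR3s when both partners
carry both chains; when either partner lacks a chain, equality of the chain
present in both suffices (single-chain fallback).
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import CellRecord, ChainRecord

log = logging.getLogger(__name__)

MATCH_MODES = ("both_chains", "alpha_only", "beta_only")


def make_key(alpha_cdr3: str | None, beta_cdr3: str | None) -> str:
    """Canonical clonotype key, e.g. ``"TRA:CAVR|TRB:CASS"``; absent chains
    are written as ``-``."""
    return f"TRA:{alpha_cdr3 or '-'}|TRB:{beta_cdr3 or '-'}"


@dataclass
class Clonotype:
    """A set of cells sharing a TCR key, bucketed per sample.

    ``members`` maps ``(patient, timepoint, compartment)`` to the member cell
    barcodes of that sample.
    """

    key: str
    alpha_cdr3: str | None
    beta_cdr3: str | None
    members: dict[tuple[str, str, str], list[str]] = field(default_factory=dict)
    beta_v_gene: str | None = None

    def __post_init__(self) -> None:
        if self.alpha_cdr3 is None and self.beta_cdr3 is None:
            raise ValueError("clonotype must carry at least one chain")

    def cells_in(self, patient: str, timepoint: str, compartment: str) -> list[str]:
        return self.members.get((patient, timepoint, compartment), [])

    def size_in(self, patient: str, timepoint: str, compartment: str) -> int:
        return len(self.cells_in(patient, timepoint, compartment))

    @property
    def total_size(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def patients(self) -> set[str]:
        return {p for (p, _, _) in self.members}

    @property
    def has_both_chains(self) -> bool:
        return self.alpha_cdr3 is not None and self.beta_cdr3 is not None


@dataclass
class MatchResult:
    """All qualifying clonotype pairs between two sets.

    ``pairs`` holds ``(key_in_a, key_in_b, match_mode)`` triples;
    ``both_chains`` appears only when both partners carry both chains.
    """

    pairs: list[tuple[str, str, str]]

    def a_to_b(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for ka, kb, _ in self.pairs:
            out[ka].add(kb)
        return dict(out)

    def matched_a_keys(self) -> set[str]:
        return {ka for ka, _, _ in self.pairs}

    def matched_b_keys(self) -> set[str]:
        return {kb for _, kb, _ in self.pairs}


def call_clonotypes(
    chains: Sequence[ChainRecord],
    cells: Sequence[CellRecord],
    collapse: str = "top_umi",
    productive_only: bool = True,
) -> list[Clonotype]:
    """Group cells into clonotypes by their (α CDR3, β CDR3) pair.

    Only productive chains contribute by default (clonotype identity is a
    functional-TCR concept). ``collapse`` controls how multi-chain cells are
    keyed: ``"top_umi"`` (default) keeps the single highest-UMI chain per
    locus, breaking ties by lexicographically smallest CDR3; ``"all_chains"``
    joins all distinct CDR3s per locus with ``+``. Chains whose barcode is
    absent from ``cells`` are logged and dropped; cells with no retained
    chain are excluded.
    """
    if collapse not in ("top_umi", "all_chains"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    if productive_only:
        chains = [c for c in chains if c.productive]
    cell_by_bc: dict[str, CellRecord] = {}
    for c in cells:
        if c.barcode in cell_by_bc:
            raise ValueError(f"duplicate barcode across dataset: {c.barcode!r}")
        cell_by_bc[c.barcode] = c
    per_cell: dict[str, list[ChainRecord]] = defaultdict(list)
    orphans = 0
    for ch in chains:
        if ch.barcode not in cell_by_bc:
            orphans += 1
            continue
        per_cell[ch.barcode].append(ch)
    if orphans:
        log.info("dropped %d chains with barcodes absent from cell metadata", orphans)

    grouped: dict[tuple[str | None, str | None], Clonotype] = {}
    for bc, chs in per_cell.items():
        tra = [c for c in chs if c.locus == "TRA"]
        trb = [c for c in chs if c.locus == "TRB"]
        if collapse == "top_umi":
            best_a = min(tra, key=lambda c: (-c.umis, c.cdr3_aa)) if tra else None
            best_b = min(trb, key=lambda c: (-c.umis, c.cdr3_aa)) if trb else None
            alpha = best_a.cdr3_aa if best_a else None
            beta = best_b.cdr3_aa if best_b else None
            beta_v = best_b.v_gene if best_b else None
        else:
            alpha = "+".join(sorted({c.cdr3_aa for c in tra})) or None
            beta = "+".join(sorted({c.cdr3_aa for c in trb})) or None
            beta_v = trb[0].v_gene if trb else None
        if alpha is None and beta is None:
            continue
        ckey = (alpha, beta)
        if ckey not in grouped:
            grouped[ckey] = Clonotype(
                key=make_key(alpha, beta), alpha_cdr3=alpha, beta_cdr3=beta,
                beta_v_gene=beta_v,
            )
        ct = grouped[ckey]
        cell = cell_by_bc[bc]
        ct.members.setdefault(cell.sample, []).append(bc)
    # deterministic output order regardless of input dict iteration history
    return sorted(grouped.values(), key=lambda c: c.key)


def match_clonotypes(
    set_a: Sequence[Clonotype], set_b: Sequence[Clonotype]
) -> MatchResult:
    """Match clonotypes between two sets with the single-chain fallback rule.

    When both partners carry both chains, a match requires equality of both
    CDR3s (mode ``both_chains``). When either partner lacks a chain, equality
    of the chain present in both suffices (``alpha_only``/``beta_only``).
    All qualifying pairs are reported, so single-chain clonotypes can match
    one-to-many.
    """
    if not set_a or not set_b:
        raise ValueError("both clonotype sets must be nonempty")
    full_b: dict[tuple[str, str], list[Clonotype]] = defaultdict(list)
    alpha_only_b: dict[str, list[Clonotype]] = defaultdict(list)
    beta_only_b: dict[str, list[Clonotype]] = defaultdict(list)
    any_alpha_b: dict[str, list[Clonotype]] = defaultdict(list)
    any_beta_b: dict[str, list[Clonotype]] = defaultdict(list)
    for cb in set_b:
        if cb.alpha_cdr3 is not None:
            any_alpha_b[cb.alpha_cdr3].append(cb)
        if cb.beta_cdr3 is not None:
            any_beta_b[cb.beta_cdr3].append(cb)
        if cb.has_both_chains:
            full_b[(cb.alpha_cdr3, cb.beta_cdr3)].append(cb)
        elif cb.alpha_cdr3 is not None:
            alpha_only_b[cb.alpha_cdr3].append(cb)
        else:
            beta_only_b[cb.beta_cdr3].append(cb)

    pairs: list[tuple[str, str, str]] = []
    for ca in set_a:
        if ca.has_both_chains:
            for cb in full_b.get((ca.alpha_cdr3, ca.beta_cdr3), ()):
                pairs.append((ca.key, cb.key, "both_chains"))
            for cb in alpha_only_b.get(ca.alpha_cdr3, ()):
                pairs.append((ca.key, cb.key, "alpha_only"))
            for cb in beta_only_b.get(ca.beta_cdr3, ()):
                pairs.append((ca.key, cb.key, "beta_only"))
        elif ca.beta_cdr3 is not None:
            for cb in any_beta_b.get(ca.beta_cdr3, ()):
                pairs.append((ca.key, cb.key, "beta_only"))
        else:
            for cb in any_alpha_b.get(ca.alpha_cdr3, ()):
                pairs.append((ca.key, cb.key, "alpha_only"))
    return MatchResult(pairs=sorted(pairs))


def annotate_tumor_matched(
    blood: Sequence[Clonotype], tumor: Sequence[Clonotype]
) -> set[str]:
    """Blood clonotype keys with at least one tumor match (existence test
    under the single-chain fallback rule). Both sets must derive from the
    same patient."""
    blood_pat = set().union(*(c.patients for c in blood)) if blood else set()
    tumor_pat = set().union(*(c.patients for c in tumor)) if tumor else set()
    if len(blood_pat | tumor_pat) > 1:
        raise ValueError(
            f"cross-patient matching refused: blood={sorted(blood_pat)}, "
            f"tumor={sorted(tumor_pat)}"
        )
    if not blood or not tumor:
        return set()
    return match_clonotypes(blood, tumor).matched_a_keys()


def clonotype_table(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    """One row per clonotype per sample: key, chain CDR3s, cell count and
    within-sample frequency."""
    sample_totals: dict[tuple[str, str, str], int] = defaultdict(int)
    for ct in clonotypes:
        for sample, bcs in ct.members.items():
            sample_totals[sample] += len(bcs)
    rows = []
    for ct in clonotypes:
        for (patient, tp, comp), bcs in sorted(ct.members.items()):
            rows.append(
                {
                    "patient": patient,
                    "timepoint": tp,
                    "compartment": comp,
                    "key": ct.key,
                    "alpha_cdr3": ct.alpha_cdr3 or "",
                    "beta_cdr3": ct.beta_cdr3 or "",
                    "n_cells": len(bcs),
                    "frequency": len(bcs) / sample_totals[(patient, tp, comp)],
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["patient", "timepoint", "compartment", "key"], ignore_index=True
    ) if rows else pd.DataFrame(
        columns=["patient", "timepoint", "compartment", "key", "alpha_cdr3",
                 "beta_cdr3", "n_cells", "frequency"]
    )


def write_clonotype_table(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    clonotype_table(clonotypes).to_csv(path, sep="\t", index=False)


def clonotypes_by_key(clonotypes: Iterable[Clonotype]) -> Mapping[str, Clonotype]:
    out: dict[str, Clonotype] = {}
    for ct in clonotypes:
        out.setdefault(ct.key, ct)
    return out
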