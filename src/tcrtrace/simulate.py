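"""Synthetic cohort generator with exact ground truth.

Emulates the statistical structure of a longitudinal checkpoint-blockade
scTCR/scRNA cohort: multi-patient paired pre/post blood samples plus a
baseline tumor sample, power-law clone-size distributions, paired α/β CDR3s
with a configurable fraction of clones missing one chain, cluster-conditioned
negative-binomial expression with a planted memory program, injected novel
expanded (NE) clones that are constructed absent from pre-treatment samples,
blood–tumor shared clones, and a minority of clones whose CDR3β is copied
into an emitted reference database.

Construction guarantees (rather than merely makes likely) the longitudinal
classes: NE clones appear only post-treatment with ≥2 cells; PE-expanded
clones get a strictly higher post frequency; PE-static and singleton clones
never do. Classification accuracy against truth is therefore exact.
All randomness flows through one ``numpy.random.Generator``, so a seed fully
determines the cohort (including emitted files, byte for byte).
"""
from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from . import io as rio
from .clonotypes import make_key
from .io import CellRecord, ChainRecord, ExpressionMatrix, RefEntry, ReferenceDB

AA20 = "ACDEFGHIKLMNPQRSTVWY"
CLUSTER_POOL = (
    "Mem-IL7R",
    "Naive-CCR7",
    "Eff-GZMB",
    "Eff-GZMK",
    "Cycling-MKI67",
    "MAIT-KLRB1",
    "Eff-CD320",
    "Treg-FOXP3",
)
MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CYB")
RIBO_GENES = ("RPL3", "RPL13", "RPS6", "RPS19")
VIRAL_SPECIES = ("CMV", "EBV", "InfluenzaA")
CLONE_CLASSES = ("NE", "PE-expanded", "PE-static", "singleton", "tumor_private")


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults encode the emulated study design: six patients with paired
    pre/post blood draws (2,000 T cells each) and a baseline tumor sample,
    5% injected novel expanded clones, 3.4% of clonotypes carrying
    reference-database CDR3βs, 10% of tumor clones shared with blood, and a
    40-gene memory program shifted by 0.5 (log₂) in NE-clone cells and
    modestly (0.25 log₂) in post-treatment pre-existing cells.
    """

    n_patients: int = 6
    cells_pre_blood: int = 2000
    cells_post_blood: int = 2000
    cells_tumor: int = 500
    clone_size_power_alpha: float = 2.5
    frac_missing_chain: float = 0.10
    frac_ne: float = 0.05
    frac_expand: float = 0.15
    ne_memory_shift: float = 0.5  # log2 fold on memory genes in NE-clone cells
    pe_timepoint_shift: float = 0.25  # log2 fold on memory genes in post PE cells
    frac_tumor_shared: float = 0.10
    frac_viral: float = 0.034
    n_genes: int = 1000
    n_memory_genes: int = 40
    n_effector_genes: int = 40
    n_cluster_types: int = 6
    nb_dispersion: float = 0.3
    library_sigma: float = 0.3
    frac_high_mito: float = 0.03
    mito_boost: float = 25.0
    frac_nonproductive: float = 0.02
    n_db_decoys: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_missing_chain", "frac_ne", "frac_expand",
                     "frac_tumor_shared", "frac_viral", "frac_high_mito",
                     "frac_nonproductive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.clone_size_power_alpha <= 1.0:
            raise ValueError("clone_size_power_alpha must be > 1")
        if not 1 <= self.n_cluster_types <= len(CLUSTER_POOL):
            raise ValueError(f"n_cluster_types must be in 1..{len(CLUSTER_POOL)}")
        reserved = len(MITO_GENES) + len(RIBO_GENES) + self.n_memory_genes + self.n_effector_genes
        if self.n_genes < reserved + 10:
            raise ValueError(f"n_genes must be at least {reserved + 10}")

    @property
    def cluster_labels(self) -> tuple[str, ...]:
        return CLUSTER_POOL[: self.n_cluster_types]


@dataclass
class CloneTruth:
    """Generator ground truth for one clone."""

    clone_id: str
    patient: str
    cls: str
    pre_count: int = 0
    post_count: int = 0
    tumor_count: int = 0
    alpha_cdr3: str | None = None
    beta_cdr3: str | None = None
    alpha_v: str | None = None
    beta_v: str | None = None
    viral: bool = False
    tumor_shared: bool = False
    home_cluster: str = ""

    @property
    def key(self) -> str:
        return make_key(self.alpha_cdr3, self.beta_cdr3)


@dataclass
class SyntheticCohort:
    config: SimConfig
    clones: list[CloneTruth]
    cells: list[CellRecord]
    chains: list[ChainRecord]
    db: ReferenceDB
    expr: ExpressionMatrix | None = None
    gene_truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# repertoire structure
# ---------------------------------------------------------------------------

def _power_law_sizes(budget: int, alpha: float, rng: np.random.Generator,
                     cap: int | None = None) -> list[int]:
    """Discrete power-law clone sizes truncated to fill ``budget`` exactly."""
    if budget <= 0:
        return []
    cap = cap if cap is not None else max(2, budget // 10)
    sizes: list[int] = []
    total = 0
    while total < budget:
        s = int(min(rng.zipf(alpha), cap, budget - total))
        sizes.append(s)
        total += s
    return sizes


def simulate_repertoire(config: SimConfig, patient: str,
                        rng: np.random.Generator) -> list[CloneTruth]:
    """Clone-size assignments for one patient's pre/post blood and tumor.

    Emitted totals match the configured budgets exactly; longitudinal
    classes are enforced by construction (see module docstring).
    """
    n_pre_cells, n_post_cells = config.cells_pre_blood, config.cells_post_blood
    pre = _power_law_sizes(n_pre_cells, config.clone_size_power_alpha, rng)
    n = len(pre)
    n_ne = int(round(config.frac_ne * n))
    cap = max(2, n_post_cells // 10)
    ne_sizes = [int(min(rng.zipf(config.clone_size_power_alpha) + 1, cap))
                for _ in range(n_ne)]
    if sum(ne_sizes) >= n_post_cells:
        raise ValueError(
            f"infeasible budget: {sum(ne_sizes)} novel-expanded cells exceed the "
            f"post-treatment budget of {n_post_cells}"
        )
    ratio = n_post_cells / n_pre_cells
    n_exp = int(round(config.frac_expand * n))
    exp_idx = set(rng.choice(n, size=n_exp, replace=False).tolist()) if n_exp else set()
    post = [0] * n
    for i in range(n):
        base = math.floor(pre[i] * ratio)
        post[i] = max(2, base + 1) if i in exp_idx else base
    surplus = sum(post) + sum(ne_sizes) - n_post_cells
    if surplus > 0:
        for i in rng.permutation(n):
            if surplus <= 0:
                break
            if i in exp_idx:
                continue
            take = min(post[i], surplus)
            post[i] -= take
            surplus -= take
        if surplus > 0:
            raise ValueError("infeasible budget: cannot balance the post-treatment sample")
    n_filler = 0
    deficit = -surplus
    exp_list = sorted(exp_idx)
    while deficit > 0:
        if exp_list and rng.random() < 0.5:
            i = exp_list[int(rng.integers(len(exp_list)))]
            add = int(min(deficit, rng.zipf(config.clone_size_power_alpha)))
            post[i] += add
            deficit -= add
        else:
            n_filler += 1
            deficit -= 1

    labels = config.cluster_labels
    mem_labels = [l for l in labels if l.startswith(("Mem", "Naive"))]

    def _home(cls: str) -> str:
        if cls == "NE" and mem_labels and rng.random() < 0.6:
            return str(rng.choice(mem_labels))
        return str(rng.choice(labels))

    clones: list[CloneTruth] = []
    serial = 0

    def _new(cls: str, pre_c: int, post_c: int) -> CloneTruth:
        nonlocal serial
        ct = CloneTruth(
            clone_id=f"{patient}-c{serial:05d}", patient=patient, cls=cls,
            pre_count=pre_c, post_count=post_c, home_cluster=_home(cls),
        )
        serial += 1
        return ct

    for i in range(n):
        if i in exp_idx:
            cls = "PE-expanded"
        elif pre[i] >= 2:
            cls = "PE-static"
        else:
            cls = "singleton"
        clones.append(_new(cls, pre[i], post[i]))
    for s in ne_sizes:
        clones.append(_new("NE", 0, s))
    for _ in range(n_filler):
        clones.append(_new("singleton", 0, 1))

    tumor_sizes = _power_law_sizes(config.cells_tumor, config.clone_size_power_alpha, rng)
    n_shared = int(round(config.frac_tumor_shared * len(tumor_sizes)))
    n_shared = min(n_shared, len(clones))
    if n_shared:
        # abundance-weighted sharing: bigger circulating clones are the ones
        # re-detected in the tumor sample
        weights = np.array([c.pre_count + c.post_count for c in clones], dtype=float)
        shared_idx = rng.choice(len(clones), size=n_shared, replace=False,
                                p=weights / weights.sum())
        for j, ci in enumerate(shared_idx):
            clones[ci].tumor_count = tumor_sizes[j]
            clones[ci].tumor_shared = True
    for s in tumor_sizes[n_shared:]:
        ct = _new("tumor_private", 0, 0)
        ct.tumor_count = s
        clones.append(ct)
    return clones


# ---------------------------------------------------------------------------
# TCR sequences
# ---------------------------------------------------------------------------

def _random_cdr3(rng: np.random.Generator, registry: set[str]) -> str:
    """Collision-free random CDR3 (length 10–18, C...F convention)."""
    while True:
        length = int(rng.integers(10, 19))
        mid = "".join(AA20[i] for i in rng.integers(0, 20, size=length - 2))
        s = "C" + mid + "F"
        if s not in registry:
            registry.add(s)
            return s


def simulate_tcrs(
    clones: Sequence[CloneTruth],
    config: SimConfig,
    rng: np.random.Generator,
    registries: tuple[set[str], set[str]] | None = None,
) -> list[RefEntry]:
    """Assign unique α/β CDR3 pairs, apply chain dropout and plant viral βs.

    ``registries`` holds the cohort-wide α and β CDR3 sets guaranteeing
    uniqueness across patients. Returns the reference-database entries for
    the planted viral clones. Viral flags are planted only on clones that
    retain their β chain, so the planted set is exactly recoverable by
    β-chain matching.
    """
    areg, breg = registries if registries is not None else (set(), set())
    for ct in clones:
        ct.alpha_cdr3 = _random_cdr3(rng, areg)
        ct.beta_cdr3 = _random_cdr3(rng, breg)
        ct.alpha_v = f"TRAV{int(rng.integers(1, 41))}"
        ct.beta_v = f"TRBV{int(rng.integers(1, 31))}-1"
    n_missing = int(round(config.frac_missing_chain * len(clones)))
    if n_missing:
        for i in rng.choice(len(clones), size=n_missing, replace=False):
            if rng.random() < 0.5:
                clones[i].alpha_cdr3 = None
                clones[i].alpha_v = None
            else:
                clones[i].beta_cdr3 = None
                clones[i].beta_v = None
    blood = [c for c in clones if c.cls != "tumor_private"]
    eligible = [c for c in blood if c.beta_cdr3 is not None]
    n_viral = min(int(round(config.frac_viral * len(blood))), len(eligible))
    entries: list[RefEntry] = []
    if n_viral:
        for i in rng.choice(len(eligible), size=n_viral, replace=False):
            c = eligible[i]
            c.viral = True
            epitope = "".join(AA20[j] for j in rng.integers(0, 20, size=9))
            entries.append(
                RefEntry(
                    cdr3_beta_aa=c.beta_cdr3,
                    epitope=epitope,
                    antigen_species=str(rng.choice(VIRAL_SPECIES)),
                    v_gene=c.beta_v,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# cells and chains
# ---------------------------------------------------------------------------

def _emit_cells(
    clones: Sequence[CloneTruth], config: SimConfig, rng: np.random.Generator
) -> tuple[list[CellRecord], list[ChainRecord]]:
    labels = config.cluster_labels
    serials: dict[tuple[str, str, str], int] = defaultdict(int)
    cells: list[CellRecord] = []
    chains: list[ChainRecord] = []
    for ct in clones:
        samples = (
            ("pre", "blood", ct.pre_count),
            ("post", "blood", ct.post_count),
            ("pre", "tumor", ct.tumor_count),
        )
        for tp, comp, count in samples:
            for _ in range(count):
                sk = (ct.patient, tp, comp)
                bc = f"{ct.patient}:{tp}:{comp}:{serials[sk]:05d}"
                serials[sk] += 1
                cluster = (
                    ct.home_cluster if rng.random() < 0.8 else str(rng.choice(labels))
                )
                cells.append(
                    CellRecord(barcode=bc, patient=ct.patient, timepoint=tp,
                               compartment=comp, cluster=cluster)
                )
                if ct.alpha_cdr3 is not None:
                    chains.append(
                        ChainRecord(barcode=bc, locus="TRA", cdr3_aa=ct.alpha_cdr3,
                                    v_gene=ct.alpha_v, j_gene="TRAJ1",
                                    productive=True, umis=int(rng.integers(2, 30)))
                    )
                if ct.beta_cdr3 is not None:
                    chains.append(
                        ChainRecord(barcode=bc, locus="TRB", cdr3_aa=ct.beta_cdr3,
                                    v_gene=ct.beta_v, j_gene="TRBJ1-1",
                                    productive=True, umis=int(rng.integers(2, 30)))
                    )
                if rng.random() < config.frac_nonproductive:
                    junk = "".join(AA20[j] for j in rng.integers(0, 20, size=12))
                    chains.append(
                        ChainRecord(barcode=bc, locus="TRB", cdr3_aa="C" + junk + "F",
                                    productive=False, umis=1)
                    )
    return cells, chains


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene metadata: symbol, program membership and base mean expression.

    Neutral base means are log-normal across genes; memory/effector program
    genes draw from a moderately expressed range so their planted shifts are
    detectable at realistic depths (signature genes are well-detected genes).
    """
    names: list[str] = list(MITO_GENES) + list(RIBO_GENES)
    programs: list[str] = ["mito"] * len(MITO_GENES) + ["ribo"] * len(RIBO_GENES)
    names += [f"MEM{i:03d}" for i in range(config.n_memory_genes)]
    programs += ["memory"] * config.n_memory_genes
    names += [f"EFF{i:03d}" for i in range(config.n_effector_genes)]
    programs += ["effector"] * config.n_effector_genes
    n_neutral = config.n_genes - len(names)
    names += [f"GENE{i:04d}" for i in range(n_neutral)]
    programs += ["neutral"] * n_neutral
    base = np.empty(config.n_genes)
    prog = np.array(programs)
    base[prog == "mito"] = 3.0
    base[prog == "ribo"] = 2.0
    n_prog = int(((prog == "memory") | (prog == "effector")).sum())
    base[(prog == "memory") | (prog == "effector")] = np.exp(
        rng.uniform(np.log(1.0), np.log(4.0), size=n_prog)
    )
    base[prog == "neutral"] = rng.lognormal(np.log(0.5), 1.2, size=n_neutral)
    return pd.DataFrame({"program": programs, "base_mean": base},
                        index=pd.Index(names, name="gene"))


def _cluster_factors(
    gene_table: pd.DataFrame, labels: Sequence[str], rng: np.random.Generator
) -> np.ndarray:
    """(genes × clusters) multiplicative fold-change matrix: 25 neutral
    marker genes at 2-fold per cluster.

    Cluster identity deliberately rests on neutral genes only: the memory
    program enters expression exclusively through the planted clone-level
    shifts, so zero-shift configurations are genuinely null for the
    signature score.
    """
    prog = gene_table["program"].to_numpy()
    neutral_idx = np.flatnonzero(prog == "neutral")
    fac = np.ones((len(gene_table), len(labels)))
    for j in range(len(labels)):
        markers = rng.choice(neutral_idx, size=min(25, len(neutral_idx)), replace=False)
        fac[markers, j] = 2.0
    return fac


def _nb_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)


def simulate_expression(
    cells: Sequence[CellRecord],
    clone_of: Mapping[str, CloneTruth],
    config: SimConfig,
    rng: np.random.Generator,
    gene_table: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts conditioned on cluster and clone class.

    Memory-program genes are shifted by ``2**ne_memory_shift`` in NE-clone
    cells and by ``2**pe_timepoint_shift`` in post-treatment blood cells of
    pre-existing clones; a small fraction of cells gets a boosted
    mitochondrial load so QC filtering has work to do; per-cell library-size
    factors are log-normal. Returns the matrix and the gene truth table.
    """
    if gene_table is None:
        gene_table = _gene_table(config, rng)
    labels = list(config.cluster_labels)
    cfac = _cluster_factors(gene_table, labels, rng)
    base = gene_table["base_mean"].to_numpy()
    prog = gene_table["program"].to_numpy()
    mem_idx = np.flatnonzero(prog == "memory")
    mito_idx = np.flatnonzero(prog == "mito")

    n_cells = len(cells)
    cl_idx = np.empty(n_cells, dtype=int)
    mem_fac = np.ones(n_cells)
    for i, cell in enumerate(cells):
        if cell.cluster not in labels:
            raise ValueError(f"cell {cell.barcode!r} has no valid cluster label")
        cl_idx[i] = labels.index(cell.cluster)
        clone = clone_of[cell.barcode]
        if cell.timepoint == "post" and cell.compartment == "blood":
            if clone.cls == "NE":
                mem_fac[i] = 2.0 ** config.ne_memory_shift
            elif clone.pre_count > 0:
                mem_fac[i] = 2.0 ** config.pe_timepoint_shift
    high_mito = rng.random(n_cells) < config.frac_high_mito
    lib = rng.lognormal(0.0, config.library_sigma, size=n_cells)

    blocks: list[sp.csr_matrix] = []
    chunk = 2000
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        mu = base[:, None] * cfac[:, cl_idx[start:stop]]
        unshifted_totals = mu.sum(axis=0)
        mu[mem_idx] *= mem_fac[start:stop]
        # keep the expected sequencing depth invariant across planted classes
        # so detection (zero) rates carry no depth confound
        mu *= unshifted_totals / mu.sum(axis=0)
        mu[mito_idx] *= np.where(high_mito[start:stop], config.mito_boost, 1.0)
        mu *= lib[start:stop]
        blocks.append(sp.csr_matrix(_nb_counts(mu, config.nb_dispersion, rng)))
    counts = sp.hstack(blocks).tocsr() if blocks else sp.csr_matrix((len(base), 0), dtype=np.int64)
    expr = ExpressionMatrix(
        genes=np.array(gene_table.index, dtype=object),
        barcodes=np.array([c.barcode for c in cells], dtype=object),
        counts=counts.astype(np.int64),
    )
    return expr, gene_table


# ---------------------------------------------------------------------------
# precursor fixture for signature derivation
# ---------------------------------------------------------------------------

@dataclass
class PrecursorDataset:
    """Paired pre/post memory- vs effector-precursor expression fixture.

    ``groups_*`` map barcodes onto the precursor labels "5M" (memory) and
    "5E" (effector). The memory program is shifted up in 5M and the effector
    program in 5E by ``lfc`` (log₂) at both timepoints; two excluded-prefix
    genes (MT-ND1, RPL3) are deliberately confounded upward in 5M so the
    symbol-exclusion rule is exercised.
    """

    expr_pre: ExpressionMatrix
    groups_pre: dict[str, str]
    expr_post: ExpressionMatrix
    groups_post: dict[str, str]
    memory_genes: list[str]
    effector_genes: list[str]
    gene_table: pd.DataFrame


def simulate_precursor_dataset(
    config: SimConfig,
    seed: int,
    n_cells_per_group: int = 500,
    lfc: float = 0.6,
) -> PrecursorDataset:
    rng = np.random.default_rng(seed)
    gt = _gene_table(config, rng)
    base = gt["base_mean"].to_numpy()
    prog = gt["program"].to_numpy()
    mem_idx = np.flatnonzero(prog == "memory")
    eff_idx = np.flatnonzero(prog == "effector")
    confound_idx = np.array([gt.index.get_loc("MT-ND1"), gt.index.get_loc("RPL3")])

    def _one_timepoint(tp: str) -> tuple[ExpressionMatrix, dict[str, str]]:
        mats, barcodes, groups = [], [], {}
        for grp in ("5M", "5E"):
            mu = base.copy()
            if grp == "5M":
                mu[mem_idx] *= 2.0 ** lfc
                mu[confound_idx] *= 2.0
            else:
                mu[eff_idx] *= 2.0 ** lfc
            # depth equalization across groups: no detection-rate confound
            mu *= base.sum() / mu.sum()
            lib = rng.lognormal(0.0, config.library_sigma, size=n_cells_per_group)
            mats.append(sp.csr_matrix(
                _nb_counts(mu[:, None] * lib, config.nb_dispersion, rng)
            ))
            bcs = [f"prec:{tp}:{grp}:{i:04d}" for i in range(n_cells_per_group)]
            barcodes += bcs
            groups.update({b: grp for b in bcs})
        expr = ExpressionMatrix(
            genes=np.array(gt.index, dtype=object),
            barcodes=np.array(barcodes, dtype=object),
            counts=sp.hstack(mats).tocsr().astype(np.int64),
        )
        return expr, groups

    expr_pre, groups_pre = _one_timepoint("pre")
    expr_post, groups_post = _one_timepoint("post")
    return PrecursorDataset(
        expr_pre=expr_pre,
        groups_pre=groups_pre,
        expr_post=expr_post,
        groups_post=groups_post,
        memory_genes=[str(g) for g in gt.index[mem_idx]],
        effector_genes=[str(g) for g in gt.index[eff_idx]],
        gene_table=gt,
    )


# ---------------------------------------------------------------------------
# cohort assembly and serialization
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig, with_expression: bool = True) -> SyntheticCohort:
    """Generate a full multi-patient cohort with ground truth."""
    rng = np.random.default_rng(config.seed)
    areg: set[str] = set()
    breg: set[str] = set()
    clones: list[CloneTruth] = []
    db_entries: list[RefEntry] = []
    for p in range(config.n_patients):
        patient = f"P{p + 1:02d}"
        pat_clones = simulate_repertoire(config, patient, rng)
        db_entries += simulate_tcrs(pat_clones, config, rng, (areg, breg))
        clones += pat_clones
    for _ in range(config.n_db_decoys):
        epitope = "".join(AA20[j] for j in rng.integers(0, 20, size=9))
        db_entries.append(
            RefEntry(
                cdr3_beta_aa=_random_cdr3(rng, breg),
                epitope=epitope,
                antigen_species=str(rng.choice(VIRAL_SPECIES)),
                v_gene=f"TRBV{int(rng.integers(1, 31))}-1",
            )
        )
    db = ReferenceDB(entries=db_entries)
    cells, chains = _emit_cells(clones, config, rng)
    expr, gene_truth = None, None
    if with_expression:
        clone_of = _clone_of_cells(clones, cells)
        expr, gene_truth = simulate_expression(cells, clone_of, config, rng)
    return SyntheticCohort(
        config=config, clones=clones, cells=cells, chains=chains, db=db,
        expr=expr, gene_truth=gene_truth,
    )


def _clone_of_cells(
    clones: Sequence[CloneTruth], cells: Sequence[CellRecord]
) -> dict[str, CloneTruth]:
    """Recover the barcode → clone map implied by the emission order."""
    out: dict[str, CloneTruth] = {}
    it = iter(cells)
    for ct in clones:
        for _tp, _comp, count in (("pre", "blood", ct.pre_count),
                                  ("post", "blood", ct.post_count),
                                  ("pre", "tumor", ct.tumor_count)):
            for _ in range(count):
                out[next(it).barcode] = ct
    return out


def clone_of_cells(cohort: SyntheticCohort) -> dict[str, CloneTruth]:
    """Barcode → ground-truth clone map for a generated cohort."""
    return _clone_of_cells(cohort.clones, cohort.cells)


def truth_table(cohort: SyntheticCohort) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "patient": c.patient,
                "key": c.key if (c.alpha_cdr3 or c.beta_cdr3) else "",
                "class": c.cls,
                "pre_count": c.pre_count,
                "post_count": c.post_count,
                "tumor_count": c.tumor_count,
                "alpha_cdr3": c.alpha_cdr3 or "",
                "beta_cdr3": c.beta_cdr3 or "",
                "viral": c.viral,
                "tumor_shared": c.tumor_shared,
                "home_cluster": c.home_cluster,
            }
            for c in cohort.clones
        ]
    )


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> Path:
    """Serialize a cohort: per-sample contig CSV + metadata table (+ MTX trio
    when expression was generated), plus the reference DB, truth tables and
    the echoed configuration. Same seed ⇒ byte-identical trees."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    by_sample: dict[tuple[str, str, str], list[CellRecord]] = defaultdict(list)
    for cell in cohort.cells:
        by_sample[cell.sample].append(cell)
    chains_by_bc: dict[str, list[ChainRecord]] = defaultdict(list)
    for ch in cohort.chains:
        chains_by_bc[ch.barcode].append(ch)
    for sample in sorted(by_sample):
        patient, tp, comp = sample
        name = f"{patient}_{tp}_{comp}"
        sample_cells = by_sample[sample]
        rio.write_cell_metadata(sample_cells, d / f"{name}_cells.tsv")
        sample_chains = [ch for c in sample_cells for ch in chains_by_bc[c.barcode]]
        rio.write_contig_annotations(sample_chains, d / f"{name}_contigs.csv")
        if cohort.expr is not None:
            idx = cohort.expr.cell_indexer([c.barcode for c in sample_cells])
            mask = np.zeros(len(cohort.expr.barcodes), dtype=bool)
            mask[idx] = True
            rio.write_expression_mtx(cohort.expr.subset_cells(mask), d / f"{name}_mtx")
    rio.write_vdjdb(cohort.db, d / "vdjdb.tsv")
    truth_table(cohort).to_csv(d / "truth_clones.tsv", sep="\t", index=False)
    if cohort.gene_truth is not None:
        cohort.gene_truth.to_csv(d / "truth_genes.tsv", sep="\t")
    (d / "config.yaml").write_text(yaml.safe_dump(asdict(cohort.config), sort_keys=True))
    return d


@dataclass
class CohortFiles:
    cells: list[CellRecord]
    chains: list[ChainRecord]
    expr: ExpressionMatrix | None
    db: ReferenceDB | None
    truth_clones: pd.DataFrame | None
    truth_genes: pd.DataFrame | None
    config: SimConfig | None


def read_cohort(directory: str | Path, productive_only: bool = True) -> CohortFiles:
    """Read back a cohort directory written by :func:`write_cohort`."""
    d = Path(directory)
    cells: list[CellRecord] = []
    for f in sorted(d.glob("*_cells.tsv")):
        cells += rio.read_cell_metadata(f)
    chains: list[ChainRecord] = []
    for f in sorted(d.glob("*_contigs.csv")):
        chains += rio.read_contig_annotations(f, productive_only=productive_only)
    expr = None
    mtx_dirs = sorted(p for p in d.glob("*_mtx") if p.is_dir())
    if mtx_dirs:
        parts = [rio.read_expression_mtx(p) for p in mtx_dirs]
        genes = parts[0].genes
        for part in parts[1:]:
            if not np.array_equal(part.genes, genes):
                raise rio.FormatError(f"{d}: inconsistent gene lists across samples")
        expr = ExpressionMatrix(
            genes=genes,
            barcodes=np.concatenate([p.barcodes for p in parts]),
            counts=sp.hstack([p.counts for p in parts]).tocsr().astype(np.int64),
        )
    db = rio.read_vdjdb(d / "vdjdb.tsv") if (d / "vdjdb.tsv").exists() else None
    truth_clones = (
        pd.read_csv(d / "truth_clones.tsv", sep="\t")
        if (d / "truth_clones.tsv").exists()
        else None
    )
    truth_genes = (
        pd.read_csv(d / "truth_genes.tsv", sep="\t", index_col=0)
        if (d / "truth_genes.tsv").exists()
        else None
    )
    config = None
    if (d / "config.yaml").exists():
        config = SimConfig(**yaml.safe_load((d / "config.yaml").read_text()))
    return CohortFiles(cells=cells, chains=chains, expr=expr, db=db,
                       truth_clones=truth_clones, truth_genes=truth_genes,
                       config=config)
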