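import numpy as np
import pytest

from tcrtrace.clonotypes import call_clonotypes
from tcrtrace.io import CellRecord, ChainRecord, normalize, qc_filter_cells
from tcrtrace.simulate import SimConfig, simulate_cohort


def make_cell(barcode, patient="P01", timepoint="pre", compartment="blood", cluster=None):
    return CellRecord(barcode=barcode, patient=patient, timepoint=timepoint,
                      compartment=compartment, cluster=cluster)


def make_chain(barcode, locus, cdr3, umis=5, productive=True, v_gene=None):
    return ChainRecord(barcode=barcode, locus=locus, cdr3_aa=cdr3,
                       v_gene=v_gene, productive=productive, umis=umis)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared small cohort with expression (2 patients)."""
    cfg = SimConfig(n_patients=2, cells_pre_blood=600, cells_post_blood=600,
                    cells_tumor=150, n_genes=300, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_normalized(small_cohort):
    expr, cells = qc_filter_cells(small_cohort.expr, small_cohort.cells)
    expr = normalize(expr)
    clonos = call_clonotypes(small_cohort.chains, cells)
    return expr, cells, clonos
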